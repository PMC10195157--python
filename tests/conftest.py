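import numpy as np
import pytest

from caecevo import simulate
from caecevo.phylostrat import CladeSpec


@pytest.fixture(scope="session")
def species_tree():
    return simulate.default_species_tree()


@pytest.fixture(scope="session")
def codon_tree():
    return simulate.default_codon_tree()


@pytest.fixture(scope="session")
def clades():
    return simulate.default_clades()


@pytest.fixture(scope="session")
def foreground(codon_tree):
    return simulate.default_foreground(codon_tree)


def random_topology(rng: np.random.Generator, labels) -> str:
    """Random binary tree over the labels by sequential joining."""
    nodes = [f"{l}:1" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    return nodes[0] + ";"
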