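"""Phylostratigraphic classification of orthogroup gains and losses.

Given an orthogroup x species gene-count table and named clade groups, each
orthogroup is assigned exactly one label:

* ``caecilian_present``   — at least one caecilian gene and at least one
  non-caecilian gene (the retained comparative set);
* ``caecilian_gain``      — genes in caecilians only;
* ``loss_all_amphibia``   — filter 1: no amphibian genes at all, but at
  least two fish species and two non-amphibian tetrapod species represented;
* ``loss_caecilian_only`` — filter 2: no caecilian genes, at least two fish
  species and two tetrapod species represented, of which at least one is a
  frog;
* ``loss_caecilian_amphibia_amniota_present`` — filter 3: no caecilian
  genes, at least two frog species and two amniote species represented;
* ``set_aside``           — caecilian-absent orthogroups matching none of
  the filters.

Filters are applied in order 1 -> 2 -> 3 with first-match-wins, so the
classes are disjoint and exhaustive.  "Present" means gene count >= 1: the
filters are about species representation, not copy number.  "Tetrapod" in
filter 2 means the non-caecilian tetrapods (frogs plus amniotes, plus
salamanders when a salamander group is supplied); the groups are explicit
configuration so users can redefine them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "CladeSpec",
    "read_genecount_tsv",
    "classify_orthogroups",
    "analysis_set",
    "summarize_partition",
]

CLASS_LABELS = (
    "caecilian_gain",
    "loss_all_amphibia",
    "loss_caecilian_only",
    "loss_caecilian_amphibia_amniota_present",
    "caecilian_present",
    "set_aside",
)


@dataclass(frozen=True)
class CladeSpec:
    """Named species groups used by the presence filters.

    Groups need not be disjoint; the non-amphibian tetrapods are the
    amniotes, and "tetrapods" for filter 2 are frogs + salamanders +
    amniotes (every tetrapod except the caecilians themselves).
    """

    caecilians: frozenset
    frogs: frozenset
    fish: frozenset
    amniotes: frozenset
    salamanders: frozenset = field(default_factory=frozenset)

    def __init__(self, caecilians, frogs, fish, amniotes, salamanders=()):
        object.__setattr__(self, "caecilians", frozenset(caecilians))
        object.__setattr__(self, "frogs", frozenset(frogs))
        object.__setattr__(self, "fish", frozenset(fish))
        object.__setattr__(self, "amniotes", frozenset(amniotes))
        object.__setattr__(self, "salamanders", frozenset(salamanders))
        if not self.caecilians:
            raise ValueError("caecilian group must be non-empty")

    @property
    def amphibians(self) -> frozenset:
        return self.caecilians | self.frogs | self.salamanders

    @property
    def tetrapods_noncaecilian(self) -> frozenset:
        return self.frogs | self.salamanders | self.amniotes

    @property
    def tetrapods_nonamphibian(self) -> frozenset:
        return self.amniotes

    @property
    def universe(self) -> frozenset:
        return self.amphibians | self.fish | self.amniotes

    def validate_against(self, species: Iterable[str]) -> None:
        unknown = self.universe - set(species)
        if unknown:
            raise ValueError(
                f"clade species missing from the count table: {sorted(unknown)}"
            )


def read_genecount_tsv(path) -> pd.DataFrame:
    """Read an OrthoFinder-style GeneCount TSV.

    First column: orthogroup id.  One column per species.  A trailing
    ``Total`` column is tolerated and dropped.  Counts must be non-negative
    integers.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "Total" in table.columns:
        table = table.drop(columns="Total")
    table = table.astype(int)
    if (table.values < 0).any():
        raise ValueError("gene counts must be non-negative")
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ValueError(f"duplicate orthogroup ids: {dupes}")
    return table


def _n_present(present: frozenset, group: frozenset) -> int:
    return len(present & group)


def classify_orthogroups(table: pd.DataFrame, clades: CladeSpec) -> pd.Series:
    """Label every orthogroup with exactly one phylostratigraphic class.

    Returns a Series indexed like ``table`` with values from
    :data:`CLASS_LABELS`.
    """
    clades.validate_against(table.columns)
    if (table.values < 0).any():
        raise ValueError("gene counts must be non-negative")

    labels = {}
    caecs = clades.caecilians
    for og, row in table.iterrows():
        present = frozenset(sp for sp, n in row.items() if n >= 1)
        has_caec = bool(present & caecs)
        if has_caec:
            labels[og] = (
                "caecilian_present" if present - caecs else "caecilian_gain"
            )
            continue
        # caecilian-absent: filters 1 -> 2 -> 3, first match wins
        if (
            not (present & clades.amphibians)
            and _n_present(present, clades.fish) >= 2
            and _n_present(present, clades.tetrapods_nonamphibian) >= 2
        ):
            labels[og] = "loss_all_amphibia"
        elif (
            _n_present(present, clades.fish) >= 2
            and _n_present(present, clades.tetrapods_noncaecilian) >= 2
            and _n_present(present, clades.frogs) >= 1
        ):
            labels[og] = "loss_caecilian_only"
        elif (
            _n_present(present, clades.frogs) >= 2
            and _n_present(present, clades.amniotes) >= 2
        ):
            labels[og] = "loss_caecilian_amphibia_amniota_present"
        else:
            labels[og] = "set_aside"
    return pd.Series(labels, index=table.index, name="class", dtype=object)


def analysis_set(partition: pd.Series) -> set:
    """Orthogroups carried into downstream analyses: all but ``set_aside``."""
    return set(partition.index[partition != "set_aside"])


def summarize_partition(partition: pd.Series) -> pd.Series:
    """Per-class counts in a fixed, deterministic order; sums to the table size."""
    counts = partition.value_counts()
    return pd.Series(
        [int(counts.get(label, 0)) for label in CLASS_LABELS],
        index=list(CLASS_LABELS),
        name="n_orthogroups",
    )
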