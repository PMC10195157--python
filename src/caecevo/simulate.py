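"""Seeded generators for every input the pipeline consumes.

Each generator is a bit-reproducible function of (parameters, seed).  One
top-level seed is split hierarchically per component through a fixed
component-index table, so adding a generator never shifts the draws of an
existing one.  Truth tables are emitted beside the data; tests read truth,
never regenerate it.

The default species tree is a 12-taxon time-scaled vertebrate phylogeny
(2 fish, 2 frogs, 3 caecilians, 5 amniotes; depths in million years,
caecilian crown ~125 Mya, root ~430 Mya) emulating the comparative panels
used for amphibian genomics.  Default rates: gene-family turnover
lambda = 0.002 per gene per million years with Poisson root mean 2.0;
codon simulations use kappa = 2.5 and, for positive-selection scenarios,
a foreground omega2 = 5 carried by 15% of sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from caecevo import famdyn
from caecevo.codon import (
    CODONS,
    BranchPartition,
    CodonAlignment,
    SiteClassModel,
    transition_matrix_factory,
    uniform_frequencies,
)
from caecevo.enhancer import AnnotatedGenome, revcomp
from caecevo.phylostrat import CLASS_LABELS, CladeSpec
from caecevo.trees import PhyloTree, parse_newick, rf_distance

__all__ = [
    "component_rng",
    "default_species_tree",
    "default_clades",
    "default_codon_tree",
    "simulate_counts",
    "simulate_codon_alignment",
    "perturb_alignment",
    "simulate_gene_trees",
    "simulate_enhancer_panel",
    "simulate_orthogroup_presence",
]

# fixed component indices for hierarchical seed splitting; append-only
_COMPONENTS = {
    "counts": 0,
    "codon": 1,
    "perturb": 2,
    "gene_trees": 3,
    "enhancer": 4,
    "presence": 5,
    "pipeline": 6,
    "selection": 7,
}


def component_rng(seed: int, component: str, index: int = 0) -> np.random.Generator:
    """Independent generator for one component of a simulation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_COMPONENTS[component], index))
    )


_SPECIES_TREE_NEWICK = (
    "((Dan_rer:380,Lep_ocu:380):50,"
    "(((Rhi_biv:125,(Geo_ser:65,Mic_uni:65):60):175,"
    "(Xen_tro:200,Ran_tem:200):100):52,"
    "((Hom_sap:90,Mus_mus:90):222,"
    "(Pyt_biv:280,(Gal_gal:100,Ana_pla:100):180):32):40):78);"
)

CAECILIANS = ("Rhi_biv", "Geo_ser", "Mic_uni")
FROGS = ("Xen_tro", "Ran_tem")
FISH = ("Dan_rer", "Lep_ocu")
AMNIOTES = ("Hom_sap", "Mus_mus", "Pyt_biv", "Gal_gal", "Ana_pla")


def default_species_tree() -> PhyloTree:
    """The 12-taxon time-scaled vertebrate tree used across the pipeline."""
    return parse_newick(_SPECIES_TREE_NEWICK)


def default_clades() -> CladeSpec:
    return CladeSpec(
        caecilians=CAECILIANS, frogs=FROGS, fish=FISH, amniotes=AMNIOTES
    )


_CODON_TREE_NEWICK = (
    "(((Rhi_biv:0.08,(Geo_ser:0.05,Mic_uni:0.05):0.04):0.10,"
    "(Xen_tro:0.12,Ran_tem:0.12):0.08):0.04,"
    "((Hom_sap:0.10,Mus_mus:0.10):0.08,(Gal_gal:0.09,Pyt_biv:0.09):0.07):0.05);"
)


def default_codon_tree() -> PhyloTree:
    """8-taxon substitution-scaled tree for codon-model simulations."""
    return parse_newick(_CODON_TREE_NEWICK)


def default_foreground(tree: Optional[PhyloTree] = None) -> BranchPartition:
    """Stem of the caecilian clade plus its internal/terminal branches."""
    tree = tree or default_codon_tree()
    return BranchPartition.from_clade(tree, CAECILIANS, mode="stem+clade")


# ---------------------------------------------------------------------------
# gene-family counts
# ---------------------------------------------------------------------------


def simulate_counts(
    tree: PhyloTree,
    *,
    lambda_: float = 0.002,
    root_prior_mean: float = 2.0,
    n_families: int = 500,
    seed: int = 0,
    max_count: Optional[int] = None,
) -> pd.DataFrame:
    """Evolve family sizes down the tree under the birth-death kernel.

    Root counts are Poisson draws; each branch applies the equal-rate
    birth-death transition.  Returns an orthogroup x species count table.
    """
    rng = component_rng(seed, "counts")
    m = max_count if max_count is not None else int(root_prior_mean * 6 + 40)
    model = famdyn.FamilyRateModel(lambda_, root_prior_mean, m)
    tips, labels = famdyn._simulate_profiles(tree, model, n_families, rng)
    index = [f"OG{i:07d}" for i in range(n_families)]
    return pd.DataFrame(tips, index=index, columns=labels)


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


def simulate_codon_alignment(
    tree: PhyloTree,
    model: SiteClassModel,
    partition: Optional[BranchPartition] = None,
    *,
    n_codons: int = 300,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> CodonAlignment:
    """Evolve a codon alignment under the site-class mixture.

    Per site a class is drawn from the model's proportions, the root codon
    from pi, and each branch applies the class- and partition-specific
    transition matrix.
    """
    rng = rng if rng is not None else component_rng(seed, "codon")
    classes = model.site_classes()
    props = np.array([c[0] for c in classes])
    props = props / props.sum()
    Pfun = transition_matrix_factory(model)

    nodes = list(tree.postorder())
    below: dict[int, frozenset] = {}
    for node in nodes:
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.child_nodes()))

    site_class = rng.choice(len(classes), size=n_codons, p=props)
    root_state = rng.choice(len(CODONS), size=n_codons, p=model.pi)
    states: dict[int, np.ndarray] = {id(nodes[-1]): root_state}
    leaf_states: dict[str, np.ndarray] = {}
    for node in reversed(nodes):  # preorder: root first
        if id(node) not in states:
            continue
        parent_state = states[id(node)]
        for child in node.child_nodes():
            fg = partition.is_foreground(below[id(child)]) if partition else False
            child_state = np.empty(n_codons, dtype=int)
            for ci, (_, w_bg, w_fg) in enumerate(classes):
                mask = site_class == ci
                if not mask.any():
                    continue
                P = Pfun(w_fg if fg else w_bg, child.edge.length)
                rows = P[parent_state[mask]]
                rows = rows / rows.sum(axis=1, keepdims=True)
                u = rng.random(mask.sum())
                child_state[mask] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
            states[id(child)] = child_state
            if child.is_leaf():
                leaf_states[child.taxon.label] = child_state
    ids = sorted(leaf_states)
    codes = np.stack([leaf_states[i] for i in ids])
    return CodonAlignment(ids, codes)


# ---------------------------------------------------------------------------
# alignment perturbation
# ---------------------------------------------------------------------------


def perturb_alignment(alignment: Mapping[str, str], rate: float, seed: int = 0) -> dict:
    """Randomly shift gap placements, leaving the ungapped sequences untouched.

    Each move slides one gap character a short random distance within its
    row, misaligning the residues it passes over.  The number of moves is
    calibrated so the fraction of homology statements disturbed is roughly
    ``rate`` (a shift of d columns in one row of an n-sequence alignment
    disturbs about d*(n-1) of the ~L*n*(n-1)/2 statements).
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = component_rng(seed, "perturb")
    rows = {i: list(s) for i, s in alignment.items()}
    length = len(next(iter(rows.values())))
    gapped_rows = [i for i, s in rows.items() if "-" in s]
    if not gapped_rows or rate == 0:
        return {i: "".join(s) for i, s in rows.items()}

    from caecevo.selection import homology_pairs

    base = homology_pairs(alignment)

    def distance() -> float:
        cur = homology_pairs({i: "".join(s) for i, s in rows.items()})
        denom = len(base) + len(cur)
        return len(base ^ cur) / denom if denom else 0.0

    batch = max(1, length // 50)
    for _ in range(500):
        if distance() >= rate:
            break
        for _ in range(batch):
            rid = gapped_rows[rng.integers(len(gapped_rows))]
            row = rows[rid]
            gaps = [k for k, ch in enumerate(row) if ch == "-"]
            src = gaps[rng.integers(len(gaps))]
            shift = int(1 + rng.geometric(0.5)) * (1 if rng.random() < 0.5 else -1)
            dst = int(np.clip(src + shift, 0, length - 1))
            ch = row.pop(src)
            row.insert(dst, ch)
    return {i: "".join(s) for i, s in rows.items()}


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------


def _random_nni(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    """Apply one nearest-neighbour interchange; retries until topology moves."""
    for _ in range(50):
        t = tree.copy()
        internal = [
            n
            for n in t.postorder()
            if not n.is_leaf() and n.parent_node is not None
        ]
        if not internal:
            raise ValueError("tree too small for NNI")
        node = internal[rng.integers(len(internal))]
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        if not siblings:
            continue
        sib = siblings[rng.integers(len(siblings))]
        kids = node.child_nodes()
        kid = kids[rng.integers(len(kids))]
        parent.remove_child(sib)
        node.remove_child(kid)
        node.add_child(sib)
        parent.add_child(kid)
        t2 = parse_newick(t.to_newick())
        if rf_distance(t2, tree) > 0:
            return t2
    raise RuntimeError("failed to produce a discordant NNI neighbour")


def simulate_gene_trees(
    species_tree: PhyloTree,
    n: int,
    discordant_fraction: float,
    seed: int = 0,
) -> tuple[list, list]:
    """Concordant copies of the species tree plus NNI-discordant decoys.

    Returns ``(trees, truth)`` where truth[i] is True for discordant trees.
    """
    rng = component_rng(seed, "gene_trees")
    trees, truth = [], []
    for _ in range(n):
        discordant = bool(rng.random() < discordant_fraction)
        if discordant:
            trees.append(_random_nni(species_tree, rng))
        else:
            trees.append(parse_newick(species_tree.to_newick()))
        truth.append(discordant)
    return trees, truth


# ---------------------------------------------------------------------------
# enhancer panel
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for k in range(len(out)):
        if rng.random() < rate:
            choices = [c for c in "ACGT" if c != out[k]]
            out[k] = choices[rng.integers(3)]
    return "".join(out)


@dataclass
class EnhancerSpeciesSpec:
    """Per-species treatment of the planted enhancer."""

    mutation_rate: float = 0.0
    deleted: bool = False
    relocated: bool = False
    minus_strand_gene: bool = False


def simulate_enhancer_panel(
    species: Mapping[str, EnhancerSpeciesSpec],
    *,
    enhancer_length: int = 800,
    control_length: int = 500,
    exon_length: int = 150,
    intron_length: int = 600,
    n_exons: int = 8,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame, dict]:
    """Toy annotated genomes with a planted limb-enhancer-like element.

    Each genome carries an LMBR1-like gene (``n_exons`` exons) whose intron
    between exons 5 and 6 contains the enhancer — mutated, excised, or
    relocated to a second contig per the species spec — plus a DLX1/DLX2-like
    gene pair whose intergenic window holds an always-intact control
    element.  Returns ``(panel, truth_table, queries)`` where queries holds
    the master ``zrs``-like and ``i12a``-like sequences.
    """
    master_rng = component_rng(seed, "enhancer", 0)
    # master elements shared by the whole panel; ETS-like core planted inside
    core = "TGGAAGTG"
    enh = _random_seq(master_rng, enhancer_length)
    mid = enhancer_length // 2
    enhancer = enh[:mid] + core + enh[mid + len(core):]
    control = _random_seq(master_rng, control_length)

    panel: dict[str, AnnotatedGenome] = {}
    truth_rows = []
    for idx, name in enumerate(sorted(species)):
        spec = species[name]
        rng = component_rng(seed, "enhancer", idx + 1)
        if spec.deleted:
            planted = ""
        elif spec.mutation_rate > 0:
            planted = _mutate(enhancer, spec.mutation_rate, rng)
        else:
            planted = enhancer

        big_intron = 5  # intron between exons 5 and 6 hosts the element
        segments = [_random_seq(rng, 500)]  # 5' flank
        features = []
        pos = len(segments[0])
        exon_coords = []
        for e in range(n_exons):
            exon_coords.append((pos, pos + exon_length))
            segments.append(_random_seq(rng, exon_length))
            pos += exon_length
            if e < n_exons - 1:
                if e + 1 == big_intron and planted and not spec.relocated:
                    pad = intron_length // 2
                    intron = (
                        _random_seq(rng, pad) + planted + _random_seq(rng, pad)
                    )
                else:
                    intron = _random_seq(rng, intron_length)
                segments.append(intron)
                pos += len(intron)
        gene_start, gene_end = exon_coords[0][0], exon_coords[-1][1]
        segments.append(_random_seq(rng, 400))  # 3' flank
        pos += 400

        # DLX-like pair with the control element between them
        dlx1 = (pos, pos + 300)
        segments.append(_random_seq(rng, 300))
        pos += 300
        inter = _random_seq(rng, 150) + control + _random_seq(rng, 150)
        segments.append(inter)
        pos += len(inter)
        dlx2 = (pos, pos + 300)
        segments.append(_random_seq(rng, 300))
        pos += 300
        segments.append(_random_seq(rng, 200))
        contig1 = "".join(segments)

        strand = "-" if spec.minus_strand_gene else "+"
        if strand == "-":
            # realise the whole arrangement on the minus strand
            L = len(contig1)
            contig1 = revcomp(contig1)
            flip = lambda s, e: (L - e, L - s)
            exon_coords = [flip(s, e) for s, e in exon_coords][::1]
            gene_start, gene_end = flip(gene_start, gene_end)
            dlx1, dlx2 = flip(*dlx1), flip(*dlx2)

        contigs = {"chr1": contig1}
        if spec.relocated and planted:
            c2 = _random_seq(rng, 1500) + planted + _random_seq(rng, 1500)
            contigs["chr2"] = c2
        else:
            contigs["chr2"] = _random_seq(rng, 2000)

        gff = ["##gff-version 3"]

        def feat(contig, kind, s0, e0, fid, parent=None, st="+"):
            attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
            gff.append(
                f"{contig}\t{'sim'}\t{kind}\t{s0 + 1}\t{e0}\t.\t{st}\t.\t{attrs}"
            )

        feat("chr1", "gene", gene_start, gene_end, "LMBR1", st=strand)
        feat("chr1", "mRNA", gene_start, gene_end, "LMBR1.t1", "LMBR1", strand)
        for k, (s0, e0) in enumerate(exon_coords):
            feat("chr1", "exon", s0, e0, f"LMBR1.e{k + 1}", "LMBR1.t1", strand)
        feat("chr1", "gene", dlx1[0], dlx1[1], "DLX1", st=strand)
        feat("chr1", "gene", dlx2[0], dlx2[1], "DLX2", st=strand)
        panel[name] = AnnotatedGenome(contigs, "\n".join(gff) + "\n")
        truth_rows.append(
            {
                "species": name,
                "planted": bool(planted),
                "mutation_rate": spec.mutation_rate,
                "deleted": spec.deleted,
                "relocated": spec.relocated,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("species")
    queries = {"zrs": enhancer, "i12a": control, "ets_core": core}
    return panel, truth, queries


# ---------------------------------------------------------------------------
# orthogroup presence patterns
# ---------------------------------------------------------------------------


def _rule_predicates(present: frozenset, clades: CladeSpec) -> dict:
    """Direct transcription of the presence filters (independent of the
    classifier implementation, for planted-truth generation)."""
    caec = bool(present & clades.caecilians)
    fish2 = len(present & clades.fish) >= 2
    f1 = (
        not (present & (clades.caecilians | clades.frogs | clades.salamanders))
        and fish2
        and len(present & clades.amniotes) >= 2
    )
    tetra = clades.frogs | clades.salamanders | clades.amniotes
    f2 = fish2 and len(present & tetra) >= 2 and len(present & clades.frogs) >= 1
    f3 = len(present & clades.frogs) >= 2 and len(present & clades.amniotes) >= 2
    return {
        "caecilian_present": caec and bool(present - clades.caecilians),
        "caecilian_gain": caec and not (present - clades.caecilians),
        "loss_all_amphibia": not caec and f1,
        "loss_caecilian_only": not caec and not f1 and f2,
        "loss_caecilian_amphibia_amniota_present": not caec and not f1 and not f2 and f3,
        "set_aside": bool(present) and not caec and not f1 and not f2 and not f3,
    }


def simulate_orthogroup_presence(
    class_counts: Mapping[str, int],
    clades: CladeSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Count table with planted phylostratigraphic class labels.

    Presence patterns are drawn uniformly (by rejection) from the patterns
    satisfying exactly the target class's rule; present species get
    1 + Poisson(0.5) gene copies.  Returns ``(table, truth_labels)``.
    """
    unknown = set(class_counts) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    rng = component_rng(seed, "presence")
    universe = sorted(clades.universe)
    rows, labels, ids = [], [], []
    og = 0
    for label in CLASS_LABELS:  # fixed order for determinism
        for _ in range(int(class_counts.get(label, 0))):
            for attempt in range(20000):
                mask = rng.random(len(universe)) < 0.5
                present = frozenset(sp for sp, m in zip(universe, mask) if m)
                if _rule_predicates(present, clades)[label]:
                    break
            else:
                raise RuntimeError(f"could not sample a pattern for {label!r}")
            counts = {
                sp: (1 + rng.poisson(0.5)) if sp in present else 0 for sp in universe
            }
            rows.append(counts)
            labels.append(label)
            ids.append(f"OG{og:07d}")
            og += 1
    table = pd.DataFrame(rows, index=ids, columns=universe).fillna(0).astype(int)
    truth = pd.Series(labels, index=ids, name="class")
    return table, truth
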