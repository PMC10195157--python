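"""Positive-selection scan: filters, branch-site model fits, and LRTs.

The scan funnels candidate gene families through the published criteria
before any model is fitted: multi-copy families are decomposed into
single-copy groups, competing alignments of the same sequences are compared
and one is selected, gene trees must agree exactly (Robinson-Foulds
distance 0) with the species tree restricted to their taxa, and at least
seven species must remain.  Surviving families are fitted with the nested
M1Neutral / ModelA-null / ModelA codon models on a designated foreground
lineage; lineage-specific positive selection is called when ModelA beats
*both* nulls after Bonferroni correction and the foreground omega exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from caecevo.codon import (
    BranchPartition,
    CodonAlignment,
    SiteClassModel,
    codon_loglik,
    f3x4_frequencies,
    uniform_frequencies,
)
from caecevo.trees import NewickParseError, PhyloTree, restrict, rf_distance

__all__ = [
    "GeneFamily",
    "SelectionResult",
    "decompose_to_sgo",
    "homology_pairs",
    "alignment_distance",
    "alignment_quality_score",
    "select_alignment",
    "concordance_and_size_filter",
    "BranchSiteCodonModel",
    "CodonModelResults",
    "fit_model",
    "lrt",
    "call_selection",
    "branch_site_test",
]

GAP_CHARS = set("-.")


@dataclass
class GeneFamily:
    """One orthogroup: genes, their source species, and an optional gene tree."""

    orthogroup: str
    genes: dict  # gene id -> species id
    tree: Optional[PhyloTree] = None
    sequences: Optional[dict] = None  # gene id -> CDS string

    def copy_counts(self) -> dict:
        counts: dict[str, int] = {}
        for sp in self.genes.values():
            counts[sp] = counts.get(sp, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# single-copy decomposition
# ---------------------------------------------------------------------------


def decompose_to_sgo(
    family: GeneFamily,
    *,
    caecilians: Iterable[str] = (),
) -> list[dict]:
    """Split a family into single-copy gene sets (gene id -> species).

    Already single-copy families pass through unchanged.  A species-specific
    duplication — duplicates confined to exactly one species and, when a
    gene tree is available, monophyletic on it — drops that species and the
    rest form one group (species-specific duplications not specific to
    caecilians are discarded with it).  Any deeper paralogy cuts the gene
    tree into maximal clades whose leaves contain each species at most
    once, largest-clade-first.
    """
    caecilians = set(caecilians)
    counts = family.copy_counts()
    dup_species = {sp for sp, n in counts.items() if n > 1}
    if not dup_species:
        return [dict(family.genes)]
    if len(dup_species) == 1:
        (sp,) = dup_species
        dup_genes = {g for g, s in family.genes.items() if s == sp}
        monophyletic = True
        if family.tree is not None:
            clades = set()
            for node in family.tree.postorder():
                if node.is_leaf():
                    clades.add(frozenset([node.taxon.label]))
                else:
                    clades.add(
                        frozenset().union(
                            *(
                                frozenset([l.taxon.label])
                                for l in node.leaf_iter()
                            )
                        )
                    )
            monophyletic = frozenset(dup_genes) in clades
        if monophyletic:
            kept = {g: s for g, s in family.genes.items() if s != sp}
            return [kept] if kept else []
    if family.tree is None:
        raise ValueError(
            f"family {family.orthogroup}: gene tree required to decompose "
            f"multi-species duplications"
        )
    unmapped = family.tree.leaf_labels - set(family.genes)
    if unmapped:
        raise ValueError(f"gene-tree leaves missing from the family: {sorted(unmapped)}")

    groups: list[dict] = []

    def species_of(leafset):
        return [family.genes[g] for g in leafset]

    def walk(node, below):
        leaves = below[id(node)]
        spp = species_of(leaves)
        if len(spp) == len(set(spp)):
            groups.append({g: family.genes[g] for g in leaves})
            return
        for child in node.child_nodes():
            walk(child, below)

    below: dict[int, frozenset] = {}
    for node in family.tree.postorder():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
    walk(family.tree.root, below)
    # drop non-caecilian species-specific leftovers (singleton groups from
    # duplicated species), keep deterministic largest-first order
    groups = [
        g
        for g in groups
        if len(g) > 1 or set(g.values()) <= caecilians
    ]
    groups.sort(key=lambda g: (-len(g), tuple(sorted(g))))
    return groups


# ---------------------------------------------------------------------------
# alignment comparison and selection
# ---------------------------------------------------------------------------


def _rows(alignment: Mapping[str, str]) -> tuple[list, list, int]:
    ids = list(alignment)
    seqs = [alignment[i] for i in ids]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    return ids, seqs, lengths.pop()


def homology_pairs(alignment: Mapping[str, str]) -> set:
    """Alignment-coordinate-free homology statements.

    For every column and unordered sequence pair: a residue~residue
    statement ``("res", (idA, ordA), (idB, ordB))`` when both are ungapped,
    or a residue~gap statement ``("gap", (id, ord), partner_id)`` when
    exactly one is.  Ordinals are 1-based positions in the ungapped
    sequence, so the statements are invariant to all-gap column padding.
    """
    ids, seqs, length = _rows(alignment)
    ordinals = [0] * len(ids)
    statements: set = set()
    for col in range(length):
        residues = []
        for r in range(len(ids)):
            ch = seqs[r][col]
            if ch not in GAP_CHARS:
                ordinals[r] += 1
                residues.append((r, ordinals[r]))
            else:
                residues.append((r, None))
        for a in range(len(ids)):
            ra, oa = residues[a]
            for b in range(a + 1, len(ids)):
                rb, ob = residues[b]
                if oa is not None and ob is not None:
                    key_a, key_b = (ids[a], oa), (ids[b], ob)
                    if key_a > key_b:
                        key_a, key_b = key_b, key_a
                    statements.add(("res", key_a, key_b))
                elif oa is not None:
                    statements.add(("gap", (ids[a], oa), ids[b]))
                elif ob is not None:
                    statements.add(("gap", (ids[b], ob), ids[a]))
    return statements


def _ungapped(alignment: Mapping[str, str]) -> dict:
    return {
        i: "".join(ch for ch in s if ch not in GAP_CHARS)
        for i, s in alignment.items()
    }


def alignment_distance(a1: Mapping[str, str], a2: Mapping[str, str]) -> float:
    """Symmetric-difference distance between two alignments' homology sets.

    d = |H1 xor H2| / (|H1| + |H2|), in [0, 1]; zero iff the alignments
    assert identical homologies.  Both alignments must contain the same
    sequences (same ids, same ungapped residues).
    """
    if set(a1) != set(a2):
        raise ValueError("alignments cover different sequence ids")
    u1, u2 = _ungapped(a1), _ungapped(a2)
    if u1 != u2:
        diff = sorted(i for i in u1 if u1[i] != u2[i])
        raise ValueError(f"underlying sequences differ for ids: {diff}")
    h1, h2 = homology_pairs(a1), homology_pairs(a2)
    denom = len(h1) + len(h2)
    if denom == 0:
        return 0.0
    return len(h1 ^ h2) / denom


_BLOSUM = None


def _blosum_similarity():
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        lo, hi = min(mat.values()), max(mat.values())
        _BLOSUM = {
            (a, b): (mat[a, b] - lo) / (hi - lo)
            for a in mat.alphabet
            for b in mat.alphabet
        }
    return _BLOSUM


def alignment_quality_score(alignment: Mapping[str, str], *, alphabet: str = "auto") -> float:
    """Normalised mean-of-pairs column score in [0, 1].

    Per column the mean pairwise similarity over ungapped pairs (identity
    for nucleotides; BLOSUM62 linearly rescaled to [0, 1] for amino acids),
    averaged over columns weighted by the number of ungapped pairs.
    """
    ids, seqs, length = _rows(alignment)
    if len(ids) < 2:
        raise ValueError("quality score needs >= 2 sequences")
    if alphabet == "auto":
        letters = {ch for s in seqs for ch in s.upper()} - GAP_CHARS
        alphabet = "nt" if letters <= set("ACGTUN") else "aa"
    sim = None if alphabet == "nt" else _blosum_similarity()
    total, pairs = 0.0, 0
    for col in range(length):
        residues = [s[col].upper() for s in seqs if s[col] not in GAP_CHARS]
        for a in range(len(residues)):
            for b in range(a + 1, len(residues)):
                pairs += 1
                if alphabet == "nt":
                    total += 1.0 if residues[a] == residues[b] else 0.0
                else:
                    total += sim.get((residues[a], residues[b]), 0.0)
    if pairs == 0:
        return 0.0
    return total / pairs


def select_alignment(
    candidates: Sequence[Mapping[str, str]],
    *,
    threshold: float = 0.05,
    metric: str = "max",
) -> tuple[int, dict]:
    """Pick one alignment from a candidate ensemble.

    If the candidates disagree by at least ``threshold`` (5% by default,
    measured as the max — or mean — pairwise :func:`alignment_distance`),
    the candidate with the highest quality score wins (ties: first in input
    order).  Below the threshold the first candidate is kept as the
    consensus.  Returns ``(index, decision_record)``.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if len(candidates) == 1:
        return 0, {"reason": "single_candidate", "distance": 0.0}
    dists = [
        alignment_distance(candidates[i], candidates[j])
        for i in range(len(candidates))
        for j in range(i + 1, len(candidates))
    ]
    spread = max(dists) if metric == "max" else float(np.mean(dists))
    if spread < threshold:
        return 0, {"reason": "below_threshold", "distance": spread}
    scores = [alignment_quality_score(c) for c in candidates]
    best = int(np.argmax(scores))  # argmax keeps the first of tied maxima
    return best, {
        "reason": "highest_quality_score",
        "distance": spread,
        "scores": scores,
    }


# ---------------------------------------------------------------------------
# concordance filter
# ---------------------------------------------------------------------------


def concordance_and_size_filter(
    gene_to_species: Mapping[str, str],
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    *,
    min_taxa: int = 7,
) -> tuple[bool, str]:
    """Retain a family only if its gene tree matches the species tree exactly.

    The gene tree's leaves are relabelled to species, the species tree is
    restricted to those species, and the family passes iff the
    Robinson-Foulds distance is zero and at least ``min_taxa`` species
    remain.  Returns ``(passed, reason)``.
    """
    unmapped = gene_tree.leaf_labels - set(gene_to_species)
    if unmapped:
        raise ValueError(f"unmapped genes: {sorted(unmapped)}")
    species = [gene_to_species[g] for g in gene_tree.leaf_labels]
    if len(species) != len(set(species)):
        return False, "duplicate_species"
    if len(species) < min_taxa:
        return False, f"min_taxa({len(species)}<{min_taxa})"
    relabelled = gene_tree.copy()
    for leaf in relabelled.dtree.leaf_node_iter():
        leaf.taxon.label = gene_to_species[leaf.taxon.label]
    try:
        pruned = restrict(species_tree, set(species))
    except ValueError as exc:
        raise ValueError(f"species missing from species tree: {exc}") from exc
    d = rf_distance(relabelled, pruned)
    if d != 0:
        return False, f"RF={d}"
    return True, "pass"


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

_SIG = lambda x: 1.0 / (1.0 + np.exp(-x))
_LOGIT = lambda p: float(np.log(p / (1.0 - p)))
_EPS = 1e-4


def _x_to_model(x: np.ndarray, variant: str, pi: np.ndarray, omega0: float) -> SiteClassModel:
    if variant == "M1Neutral":
        logk, a, logs = x
        return SiteClassModel(
            "M1Neutral", float(np.exp(logk)), pi, float(_SIG(a)),
            tree_scale=float(np.exp(logs)), omega0=omega0,
        )
    logk, a, b, u, logs = x
    p0 = float(_SIG(a))
    p1 = float((1.0 - p0) * _SIG(b))
    if variant == "ModelA":
        omega2 = float(1.0 + np.exp(u))
    else:
        omega2 = float(_SIG(u))
    return SiteClassModel(
        variant, float(np.exp(logk)), pi, p0, p1=p1, omega2=omega2,
        tree_scale=float(np.exp(logs)), omega0=omega0,
    )


def _model_to_x(m: SiteClassModel, variant: str) -> np.ndarray:
    clip = lambda p: min(max(p, _EPS), 1.0 - _EPS)
    if variant == "M1Neutral":
        return np.array([np.log(m.kappa), _LOGIT(clip(m.p0)), np.log(m.tree_scale)])
    p0 = clip(m.p0)
    b = clip(m.p1 / max(1.0 - p0, _EPS))
    if variant == "ModelA":
        u = float(np.log(max(m.omega2 - 1.0, _EPS)))
    else:
        u = _LOGIT(clip(m.omega2))
    return np.array([np.log(m.kappa), _LOGIT(p0), _LOGIT(b), u, np.log(m.tree_scale)])


_BOUNDS = {
    "logk": (np.log(0.05), np.log(30.0)),
    "logit": (-9.0, 9.0),
    "uA": (np.log(1e-3), np.log(49.0)),
    "logs": (np.log(1e-3), np.log(1e3)),
}


def _bounds_for(variant: str):
    if variant == "M1Neutral":
        return [_BOUNDS["logk"], _BOUNDS["logit"], _BOUNDS["logs"]]
    u = _BOUNDS["uA"] if variant == "ModelA" else _BOUNDS["logit"]
    return [_BOUNDS["logk"], _BOUNDS["logit"], _BOUNDS["logit"], u, _BOUNDS["logs"]]


class BranchSiteCodonModel:
    """A site-class codon model to be fitted to one family's alignment.

    Parameters
    ----------
    alignment : CodonAlignment
    tree : PhyloTree
        Substitution-scaled tree whose leaves equal the alignment ids; by
        default only a single global scale on the input branch lengths is
        re-estimated.
    partition : BranchPartition or None
        Foreground lineage; required for ModelA / ModelAnull.
    variant : {"M1Neutral", "ModelA", "ModelAnull"}
    pi_mode : {"f3x4", "uniform"}
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        partition: Optional[BranchPartition] = None,
        *,
        variant: str = "ModelA",
        pi_mode: str = "f3x4",
        omega0: float = 0.0,
    ):
        if variant not in ("M1Neutral", "ModelA", "ModelAnull"):
            raise ValueError(f"unknown variant {variant!r}")
        if variant != "M1Neutral" and partition is None:
            raise ValueError(f"{variant} requires a branch partition")
        self.alignment = alignment
        self.tree = tree
        self.partition = partition if variant != "M1Neutral" else partition
        self.variant = variant
        self.omega0 = float(omega0)
        if pi_mode == "f3x4":
            self.pi = f3x4_frequencies(alignment)
        elif pi_mode == "uniform":
            self.pi = uniform_frequencies()
        else:
            raise ValueError(f"unknown pi_mode {pi_mode!r}")

    def loglik(self, model: SiteClassModel) -> float:
        return codon_loglik(self.alignment, self.tree, model, self.partition)

    def _default_start(self) -> SiteClassModel:
        if self.variant == "M1Neutral":
            return SiteClassModel("M1Neutral", 2.0, self.pi, 0.5, omega0=self.omega0)
        omega2 = 2.0 if self.variant == "ModelA" else 0.5
        return SiteClassModel(
            self.variant, 2.0, self.pi, 0.45, p1=0.45, omega2=omega2, omega0=self.omega0
        )

    def fit(
        self,
        *,
        starts: Optional[Sequence[SiteClassModel]] = None,
        maxiter: int = 200,
    ) -> "CodonModelResults":
        """Bounded quasi-Newton ML fit from one or more starts (best kept)."""
        if starts is None:
            starts = [self._default_start()]

        def nll(x):
            try:
                m = _x_to_model(x, self.variant, self.pi, self.omega0)
            except ValueError:
                return 1e12
            return -self.loglik(m)

        best = None
        nfev = 0
        for start in starts:
            x0 = _model_to_x(start, self.variant)
            res = optimize.minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=_bounds_for(self.variant),
                options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
            )
            nfev += int(res.nfev)
            if best is None or res.fun < best.fun:
                best = res
        fitted = _x_to_model(best.x, self.variant, self.pi, self.omega0)
        return CodonModelResults(
            self, fitted, -float(best.fun), nfev=nfev, converged=bool(best.success)
        )


class CodonModelResults:
    """Fitted codon model: parameter estimates and log-likelihood."""

    def __init__(self, model: BranchSiteCodonModel, params: SiteClassModel, llf: float, *, nfev: int, converged: bool):
        self.model = model
        self.params = params
        self.llf = llf
        self.nfev = nfev
        self.converged = converged

    @property
    def kappa(self) -> float:
        return self.params.kappa

    @property
    def omega2(self) -> Optional[float]:
        return self.params.omega2

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Codon site-class model: {p.name}",
            "=" * 44,
            f"sequences            {len(self.model.alignment):>12d}",
            f"codon sites          {self.model.alignment.n_sites:>12d}",
            f"kappa (ts/tv)        {p.kappa:>12.4f}",
            f"tree scale           {p.tree_scale:>12.4f}",
            f"log-likelihood       {self.llf:>12.4f}",
        ]
        for i, (prop, wb, wf) in enumerate(p.site_classes()):
            lines.append(
                f"class {i}: p={prop:.4f}  omega(bg)={wb:.4f}  omega(fg)={wf:.4f}"
            )
        return "\n".join(lines)


def fit_model(
    alignment: CodonAlignment,
    tree: PhyloTree,
    variant: str,
    partition: Optional[BranchPartition] = None,
    **kwargs,
) -> CodonModelResults:
    """Functional wrapper over :class:`BranchSiteCodonModel`."""
    return BranchSiteCodonModel(
        alignment, tree, partition, variant=variant, **kwargs
    ).fit()


def lrt(lnl_alt: float, lnl_null: float, df: int) -> float:
    """Upper-tail chi-square p-value at 2*(lnL_alt - lnL_null), clamped at 0."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return float(stats.chi2.sf(stat, df))


@dataclass
class SelectionResult:
    """Per-family, per-lineage outcome of the branch-site test."""

    orthogroup: str
    lineage: str
    lnl_m1: float
    lnl_null: float
    lnl_alt: float
    p_vs_m1: float
    p_vs_null: float
    omega2: float
    kappa: float
    selected: Optional[bool] = None
    p_adjusted: Optional[float] = None

    @property
    def p_max(self) -> float:
        return max(self.p_vs_m1, self.p_vs_null)


def branch_site_test(
    alignment: CodonAlignment,
    tree: PhyloTree,
    partition: BranchPartition,
    *,
    orthogroup: str = "",
    lineage: str = "",
    pi_mode: str = "f3x4",
    omega0: float = 0.0,
) -> SelectionResult:
    """Fit the nested model chain and compute both LRTs for one family.

    Models are fitted in nesting order (M1Neutral, ModelAnull, ModelA),
    warm-starting each fit from the previous optimum so the fitted
    log-likelihoods respect the nesting up to optimizer tolerance.
    """
    kw = dict(pi_mode=pi_mode, omega0=omega0)
    m1 = BranchSiteCodonModel(alignment, tree, None, variant="M1Neutral", **kw).fit()

    def embed(prev: SiteClassModel, variant: str, omega2: float) -> SiteClassModel:
        p0 = prev.p0 * (1 - 2 * _EPS)
        p1 = (prev.p1 if prev.p1 is not None else 1.0 - prev.p0) * (1 - 2 * _EPS)
        return SiteClassModel(
            variant, prev.kappa, prev.pi, p0, p1=p1, omega2=omega2,
            tree_scale=prev.tree_scale, omega0=omega0,
        )

    null_model = BranchSiteCodonModel(alignment, tree, partition, variant="ModelAnull", **kw)
    null = null_model.fit(starts=[embed(m1.params, "ModelAnull", 0.5)])
    if null.llf < m1.llf - 1e-3:
        retry = null_model.fit(starts=[embed(m1.params, "ModelAnull", 0.999)])
        if retry.llf > null.llf:
            null = retry

    alt_model = BranchSiteCodonModel(alignment, tree, partition, variant="ModelA", **kw)
    w2_start = 2.0 if (null.omega2 or 0) > 0.95 else 1.001
    alt = alt_model.fit(starts=[embed(null.params, "ModelA", max(w2_start, 1.001))])
    if alt.llf < m1.llf - 1e-3:
        retry = alt_model.fit(starts=[embed(m1.params, "ModelA", 1.001)])
        if retry.llf > alt.llf:
            alt = retry

    return SelectionResult(
        orthogroup=orthogroup,
        lineage=lineage,
        lnl_m1=m1.llf,
        lnl_null=null.llf,
        lnl_alt=alt.llf,
        p_vs_m1=lrt(alt.llf, m1.llf, df=2),
        p_vs_null=lrt(alt.llf, null.llf, df=1),
        omega2=float(alt.params.omega2),
        kappa=float(alt.params.kappa),
    )


def call_selection(
    results: Sequence[SelectionResult],
    *,
    alpha: float = 0.05,
    m: Optional[int] = None,
) -> list[SelectionResult]:
    """Bonferroni-corrected positive-selection calls.

    A family is called iff *both* LRT p-values are at most ``alpha / m``
    and the fitted foreground omega exceeds 1.  ``m`` defaults to the
    number of results (families x lineages tested).
    """
    m = len(results) if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    out = []
    for r in results:
        for p in (r.p_vs_m1, r.p_vs_null):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value out of range: {p}")
        adjusted = min(1.0, r.p_max * m)
        r.p_adjusted = adjusted
        r.selected = bool(r.p_max <= alpha / m and r.omega2 > 1.0)
        out.append(r)
    return out
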