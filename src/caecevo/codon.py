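"""Branch-site codon substitution models (GY94-style) and their likelihoods.

The instantaneous rate between sense codons differing at exactly one
nucleotide position is pi_j for a synonymous transversion, kappa*pi_j for a
synonymous transition, and omega-scaled for nonsynonymous changes;
multi-nucleotide changes have rate 0 and rows sum to zero.  The matrix is
scaled so the expected substitution rate equals 1 under the model's
stationary site-class mixture (background omegas), so branch lengths are
expected substitutions per site.

Three nested site-class models are provided:

* ``M1Neutral`` — two classes shared by all branches: omega0 = 0 with
  proportion p0 and omega1 = 1 with proportion 1 - p0.
* ``ModelA`` — adds foreground-specific classes 2a/2b: background omega
  stays 0 or 1 while the designated foreground branches evolve with a free
  omega2 >= 1; the extra proportion p2 = 1 - p0 - p1 is split between 2a
  and 2b proportionally to p0 : p1.
* ``ModelAnull`` — identical to ModelA but with omega2 constrained to
  [0, 1], permitting relaxation but not positive selection.

omega0 is fixed at 0 by default; an estimated-omega0 variant can be had by
passing ``omega0`` explicitly.  Gaps and ambiguity codes are treated as
missing data and marginalised in the pruning pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio.Data import CodonTable
from scipy.special import logsumexp

from caecevo.trees import PhyloTree

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "STOP_CODONS",
    "CodonAlignment",
    "BranchPartition",
    "SiteClassModel",
    "build_rate_matrix",
    "f3x4_frequencies",
    "uniform_frequencies",
    "transition_matrix_factory",
    "codon_loglik",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))
CODONS = tuple(
    sorted(c for c in ("".join((a, b, d)) for a in "ACGT" for b in "ACGT" for d in "ACGT") if c not in STOP_CODONS)
)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_AA = {c: _STANDARD.forward_table[c] for c in CODONS}
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_PI_FLOOR = 1e-6

# precomputed sparse structure of single-nucleotide codon changes
_PAIRS: list[tuple[int, int, bool, bool]] = []
for _i, _ci in enumerate(CODONS):
    for _j, _cj in enumerate(CODONS):
        if _i == _j:
            continue
        diff = [k for k in range(3) if _ci[k] != _cj[k]]
        if len(diff) != 1:
            continue
        k = diff[0]
        is_ts = frozenset((_ci[k], _cj[k])) in _TRANSITIONS
        is_syn = _AA[_ci] == _AA[_cj]
        _PAIRS.append((_i, _j, is_ts, is_syn))
_PAIR_I = np.array([p[0] for p in _PAIRS])
_PAIR_J = np.array([p[1] for p in _PAIRS])
_PAIR_TS = np.array([p[2] for p in _PAIRS])
_PAIR_SYN = np.array([p[3] for p in _PAIRS])


class CodonAlignment:
    """Gap-aware matrix of codon states over the 61 sense codons.

    Rows are sequences (equal length in codons); each site state is a codon
    index, or -1 for missing (gap-containing or ambiguous codons).  In-frame
    stop codons are a validation error naming the sequence and site.
    """

    def __init__(self, ids: list, codes: np.ndarray):
        self.ids = list(ids)
        self.codes = np.asarray(codes, dtype=int)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.ids):
            raise ValueError("codes must be (n_sequences, n_sites)")
        if self.codes.shape[1] < 1:
            raise ValueError("alignment must have >= 1 codon site")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @classmethod
    def from_nucleotide(cls, seqs: Mapping[str, str]) -> "CodonAlignment":
        ids = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        n_sites = length // 3
        codes = np.full((len(ids), n_sites), -1, dtype=int)
        for r, sid in enumerate(ids):
            seq = seqs[sid].upper()
            for s in range(n_sites):
                codon = seq[3 * s : 3 * s + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"in-frame stop codon {codon} in sequence {sid!r} at codon site {s + 1}"
                    )
                codes[r, s] = CODON_INDEX.get(codon, -1)
        return cls(ids, codes)

    def to_nucleotide(self, gap: str = "---") -> dict:
        return {
            sid: "".join(
                CODONS[c] if c >= 0 else gap for c in self.codes[r]
            )
            for r, sid in enumerate(self.ids)
        }

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their multiplicities."""
        cols = self.codes.T  # (n_sites, n_seq)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        return uniq.T.copy(), counts


class BranchPartition:
    """Foreground/background labelling of tree edges.

    An edge is identified by the leaf set below it, which survives tree
    copying and restriction.  Foreground lineages are usually the stem edge
    of a named clade plus, optionally, all edges inside the clade.
    """

    def __init__(self, foreground: Iterable[frozenset]):
        self.foreground = frozenset(frozenset(f) for f in foreground)
        if not self.foreground:
            raise ValueError("at least one foreground edge is required")

    @classmethod
    def from_clade(
        cls, tree: PhyloTree, clade: Iterable[str], *, mode: str = "stem"
    ) -> "BranchPartition":
        """Foreground = the clade's stem edge; ``mode='stem+clade'`` adds
        every terminal and internal edge within the clade."""
        clade = frozenset(clade)
        unknown = clade - tree.leaf_labels
        if unknown:
            raise ValueError(f"clade taxa not on tree: {sorted(unknown)}")
        below = {}
        for node in tree.postorder():
            if node.is_leaf():
                below[id(node)] = frozenset([node.taxon.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.child_nodes())
                )
        edges = set(below.values())
        if clade not in edges and mode in ("stem", "stem+clade"):
            raise ValueError(f"clade {sorted(clade)} is not monophyletic on the tree")
        fg = {clade}
        if mode == "stem+clade":
            fg |= {e for e in edges if e < clade}
        elif mode != "stem":
            raise ValueError(f"unknown mode {mode!r}")
        return cls(fg)

    def is_foreground(self, below_leafset: frozenset) -> bool:
        return frozenset(below_leafset) in self.foreground


def uniform_frequencies() -> np.ndarray:
    return np.full(len(CODONS), 1.0 / len(CODONS))


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies."""
    counts = np.zeros((3, 4))
    nt_index = {n: k for k, n in enumerate("ACGT")}
    for r in range(len(alignment)):
        for c in alignment.codes[r]:
            if c >= 0:
                codon = CODONS[c]
                for pos in range(3):
                    counts[pos, nt_index[codon[pos]]] += 1
    counts += 0.5  # pseudo-count so absent nucleotides stay representable
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in CODONS
        ]
    )
    pi = np.maximum(pi / pi.sum(), _PI_FLOOR)
    return pi / pi.sum()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 generator; reversible with respect to pi."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    n = len(CODONS)
    Q = np.zeros((n, n))
    rates = pi[_PAIR_J] * np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q[_PAIR_I, _PAIR_J] = rates
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return Q


class _Eig:
    """Spectral form of a reversible generator, for cheap P(t) = exp(Qt)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = Q * (d[:, None] / d[None, :])
        S = (S + S.T) / 2.0
        w, U = np.linalg.eigh(S)
        self.w = w
        self.B = U / d[:, None]
        self.C = U.T * d[None, :]

    def P(self, t: float) -> np.ndarray:
        P = (self.B * np.exp(self.w * t)) @ self.C
        np.clip(P, 0.0, None, out=P)
        return P


@dataclass
class SiteClassModel:
    """Parameterisation of one of the three nested site-class models."""

    name: str
    kappa: float
    pi: np.ndarray
    p0: float
    p1: Optional[float] = None  # ModelA/null only; M1Neutral uses 1 - p0
    omega2: Optional[float] = None
    tree_scale: float = 1.0
    omega0: float = 0.0
    omega1: float = 1.0

    def __post_init__(self):
        if self.name not in ("M1Neutral", "ModelA", "ModelAnull"):
            raise ValueError(f"unknown model {self.name!r}")
        if self.kappa <= 0 or self.tree_scale <= 0:
            raise ValueError("kappa and tree_scale must be positive")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (len(CODONS),) or abs(self.pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be 61 frequencies summing to 1")
        if self.name == "M1Neutral":
            if not (0 <= self.p0 <= 1):
                raise ValueError("p0 must be in [0, 1]")
        else:
            if self.p1 is None or self.omega2 is None:
                raise ValueError(f"{self.name} requires p1 and omega2")
            if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
                raise ValueError("need p0, p1 >= 0 with p0 + p1 <= 1")
            if self.name == "ModelA" and self.omega2 < 1 - 1e-9:
                raise ValueError("ModelA requires omega2 >= 1")
            if self.name == "ModelAnull" and self.omega2 > 1 + 1e-9:
                raise ValueError("ModelAnull requires omega2 <= 1")

    def site_classes(self) -> list[tuple[float, float, float]]:
        """List of (proportion, background omega, foreground omega)."""
        w0, w1 = self.omega0, self.omega1
        if self.name == "M1Neutral":
            return [(self.p0, w0, w0), (1.0 - self.p0, w1, w1)][::1]
        p0, p1 = self.p0, self.p1
        p2 = max(1.0 - p0 - p1, 0.0)
        denom = p0 + p1
        if denom <= 0:
            p2a, p2b = p2 / 2.0, p2 / 2.0
        else:
            p2a, p2b = p2 * p0 / denom, p2 * p1 / denom
        w2 = self.omega2
        return [(p0, w0, w0), (p1, w1, w1), (p2a, w0, w2), (p2b, w1, w2)]

    def free_parameter_count(self) -> int:
        # kappa, tree_scale, plus proportions (1 or 2) and omega2 where free
        return 3 if self.name == "M1Neutral" else 5


def transition_matrix_factory(model: SiteClassModel):
    """Return ``P(omega, t)`` with the mixture-scaled generator.

    The scale is fixed so the expected rate over site classes — at the
    background omegas, under pi — equals 1.
    """
    eigs: dict[float, _Eig] = {}
    rate_cache: dict[float, float] = {}

    def rate(omega: float) -> float:
        if omega not in rate_cache:
            Q = build_rate_matrix(model.kappa, omega, model.pi)
            rate_cache[omega] = float(-np.dot(model.pi, np.diag(Q)))
        return rate_cache[omega]

    mix = sum(p * rate(wb) for p, wb, _ in model.site_classes())
    mix = max(mix, 1e-12)

    def P(omega: float, t: float) -> np.ndarray:
        if omega not in eigs:
            eigs[omega] = _Eig(build_rate_matrix(model.kappa, omega, model.pi), model.pi)
        return eigs[omega].P(t * model.tree_scale / mix)

    return P


def _edge_roles(tree: PhyloTree, partition: Optional[BranchPartition]):
    nodes = list(tree.postorder())
    below: dict[int, frozenset] = {}
    roles = []
    for node in nodes:
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
        fg = partition.is_foreground(below[id(node)]) if partition else False
        roles.append("foreground" if fg else "background")
    return nodes, roles


def codon_loglik(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model: SiteClassModel,
    partition: Optional[BranchPartition] = None,
    *,
    return_site_logliks: bool = False,
):
    """Felsenstein-pruning log-likelihood under the site-class mixture.

    Per-site likelihood is the class-proportion-weighted sum of pruning
    likelihoods; gaps and ambiguous codons are marginalised as missing
    data.  The tree's leaf set must equal the alignment's sequence ids.
    """
    if set(alignment.ids) != tree.leaf_labels:
        raise ValueError("tree leaves and alignment sequence ids differ")
    nodes, roles = _edge_roles(tree, partition)
    node_index = {id(n): i for i, n in enumerate(nodes)}
    row_of = {sid: r for r, sid in enumerate(alignment.ids)}
    patterns, counts = alignment.patterns()
    npat = patterns.shape[1]
    n_states = len(CODONS)
    Pfun = transition_matrix_factory(model)

    class_logliks = []
    log_props = []
    for prop, w_bg, w_fg in model.site_classes():
        if prop <= 0:
            continue
        log_props.append(np.log(prop))
        partials: list[Optional[np.ndarray]] = [None] * len(nodes)
        scalers = np.zeros(npat)
        for i, node in enumerate(nodes):
            if node.is_leaf():
                codes = patterns[row_of[node.taxon.label]]
                v = np.zeros((n_states, npat))
                obs = codes >= 0
                v[codes[obs], np.nonzero(obs)[0]] = 1.0
                v[:, ~obs] = 1.0
                partials[i] = v
            else:
                v = np.ones((n_states, npat))
                for child in node.child_nodes():
                    ci = node_index[id(child)]
                    t = child.edge.length
                    if t is None:
                        raise ValueError("codon likelihood requires branch lengths")
                    omega = w_fg if roles[ci] == "foreground" else w_bg
                    v = v * (Pfun(omega, t) @ partials[ci])
                    partials[ci] = None
                mx = v.max(axis=0)
                mx = np.where(mx > 0, mx, 1.0)
                v /= mx
                scalers += np.log(mx)
                partials[i] = v
        site_like = model.pi @ partials[-1]
        with np.errstate(divide="ignore"):
            class_logliks.append(np.log(np.maximum(site_like, 1e-300)) + scalers)
    stacked = np.stack(class_logliks) + np.array(log_props)[:, None]
    site_ll = logsumexp(stacked, axis=0)
    total = float(np.dot(site_ll, counts))
    if return_site_logliks:
        return total, site_ll, counts
    return total
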