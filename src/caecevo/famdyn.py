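"""Birth-death model of gene-family size evolution on a time-scaled tree.

The family size evolves along each branch as a continuous-time Markov chain
on counts with equal per-gene gain and loss rate ``lambda`` (per gene per
unit branch time).  The transition probability has the classical closed
form: with ``a = lambda*t / (1 + lambda*t)``,

    P(c | s, t) = sum_{j=0..min(s,c)} C(s, j) C(s+c-j-1, s-1)
                  * a^(s+c-2j) * (1-2a)^j          for s >= 1,

and P(0|0) = 1 (zero is absorbing).  The root family size carries a Poisson
prior whose mean is estimated jointly with lambda by maximum likelihood.
Likelihoods are computed by Felsenstein pruning over the truncated count
state space 0..max_count; ancestral counts are marginal maximum-a-posteriori
states from an up-down pass, with ties broken toward the smaller count.

Per-family significance is Monte-Carlo: the p-value is the fraction of
null-simulated families (root drawn from the Poisson prior, evolved by the
fitted kernel) whose log-likelihood under the fitted model is at most the
observed family's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import comb, logsumexp

from caecevo.phylostrat import CladeSpec
from caecevo.trees import PhyloTree

__all__ = [
    "FamilyRateModel",
    "bd_transition_prob",
    "bd_transition_matrix",
    "family_loglik",
    "estimate_lambda",
    "reconstruct_ancestral",
    "family_pvalue",
    "exclusion_filter",
    "BirthDeathFamilyModel",
    "BirthDeathFamilyResults",
]

_LAMBDA_BOUNDS = (1e-8, 10.0)
_ROOT_MEAN_BOUNDS = (1e-3, 1e3)


@dataclass
class FamilyRateModel:
    """Equal-rate birth-death model parameters.

    lambda_ is the per-gene gain/loss rate per unit branch time;
    root_prior_mean is the Poisson mean of the root family size;
    max_count truncates the count state space (must cover the data).
    """

    lambda_: float
    root_prior_mean: float
    max_count: int

    def __post_init__(self):
        if not (np.isfinite(self.lambda_) and self.lambda_ > 0):
            raise ValueError("lambda must be positive and finite")
        if not (np.isfinite(self.root_prior_mean) and self.root_prior_mean > 0):
            raise ValueError("root_prior_mean must be positive and finite")
        if self.max_count < 1:
            raise ValueError("max_count must be >= 1")

    def root_log_prior(self) -> np.ndarray:
        counts = np.arange(self.max_count + 1)
        return stats.poisson.logpmf(counts, self.root_prior_mean)


def bd_transition_prob(s: int, c: int, t: float, lam: float) -> float:
    """P(child count = c | parent count = s) after branch time t."""
    if s < 0 or c < 0 or t < 0 or lam < 0:
        raise ValueError("counts, time and rate must be non-negative")
    if t == 0 or lam == 0:
        return 1.0 if c == s else 0.0
    if s == 0:
        return 1.0 if c == 0 else 0.0
    a = lam * t / (1.0 + lam * t)
    j = np.arange(min(s, c) + 1)
    terms = (
        comb(s, j)
        * comb(s + c - j - 1, s - 1)
        * a ** (s + c - 2 * j)
        * (1.0 - 2.0 * a) ** j
    )
    return float(max(terms.sum(), 0.0))


def bd_transition_matrix(lam: float, t: float, max_count: int) -> np.ndarray:
    """(max_count+1)^2 matrix P[s, c]; rows sum to 1 up to truncation."""
    m = max_count
    if t == 0 or lam == 0:
        return np.eye(m + 1)
    P = np.zeros((m + 1, m + 1))
    P[0, 0] = 1.0
    a = lam * t / (1.0 + lam * t)
    one_minus_2a = 1.0 - 2.0 * a
    c = np.arange(m + 1)
    for s in range(1, m + 1):
        jmax = min(s, m)
        j = np.arange(jmax + 1)
        # terms[j, c]: defined only where j <= min(s, c)
        mask = j[:, None] <= np.minimum(s, c)[None, :]
        expo = np.where(mask, s + c[None, :] - 2 * j[:, None], 0)
        terms = (
            comb(s, j)[:, None]
            * comb(np.where(mask, s + c[None, :] - j[:, None] - 1, 0), s - 1)
            * a ** expo
            * one_minus_2a ** j[:, None]
        )
        P[s] = np.where(mask, terms, 0.0).sum(axis=0)
    np.clip(P, 0.0, 1.0, out=P)
    return P


def _tree_edges(tree: PhyloTree):
    """Postorder node list plus parent indices and branch lengths."""
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    parents = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    for i, n in enumerate(nodes):
        if n.parent_node is not None:
            parents[i] = index[id(n.parent_node)]
            if n.edge.length is None:
                raise ValueError("family dynamics requires branch lengths on every edge")
            lengths[i] = n.edge.length
    return nodes, parents, lengths


def _branch_matrices(lengths: np.ndarray, parents: np.ndarray, lam: float, max_count: int):
    mats: dict[float, np.ndarray] = {}
    out: list[Optional[np.ndarray]] = [None] * len(lengths)
    for i, t in enumerate(lengths):
        if parents[i] < 0:
            continue
        key = float(t)
        if key not in mats:
            mats[key] = bd_transition_matrix(lam, key, max_count)
        out[i] = mats[key]
    return out


def _leaf_partials(nodes, profile: Mapping[str, int], max_count: int) -> list:
    """Per-node conditional likelihood vectors; unobserved leaves are missing."""
    partials = []
    for n in nodes:
        if n.is_leaf():
            label = n.taxon.label
            if label in profile:
                cnt = int(profile[label])
                if cnt < 0:
                    raise ValueError(f"negative count for {label}")
                if cnt > max_count:
                    raise ValueError(
                        f"count {cnt} for {label} exceeds max_count {max_count}"
                    )
                v = np.zeros(max_count + 1)
                v[cnt] = 1.0
            else:
                v = np.ones(max_count + 1)
            partials.append(v)
        else:
            partials.append(None)
    return partials


def _inside_pass(nodes, parents, branch_mats, partials):
    """Fill internal-node partials bottom-up; returns per-node vectors."""
    children: list[list[int]] = [[] for _ in nodes]
    for i, p in enumerate(parents):
        if p >= 0:
            children[p].append(i)
    out = list(partials)
    for i, n in enumerate(nodes):
        if n.is_leaf():
            continue
        v = np.ones(branch_mats[children[i][0]].shape[0])
        for c in children[i]:
            v = v * (branch_mats[c] @ out[c])
        out[i] = v
    return out, children


class _BDEngine:
    """Cached tree structure + transition matrices for one (lambda, max_count).

    Batched pruning: evaluates many families against the same model in one
    vectorized pass.
    """

    def __init__(self, tree: PhyloTree, model: FamilyRateModel):
        self.tree = tree
        self.model = model
        self.nodes, self.parents, self.lengths = _tree_edges(tree)
        self.mats = _branch_matrices(
            self.lengths, self.parents, model.lambda_, model.max_count
        )
        self.children: list[list[int]] = [[] for _ in self.nodes]
        for i, p in enumerate(self.parents):
            if p >= 0:
                self.children[p].append(i)
        self.leaf_labels = [
            n.taxon.label for n in self.nodes if n.is_leaf()
        ]
        self.log_prior = model.root_log_prior()

    def logliks(self, tips: np.ndarray, labels: list) -> np.ndarray:
        """(n_families,) log-likelihoods for (n_families, len(labels)) counts."""
        m = self.model.max_count
        n = tips.shape[0]
        col_of = {sp: k for k, sp in enumerate(labels)}
        partials: list[Optional[np.ndarray]] = [None] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            if node.is_leaf():
                label = node.taxon.label
                if label in col_of:
                    counts = tips[:, col_of[label]].astype(int)
                    if (counts < 0).any():
                        raise ValueError(f"negative count for {label}")
                    if (counts > m).any():
                        raise ValueError(f"count exceeds max_count {m} for {label}")
                    v = np.zeros((n, m + 1))
                    v[np.arange(n), counts] = 1.0
                else:
                    v = np.ones((n, m + 1))
                partials[i] = v
            else:
                v = np.ones((n, m + 1))
                for c in self.children[i]:
                    v = v * (partials[c] @ self.mats[c].T)
                    partials[c] = None
                partials[i] = v
        with np.errstate(divide="ignore"):
            return logsumexp(
                self.log_prior[None, :] + np.log(np.maximum(partials[-1], 0.0)),
                axis=1,
            )


def family_loglik(tree: PhyloTree, profile: Mapping[str, int], model: FamilyRateModel) -> float:
    """Log-likelihood of one family's tip counts under the model."""
    missing = set(profile) - set(tree.leaf_labels)
    if missing:
        raise ValueError(f"species not on the tree: {sorted(missing)}")
    engine = _BDEngine(tree, model)
    labels = sorted(profile)
    tips = np.array([[int(profile[sp]) for sp in labels]])
    return float(engine.logliks(tips, labels)[0])


class BirthDeathFamilyModel:
    """Gene-family size evolution fitted to an orthogroup count table.

    Parameters
    ----------
    counts : DataFrame
        Orthogroup x species non-negative integer gene counts.
    tree : PhyloTree
        Time-scaled species tree covering the table's species.
    max_count : int, optional
        Count-space truncation bound; defaults to 2 * max observed + 10,
        with truncation stability checkable via :meth:`loglik`.
    """

    def __init__(self, counts: pd.DataFrame, tree: PhyloTree, *, max_count: Optional[int] = None):
        missing = set(counts.columns) - set(tree.leaf_labels)
        if missing:
            raise ValueError(f"table species not on the tree: {sorted(missing)}")
        if (counts.values < 0).any():
            raise ValueError("gene counts must be non-negative")
        if not counts.values.any():
            raise ValueError("all counts are zero: lambda is unidentifiable")
        self.counts = counts.astype(int)
        self.tree = tree
        obs_max = int(self.counts.values.max())
        self.max_count = int(max_count) if max_count is not None else 2 * obs_max + 10
        if self.max_count < obs_max:
            raise ValueError("max_count must cover the observed maximum count")
        self._nodes, self._parents, self._lengths = _tree_edges(tree)
        self._leaf_index = {
            n.taxon.label: i for i, n in enumerate(self._nodes) if n.is_leaf()
        }
        # dense per-family tip counts aligned with the node list
        self._tip_counts = np.array(
            [
                [int(row[sp]) for sp in self.counts.columns]
                for _, row in self.counts.iterrows()
            ]
        )

    # -- likelihood -----------------------------------------------------

    def loglik(self, lambda_: float, root_prior_mean: float, *, max_count: Optional[int] = None) -> float:
        """Summed log-likelihood of every family at the given parameters."""
        m = self.max_count if max_count is None else int(max_count)
        mats = _branch_matrices(self._lengths, self._parents, lambda_, m)
        log_prior = stats.poisson.logpmf(np.arange(m + 1), root_prior_mean)
        children: list[list[int]] = [[] for _ in self._nodes]
        for i, p in enumerate(self._parents):
            if p >= 0:
                children[p].append(i)
        nfam = len(self.counts)
        # partials: node -> (nfam, m+1)
        partials: list[Optional[np.ndarray]] = [None] * len(self._nodes)
        col_of = {sp: k for k, sp in enumerate(self.counts.columns)}
        total = 0.0
        for i, n in enumerate(self._nodes):
            if n.is_leaf():
                label = n.taxon.label
                if label in col_of:
                    v = np.zeros((nfam, m + 1))
                    v[np.arange(nfam), self._tip_counts[:, col_of[label]]] = 1.0
                else:
                    v = np.ones((nfam, m + 1))
                partials[i] = v
            else:
                v = np.ones((nfam, m + 1))
                for c in children[i]:
                    v = v * (partials[c] @ mats[c].T)
                    partials[c] = None
                partials[i] = v
        root = partials[-1]
        with np.errstate(divide="ignore"):
            ll = logsumexp(log_prior[None, :] + np.log(np.maximum(root, 0.0)), axis=1)
        total = float(ll.sum())
        self._last_family_logliks = ll
        return total

    def fit(self, *, start_lambda: Optional[float] = None, start_root_mean: Optional[float] = None) -> "BirthDeathFamilyResults":
        """Maximum-likelihood estimate of (lambda, root prior mean)."""
        mean_tip = float(self.counts.values.mean())
        x0 = np.log(
            [
                start_lambda if start_lambda is not None else 1.0 / max(self._tree_depth(), 1.0),
                start_root_mean if start_root_mean is not None else max(mean_tip, 0.1),
            ]
        )

        def nll(x):
            lam, mu = np.exp(x)
            lam = float(np.clip(lam, *_LAMBDA_BOUNDS))
            mu = float(np.clip(mu, *_ROOT_MEAN_BOUNDS))
            return -self.loglik(lam, mu)

        bounds = [tuple(np.log(_LAMBDA_BOUNDS)), tuple(np.log(_ROOT_MEAN_BOUNDS))]
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        lam, mu = np.exp(res.x)
        fitted = FamilyRateModel(float(lam), float(mu), self.max_count)
        llf = self.loglik(fitted.lambda_, fitted.root_prior_mean)
        return BirthDeathFamilyResults(
            self, fitted, llf, family_logliks=self._last_family_logliks.copy(),
            nfev=int(res.nfev), converged=bool(res.success),
        )

    def _tree_depth(self) -> float:
        depth = 0.0
        for leaf in self.tree.dtree.leaf_node_iter():
            d, n = 0.0, leaf
            while n.parent_node is not None:
                d += n.edge.length or 0.0
                n = n.parent_node
            depth = max(depth, d)
        return depth


class BirthDeathFamilyResults:
    """Fitted birth-death family model: estimates, reconstructions, tests."""

    def __init__(self, model, params: FamilyRateModel, llf: float, *, family_logliks, nfev, converged):
        self.model = model
        self.params = params
        self.lambda_ = params.lambda_
        self.root_prior_mean = params.root_prior_mean
        self.llf = llf
        self.family_logliks = pd.Series(family_logliks, index=model.counts.index)
        self.nfev = nfev
        self.converged = converged

    def summary(self) -> str:
        lines = [
            "Birth-death gene-family model",
            "=" * 46,
            f"families                {len(self.model.counts):>12d}",
            f"species                 {len(self.model.counts.columns):>12d}",
            f"max_count (truncation)  {self.params.max_count:>12d}",
            f"lambda (per gene/time)  {self.lambda_:>12.6g}",
            f"root prior mean         {self.root_prior_mean:>12.4g}",
            f"log-likelihood          {self.llf:>12.4f}",
            f"converged               {str(self.converged):>12s}",
        ]
        return "\n".join(lines)

    def reconstruct(self, orthogroup) -> dict:
        profile = self.model.counts.loc[orthogroup].to_dict()
        return reconstruct_ancestral(self.model.tree, profile, self.params)

    def family_pvalues(self, *, reps: int = 200, seed: int = 0) -> pd.Series:
        """Monte-Carlo family-wide p-value per orthogroup (seeded).

        Each family gets an independent null sample so the p-values are
        independent across families.
        """
        rng = np.random.default_rng(seed)
        engine = _BDEngine(self.model.tree, self.params)
        ps = {}
        for og in self.model.counts.index:
            null_ll = _simulate_null_logliks(
                self.model.tree, self.params, reps, rng, engine=engine
            )
            ps[og] = float(np.mean(null_ll <= self.family_logliks[og]))
        return pd.Series(ps, name="pvalue")

    def exclusion(self, clades: CladeSpec, *, min_species_present: int = 4) -> pd.Series:
        return exclusion_filter(
            self.model.tree, self.model.counts, clades, self.params,
            min_species_present=min_species_present,
        )

    def branch_pvalues(self, orthogroup) -> pd.Series:
        """Per-branch transition p-values for one family.

        For each branch, with the (reconstructed or observed) parent count s
        and child count c: the total probability of child counts whose
        transition probability from s is at most that of c — small when the
        branch saw an unusually large change.  Complements the family-wide
        Monte-Carlo p-value; neither is privileged.
        """
        tree = self.model.tree
        nodes, parents, lengths = _tree_edges(tree)
        labels = _node_labels(nodes)
        rec = self.reconstruct(orthogroup)
        row = self.model.counts.loc[orthogroup]
        out = {}
        for i, n in enumerate(nodes):
            if parents[i] < 0:
                continue
            s = rec[labels[parents[i]]]
            c = int(row[labels[i]]) if n.is_leaf() and labels[i] in row else rec[labels[i]]
            probs = np.array(
                [
                    bd_transition_prob(s, k, lengths[i], self.lambda_)
                    for k in range(self.params.max_count + 1)
                ]
            )
            out[labels[i]] = float(min(1.0, probs[probs <= probs[c] + 1e-15].sum()))
        return pd.Series(out, name="branch_pvalue")

    def node_change_summary(self) -> pd.DataFrame:
        """Per-internal-node counts of family expansions and contractions."""
        tree = self.model.tree
        nodes, parents, _ = _tree_edges(tree)
        labels = _node_labels(nodes)
        expansions = np.zeros(len(nodes), dtype=int)
        contractions = np.zeros(len(nodes), dtype=int)
        for og in self.model.counts.index:
            rec = self.reconstruct(og)
            for i, n in enumerate(nodes):
                if parents[i] < 0:
                    continue
                child = rec[labels[i]]
                parent = rec[labels[parents[i]]]
                if child > parent:
                    expansions[i] += 1
                elif child < parent:
                    contractions[i] += 1
        return pd.DataFrame(
            {"node": labels, "expansions": expansions, "contractions": contractions}
        ).set_index("node")


def estimate_lambda(tree: PhyloTree, profiles: pd.DataFrame, *, max_count: Optional[int] = None) -> "BirthDeathFamilyResults":
    """Functional wrapper: fit the birth-death model to a count table."""
    _warn_if_not_ultrametric(tree)
    return BirthDeathFamilyModel(profiles, tree, max_count=max_count).fit()


def _warn_if_not_ultrametric(tree: PhyloTree, rtol: float = 1e-3) -> None:
    import warnings

    depths = []
    for leaf in tree.dtree.leaf_node_iter():
        d, n = 0.0, leaf
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        depths.append(d)
    if depths and (max(depths) - min(depths)) > rtol * max(depths):
        warnings.warn("tree is not ultrametric; branch lengths are treated as time")


def _node_labels(nodes) -> list:
    labels = []
    for i, n in enumerate(nodes):
        if n.is_leaf():
            labels.append(n.taxon.label)
        elif n.label:
            labels.append(n.label)
        else:
            labels.append(f"node{i}")
    return labels


def reconstruct_ancestral(tree: PhyloTree, profile: Mapping[str, int], model: FamilyRateModel) -> dict:
    """Marginal MAP count per node (up-down pass); ties -> smaller count."""
    nodes, parents, lengths = _tree_edges(tree)
    mats = _branch_matrices(lengths, parents, model.lambda_, model.max_count)
    partials = _leaf_partials(nodes, profile, model.max_count)
    inside, children = _inside_pass(nodes, parents, mats, partials)
    prior = np.exp(model.root_log_prior())
    outside: list[Optional[np.ndarray]] = [None] * len(nodes)
    outside[-1] = prior
    for i in reversed(range(len(nodes))):
        if nodes[i].is_leaf():
            continue
        for c in children[i]:
            sib = np.ones(model.max_count + 1)
            for c2 in children[i]:
                if c2 != c:
                    sib = sib * (mats[c2] @ inside[c2])
            outside[c] = (outside[i] * sib) @ mats[c]
    labels = _node_labels(nodes)
    rec = {}
    for i, n in enumerate(nodes):
        post = outside[i] * inside[i]
        rec[labels[i]] = int(np.argmax(post))  # argmax returns the smallest tie
    return rec


def _simulate_profiles(tree: PhyloTree, model: FamilyRateModel, n: int, rng) -> np.ndarray:
    """Evolve n families down the tree; returns (n, n_leaves) tip counts."""
    nodes, parents, lengths = _tree_edges(tree)
    order = list(reversed(range(len(nodes))))  # root first
    counts = np.zeros((len(nodes), n), dtype=int)
    mats = _branch_matrices(lengths, parents, model.lambda_, model.max_count)
    counts[len(nodes) - 1] = np.minimum(
        rng.poisson(model.root_prior_mean, size=n), model.max_count
    )
    for i in order:
        if parents[i] < 0:
            continue
        P = mats[i]
        parent_counts = counts[parents[i]]
        # sample child state per family from the parent's transition row
        rows = P[parent_counts]
        rows = rows / np.maximum(rows.sum(axis=1, keepdims=True), 1e-300)
        u = rng.random(n)
        counts[i] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
    leaf_idx = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
    return counts[leaf_idx].T, [nodes[i].taxon.label for i in leaf_idx]


def _simulate_observable_profiles(tree: PhyloTree, model: FamilyRateModel, n: int, rng):
    """Null profiles conditioned on being observable (>= 1 non-zero tip).

    Orthogroup tables only ever contain families with at least one gene
    somewhere, so the null the p-values are computed against carries the
    same conditioning.
    """
    kept = []
    labels = None
    while len(kept) < n:
        tips, labels = _simulate_profiles(tree, model, max(n - len(kept), 16), rng)
        for row in tips:
            if row.sum() > 0:
                kept.append(row)
            if len(kept) == n:
                break
    return np.array(kept), labels


def _simulate_null_logliks(
    tree: PhyloTree, model: FamilyRateModel, reps: int, rng, engine: Optional[_BDEngine] = None
) -> np.ndarray:
    engine = engine if engine is not None else _BDEngine(tree, model)
    tips, labels = _simulate_observable_profiles(tree, model, reps, rng)
    return engine.logliks(tips, labels)


def family_pvalue(
    tree: PhyloTree,
    profile: Mapping[str, int],
    model: FamilyRateModel,
    *,
    reps: int = 1000,
    seed: int = 0,
    engine: Optional[_BDEngine] = None,
) -> float:
    """Monte-Carlo p-value for one family under the fitted model.

    The fraction of observable null families whose log-likelihood is at
    most the observed family's; seeded and reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    engine = engine if engine is not None else _BDEngine(tree, model)
    labels = sorted(profile)
    obs = float(engine.logliks(np.array([[int(profile[sp]) for sp in labels]]), labels)[0])
    null_ll = _simulate_null_logliks(tree, model, reps, rng, engine=engine)
    return float(np.mean(null_ll <= obs))


def exclusion_filter(
    tree: PhyloTree,
    counts: pd.DataFrame,
    clades: CladeSpec,
    model: FamilyRateModel,
    *,
    min_species_present: int = 4,
) -> pd.Series:
    """Classify families as no_net_change / insufficient_sampling / analyzed.

    ``no_net_change``: every caecilian tip count equals the reconstructed
    count at the ancestral amphibian node (the MRCA of the amphibian
    species on the tree).  ``insufficient_sampling``: fewer than
    ``min_species_present`` species carry a non-zero count.
    """
    clades.validate_against(counts.columns)
    amphibians = sorted(clades.amphibians & tree.leaf_labels)
    if len(amphibians) < 2:
        raise ValueError("need >= 2 amphibian species on the tree to locate their MRCA")
    mrca = tree.dtree.mrca(taxon_labels=amphibians)
    nodes, _, _ = _tree_edges(tree)
    labels = _node_labels(nodes)
    mrca_label = labels[[id(n) for n in nodes].index(id(mrca))]
    caecs = sorted(clades.caecilians & set(counts.columns))
    out = {}
    for og, row in counts.iterrows():
        rec = reconstruct_ancestral(tree, row.to_dict(), model)
        anc = rec[mrca_label]
        if all(int(row[sp]) == anc for sp in caecs):
            out[og] = "no_net_change"
        elif int((row >= 1).sum()) < min_species_present:
            out[og] = "insufficient_sampling"
        else:
            out[og] = "analyzed"
    return pd.Series(out, name="exclusion")
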