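"""Birth-death gene-family dynamics: kernel, pruning, estimation, p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import expm

from caecevo.famdyn import (
    BirthDeathFamilyModel,
    FamilyRateModel,
    bd_transition_matrix,
    bd_transition_prob,
    estimate_lambda,
    exclusion_filter,
    family_loglik,
    family_pvalue,
    reconstruct_ancestral,
)
from caecevo.phylostrat import CladeSpec
from caecevo.simulate import default_species_tree, simulate_counts
from caecevo.trees import parse_newick


def bd_generator(lam: float, max_count: int) -> np.ndarray:
    """Truncated generator of the equal-rate birth-death chain (oracle)."""
    Q = np.zeros((max_count + 1, max_count + 1))
    for i in range(max_count + 1):
        if i + 1 <= max_count:
            Q[i, i + 1] = lam * i
        if i - 1 >= 0:
            Q[i, i - 1] = lam * i
        Q[i, i] = -Q[i].sum()
    return Q


class TestTransitionKernel:
    def test_zero_time_is_identity(self):
        for s in range(5):
            for c in range(5):
                assert bd_transition_prob(s, c, 0.0, 0.1) == (1.0 if c == s else 0.0)

    def test_single_gene_loss_at_half_alpha(self):
        # lambda*t = 1 gives alpha = 1/2, and P(0|1) = alpha
        assert bd_transition_prob(1, 0, 1.0, 1.0) == pytest.approx(0.5)

    def test_negative_inputs_are_errors(self):
        with pytest.raises(ValueError):
            bd_transition_prob(-1, 0, 1.0, 0.1)
        with pytest.raises(ValueError):
            bd_transition_prob(0, 0, -1.0, 0.1)

    def test_matches_generator_exponential(self):
        """Closed form vs matrix exponential of the truncated generator."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            lam = float(rng.uniform(0.001, 0.05))
            t = float(rng.uniform(1.0, 80.0))
            M = 60
            P = bd_transition_matrix(lam, t, M)
            Pe = expm(bd_generator(lam, M) * t)
            # compare interior states, far from the truncation boundary
            assert np.abs(P[:15, :15] - Pe[:15, :15]).max() < 1e-6

    def test_rows_sum_to_one_within_truncation(self):
        P = bd_transition_matrix(0.002, 100.0, 40)
        assert np.all(P.sum(axis=1)[:20] > 1 - 1e-8)
        assert np.all(P.sum(axis=1) <= 1 + 1e-8)


class TestFamilyLoglik:
    def brute_force(self, tree_spec, counts, model):
        """Exhaustive sum over all internal-node count assignments."""
        # tree_spec: ((A,B),C) with fixed branch lengths as in newick below
        total = 0.0
        prior = stats.poisson.pmf(np.arange(model.max_count + 1), model.root_prior_mean)
        for r in range(model.max_count + 1):
            for x in range(model.max_count + 1):
                total += (
                    prior[r]
                    * bd_transition_prob(r, x, 50, model.lambda_)
                    * bd_transition_prob(x, counts["A"], 100, model.lambda_)
                    * bd_transition_prob(x, counts["B"], 100, model.lambda_)
                    * bd_transition_prob(r, counts["C"], 150, model.lambda_)
                )
        return np.log(total)

    def test_pruning_equals_enumeration_three_taxa(self):
        tree = parse_newick("((A:100,B:100):50,C:150);")
        model = FamilyRateModel(0.003, 2.0, 6)
        for counts in [{"A": 2, "B": 1, "C": 2}, {"A": 0, "B": 3, "C": 1}]:
            ll = family_loglik(tree, counts, model)
            assert ll == pytest.approx(self.brute_force(tree, counts, model), abs=1e-8)

    def test_pruning_equals_enumeration_four_taxa(self):
        tree = parse_newick("((A:60,B:60):40,(C:70,D:70):30);")
        model = FamilyRateModel(0.004, 1.5, 5)
        counts = {"A": 1, "B": 2, "C": 0, "D": 1}
        M = model.max_count
        prior = stats.poisson.pmf(np.arange(M + 1), model.root_prior_mean)
        total = 0.0
        for r, x, y in itertools.product(range(M + 1), repeat=3):
            total += (
                prior[r]
                * bd_transition_prob(r, x, 40, model.lambda_)
                * bd_transition_prob(r, y, 30, model.lambda_)
                * bd_transition_prob(x, 1, 60, model.lambda_)
                * bd_transition_prob(x, 2, 60, model.lambda_)
                * bd_transition_prob(y, 0, 70, model.lambda_)
                * bd_transition_prob(y, 1, 70, model.lambda_)
            )
        assert family_loglik(tree, counts, model) == pytest.approx(np.log(total), abs=1e-8)

    def test_small_lambda_limit_is_root_prior(self):
        tree = parse_newick("((A:100,B:100):50,C:150);")
        model = FamilyRateModel(1e-8, 2.0, 10)
        ll = family_loglik(tree, {"A": 3, "B": 3, "C": 3}, model)
        assert ll == pytest.approx(stats.poisson.logpmf(3, 2.0), abs=1e-4)

    def test_truncation_stability(self):
        tree = default_species_tree()
        counts = {sp: 2 for sp in tree.leaf_labels}
        base = FamilyRateModel(0.002, 2.0, 10)
        big = FamilyRateModel(0.002, 2.0, 60)
        assert family_loglik(tree, counts, big) == pytest.approx(
            family_loglik(tree, counts, base), abs=1e-8
        )

    def test_unknown_species_is_error(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="Z"):
            family_loglik(tree, {"Z": 1}, FamilyRateModel(0.1, 1.0, 5))


class TestEstimation:
    def test_recovers_lambda_within_twenty_percent(self, species_tree):
        rels = []
        for seed in range(3):
            counts = simulate_counts(
                species_tree, lambda_=0.002, root_prior_mean=2.0,
                n_families=400, seed=seed,
            )
            counts = counts.loc[counts.sum(axis=1) > 0]
            res = BirthDeathFamilyModel(counts, species_tree).fit()
            rels.append(abs(res.lambda_ - 0.002) / 0.002)
            assert res.llf >= res.model.loglik(0.002, 2.0) - 1e-6
        assert np.median(rels) < 0.2

    def test_constant_counts_drive_lambda_to_lower_bound(self, species_tree):
        counts = pd.DataFrame(
            2, index=[f"OG{i}" for i in range(50)],
            columns=sorted(species_tree.leaf_labels),
        )
        res = BirthDeathFamilyModel(counts, species_tree).fit()
        assert res.lambda_ < 1e-5

    def test_all_zero_table_is_error(self, species_tree):
        counts = pd.DataFrame(
            0, index=["OG0"], columns=sorted(species_tree.leaf_labels)
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            BirthDeathFamilyModel(counts, species_tree)

    def test_summary_mentions_estimates(self, species_tree):
        counts = simulate_counts(species_tree, n_families=50, seed=1)
        counts = counts.loc[counts.sum(axis=1) > 0]
        res = BirthDeathFamilyModel(counts, species_tree).fit()
        text = res.summary()
        assert "lambda" in text and "log-likelihood" in text


class TestReconstruction:
    def test_map_equals_exhaustive_argmax_three_taxa(self):
        tree = parse_newick("((A:100,B:100):50,C:150);")
        model = FamilyRateModel(0.004, 2.0, 5)
        counts = {"A": 3, "B": 2, "C": 1}
        rec = reconstruct_ancestral(tree, counts, model)
        M = model.max_count
        prior = stats.poisson.pmf(np.arange(M + 1), model.root_prior_mean)
        # exhaustive marginal posterior for the AB ancestor and the root
        joint = np.zeros((M + 1, M + 1))  # [root, ab]
        for r, x in itertools.product(range(M + 1), repeat=2):
            joint[r, x] = (
                prior[r]
                * bd_transition_prob(r, x, 50, model.lambda_)
                * bd_transition_prob(x, 3, 100, model.lambda_)
                * bd_transition_prob(x, 2, 100, model.lambda_)
                * bd_transition_prob(r, 1, 150, model.lambda_)
            )
        internal = {k: v for k, v in rec.items() if k.startswith("node")}
        ab_label = min(internal, key=lambda k: int(k[4:]))
        root_label = max(internal, key=lambda k: int(k[4:]))
        assert rec[ab_label] == int(np.argmax(joint.sum(axis=0)))
        assert rec[root_label] == int(np.argmax(joint.sum(axis=1)))

    def test_stasis_limit(self):
        tree = parse_newick("((A:100,B:100):50,C:150);")
        model = FamilyRateModel(1e-8, 2.0, 10)
        rec = reconstruct_ancestral(tree, {"A": 4, "B": 4, "C": 4}, model)
        assert all(v == 4 for v in rec.values())

    def test_invariant_to_tip_order(self):
        t1 = parse_newick("((A:100,B:100):50,C:150);")
        t2 = parse_newick("((B:100,A:100):50,C:150);")
        model = FamilyRateModel(0.003, 2.0, 6)
        counts = {"A": 1, "B": 3, "C": 2}
        r1 = reconstruct_ancestral(t1, counts, model)
        r2 = reconstruct_ancestral(t2, counts, model)
        assert sorted(r1.values()) == sorted(r2.values())
        assert all(r1[k] == r2[k] for k in "ABC")


class TestPValues:
    def test_same_seed_same_pvalue(self, species_tree):
        model = FamilyRateModel(0.002, 2.0, 30)
        profile = {sp: 2 for sp in species_tree.leaf_labels}
        p1 = family_pvalue(species_tree, profile, model, reps=200, seed=7)
        p2 = family_pvalue(species_tree, profile, model, reps=200, seed=7)
        assert p1 == p2

    def test_extreme_expansion_is_significant(self, species_tree):
        model = FamilyRateModel(0.002, 1.0, 120)
        profile = {sp: 1 for sp in species_tree.leaf_labels}
        profile["Geo_ser"] = 50
        p = family_pvalue(species_tree, profile, model, reps=1000, seed=5)
        assert p < 0.05

    def test_reps_below_one_is_error(self, species_tree):
        model = FamilyRateModel(0.002, 2.0, 10)
        with pytest.raises(ValueError):
            family_pvalue(species_tree, {"Geo_ser": 1}, model, reps=0)


class TestBranchPValues:
    def test_extreme_branch_change_scores_low(self, species_tree):
        counts = simulate_counts(species_tree, n_families=30, seed=2)
        counts = counts.loc[counts.sum(axis=1) > 0]
        counts.iloc[0, counts.columns.get_loc("Geo_ser")] = 25
        res = BirthDeathFamilyModel(counts, species_tree).fit()
        bp = res.branch_pvalues(counts.index[0])
        quiet = res.branch_pvalues(counts.index[1])
        assert bp["Geo_ser"] < 0.05
        assert bp["Geo_ser"] < quiet.median()
        assert ((bp >= 0) & (bp <= 1)).all()


class TestExclusion:
    @pytest.fixture
    def setup(self, species_tree, clades):
        model = FamilyRateModel(0.002, 2.0, 30)
        return species_tree, clades, model

    def test_no_net_change_when_caecilians_match_ancestor(self, setup):
        tree, clades, model = setup
        counts = pd.DataFrame(
            {sp: [2] for sp in tree.leaf_labels}, index=["OG0"]
        )
        out = exclusion_filter(tree, counts, clades, model)
        assert out["OG0"] == "no_net_change"

    def test_sparse_family_is_insufficient_sampling(self, setup):
        tree, clades, model = setup
        row = {sp: 0 for sp in tree.leaf_labels}
        row["Dan_rer"] = 1
        row["Geo_ser"] = 2
        counts = pd.DataFrame({sp: [row[sp]] for sp in tree.leaf_labels}, index=["OG0"])
        out = exclusion_filter(tree, counts, clades, model)
        assert out["OG0"] == "insufficient_sampling"

    def test_planted_expansion_is_analyzed(self, setup):
        tree, clades, model = setup
        row = {sp: 2 for sp in tree.leaf_labels}
        row["Geo_ser"] = 9
        counts = pd.DataFrame({sp: [row[sp]] for sp in tree.leaf_labels}, index=["OG0"])
        out = exclusion_filter(tree, counts, clades, model)
        assert out["OG0"] == "analyzed"
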