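"""Selection-scan operations: decomposition, alignment choice, filters, LRTs."""

import numpy as np
import pytest

from caecevo.codon import BranchPartition, SiteClassModel, uniform_frequencies
from caecevo.selection import (
    GeneFamily,
    SelectionResult,
    alignment_distance,
    alignment_quality_score,
    call_selection,
    concordance_and_size_filter,
    decompose_to_sgo,
    homology_pairs,
    lrt,
    select_alignment,
    branch_site_test,
)
from caecevo.simulate import (
    component_rng,
    default_codon_tree,
    default_foreground,
    perturb_alignment,
    simulate_codon_alignment,
)
from caecevo.trees import parse_newick


class TestDecomposition:
    def test_single_copy_family_passes_through(self):
        fam = GeneFamily("OG1", {"a1": "A", "b1": "B", "c1": "C"})
        assert decompose_to_sgo(fam) == [{"a1": "A", "b1": "B", "c1": "C"}]

    def test_single_species_duplication_drops_that_species(self):
        fam = GeneFamily("OG1", {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        assert decompose_to_sgo(fam) == [{"b1": "B", "c1": "C"}]

    def test_gene_tree_cut_into_maximal_single_copy_clades(self):
        tree = parse_newick("((a1,b1),(a2,c1));")
        fam = GeneFamily(
            "OG1", {"a1": "A", "a2": "A", "b1": "B", "c1": "C", "b2": "B"},
        )
        fam.genes = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        fam.tree = tree
        groups = decompose_to_sgo(fam)
        assert {frozenset(g) for g in groups} == {
            frozenset({"a1", "b1"}),
            frozenset({"a2", "c1"}),
        }

    def test_missing_gene_tree_is_error(self):
        fam = GeneFamily("OG1", {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError, match="gene tree"):
            decompose_to_sgo(fam)


class TestHomologyPairs:
    def test_ungapped_pair_has_one_statement_per_column(self):
        stmts = homology_pairs({"X": "ACGT", "Y": "ACGA"})
        assert len(stmts) == 4
        assert all(s[0] == "res" for s in stmts)

    def test_hand_worked_gap_example(self):
        stmts = homology_pairs({"X": "ACG", "Y": "A-G"})
        assert stmts == {
            ("res", ("X", 1), ("Y", 1)),
            ("res", ("X", 3), ("Y", 2)),
            ("gap", ("X", 2), "Y"),
        }

    def test_invariant_under_all_gap_column_padding(self):
        a = {"X": "ACG", "Y": "A-G"}
        b = {"X": "AC-G", "Y": "A--G"}
        assert homology_pairs(a) == homology_pairs(b)


class TestAlignmentDistance:
    def test_identical_alignments_give_zero(self):
        a = {"X": "AC-G", "Y": "ACTG"}
        assert alignment_distance(a, a) == 0.0

    def test_hand_worked_two_thirds(self):
        a1 = {"X": "ACG", "Y": "A-G"}
        a2 = {"X": "ACG", "Y": "AG-"}
        assert alignment_distance(a1, a2) == pytest.approx(2 / 3)

    def test_symmetry(self):
        a1 = {"X": "AC-G", "Y": "ACTG"}
        a2 = {"X": "A-CG", "Y": "ACTG"}
        assert alignment_distance(a1, a2) == alignment_distance(a2, a1)

    def test_different_sequences_is_error(self):
        with pytest.raises(ValueError, match="differ"):
            alignment_distance({"X": "ACG"}, {"X": "ACT"})


class TestQualityScore:
    def test_identical_rows_score_one(self):
        assert alignment_quality_score({"a": "ACGT", "b": "ACGT", "c": "ACGT"}) == 1.0

    def test_fully_mismatched_rows_score_zero_nt(self):
        assert alignment_quality_score({"a": "AAAA", "b": "CCCC"}) == 0.0

    def test_three_rows_one_mismatching_column(self):
        # four identical columns (pair similarity 1) and one column where a
        # single row differs (1 of 3 pairs identical): (4*3 + 1) / (5*3)
        aln = {"a": "ACGTA", "b": "ACGTA", "c": "ACGTC"}
        assert alignment_quality_score(aln) == pytest.approx(13 / 15)

    def test_single_sequence_is_error(self):
        with pytest.raises(ValueError):
            alignment_quality_score({"a": "ACGT"})

    def test_amino_acid_mode_uses_scaled_similarity(self):
        ident = alignment_quality_score({"a": "MKV", "b": "MKV"}, alphabet="aa")
        similar = alignment_quality_score({"a": "MKV", "b": "MKI"}, alphabet="aa")
        distant = alignment_quality_score({"a": "MKV", "b": "MKD"}, alphabet="aa")
        assert ident > similar > distant


class TestSelectAlignment:
    def test_identical_candidates_keep_first(self):
        a = {"X": "AC-G", "Y": "ACTG"}
        idx, record = select_alignment([a, dict(a)])
        assert idx == 0 and record["reason"] == "below_threshold"

    def test_empty_candidate_list_is_error(self):
        with pytest.raises(ValueError):
            select_alignment([])

    def test_true_alignment_beats_perturbed_decoy(self):
        tree = parse_newick("((A:0.05,B:0.05):0.02,(C:0.06,D:0.06):0.02);")
        model = SiteClassModel("M1Neutral", 2.0, uniform_frequencies(), 0.5)
        rng = component_rng(99, "codon")
        wins = 0
        n_trials = 20
        for trial in range(n_trials):
            aln = simulate_codon_alignment(tree, model, None, n_codons=100, rng=rng)
            seqs = aln.to_nucleotide()
            ids = sorted(seqs)
            for rid in (ids[0], ids[2]):
                start = int(rng.integers(10, 80)) * 3
                s = seqs[rid]
                seqs[rid] = s[:start] + "-" * 9 + s[start + 9:]
            decoy = perturb_alignment(seqs, 0.2, seed=trial)
            order = [seqs, decoy] if trial % 2 == 0 else [decoy, seqs]
            chosen, _ = select_alignment(order, threshold=0.05)
            wins += chosen == (0 if trial % 2 == 0 else 1)
        assert wins >= 0.9 * n_trials


class TestConcordanceFilter:
    def test_concordant_tree_with_enough_taxa_passes(self, codon_tree):
        genes = {f"{sp}_g": sp for sp in codon_tree.leaf_labels}
        gtree = parse_newick(codon_tree.to_newick())
        for leaf in gtree.dtree.leaf_node_iter():
            leaf.taxon.label += "_g"
        ok, reason = concordance_and_size_filter(genes, gtree, codon_tree)
        assert ok and reason == "pass"

    def test_too_few_taxa_fails_with_reason(self):
        species = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
        sub = species.restrict({"A", "B", "C", "D", "E", "F"})
        genes = {f"{sp}_g": sp for sp in sub.leaf_labels}
        gtree = parse_newick(sub.to_newick())
        for leaf in gtree.dtree.leaf_node_iter():
            leaf.taxon.label += "_g"
        ok, reason = concordance_and_size_filter(genes, gtree, species)
        assert not ok and reason.startswith("min_taxa")

    def test_discordant_tree_fails_with_rf_reason(self, codon_tree):
        rng = component_rng(1, "gene_trees")
        from caecevo.simulate import _random_nni

        gtree = _random_nni(codon_tree, rng)
        genes = {f"{sp}_g": sp for sp in codon_tree.leaf_labels}
        for leaf in gtree.dtree.leaf_node_iter():
            leaf.taxon.label += "_g"
        ok, reason = concordance_and_size_filter(genes, gtree, codon_tree)
        assert not ok and reason.startswith("RF=")


class TestLRT:
    def test_zero_statistic_gives_p_one(self):
        assert lrt(10.0, 10.0, 1) == 1.0

    def test_chi2_critical_values(self):
        assert lrt(1.9205, 0.0, 1) == pytest.approx(0.05, abs=5e-4)
        assert lrt(2.9955, 0.0, 2) == pytest.approx(0.05, abs=5e-4)

    def test_df_below_one_is_error(self):
        with pytest.raises(ValueError):
            lrt(1.0, 0.0, 0)

    def test_negative_statistic_clamped(self):
        assert lrt(1.0, 2.0, 1) == 1.0


class TestCallSelection:
    def result(self, p1, p2, omega2=3.0):
        return SelectionResult("og", "lin", -10, -10, -9, p1, p2, omega2, 2.0)

    def test_both_tests_required(self):
        out = call_selection([self.result(0.001, 0.2)], alpha=0.05, m=1)
        assert not out[0].selected

    def test_threshold_arithmetic(self):
        out = call_selection([self.result(0.004, 0.003)], alpha=0.05, m=10)
        assert out[0].selected
        assert out[0].p_adjusted == pytest.approx(0.04)

    def test_all_p_one_gives_zero_calls(self):
        out = call_selection([self.result(1.0, 1.0) for _ in range(5)], alpha=0.05)
        assert not any(r.selected for r in out)

    def test_omega_above_one_required(self):
        out = call_selection([self.result(1e-6, 1e-6, omega2=0.9)], alpha=0.05, m=1)
        assert not out[0].selected

    def test_invalid_m_is_error(self):
        with pytest.raises(ValueError):
            call_selection([self.result(0.5, 0.5)], m=0)


class TestModelFits:
    def test_nesting_and_power_on_positive_data(self, codon_tree, foreground):
        pi = uniform_frequencies()
        true = SiteClassModel("ModelA", 2.5, pi, 0.425, p1=0.425, omega2=5.0)
        aln = simulate_codon_alignment(
            codon_tree, true, foreground, n_codons=400, seed=11
        )
        res = branch_site_test(aln, codon_tree, foreground)
        assert res.lnl_alt >= res.lnl_m1 - 1e-6
        assert res.lnl_alt >= res.lnl_null - 1e-3
        assert res.omega2 > 1.0
        assert res.p_vs_m1 < 0.05 and res.p_vs_null < 0.05

    def test_null_data_is_not_called(self, codon_tree, foreground):
        pi = uniform_frequencies()
        null = SiteClassModel("M1Neutral", 2.5, pi, 0.5)
        aln = simulate_codon_alignment(codon_tree, null, None, n_codons=200, seed=12)
        res = branch_site_test(aln, codon_tree, foreground)
        assert max(res.p_vs_m1, res.p_vs_null) > 0.05
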