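"""Enhancer conservation scan: extraction, local alignment, motifs, panel."""

import numpy as np
import pytest

from caecevo.enhancer import (
    AnnotatedGenome,
    conservation_fraction,
    extract_intergenic,
    extract_intron,
    genome_wide_search,
    local_align,
    motif_scan,
    revcomp,
    scan_species_panel,
    smith_waterman,
)
from caecevo.simulate import EnhancerSpeciesSpec, _random_seq, simulate_enhancer_panel


def toy_genome(seq: str, gff_body: str) -> AnnotatedGenome:
    return AnnotatedGenome({"chr1": seq}, "##gff-version 3\n" + gff_body)


GFF_PLUS = (
    "chr1\tsim\tgene\t1\t30\t.\t+\t.\tID=g1\n"
    "chr1\tsim\tmRNA\t1\t30\t.\t+\t.\tID=g1.t1;Parent=g1\n"
    "chr1\tsim\texon\t1\t10\t.\t+\t.\tID=g1.e1;Parent=g1.t1\n"
    "chr1\tsim\texon\t21\t30\t.\t+\t.\tID=g1.e2;Parent=g1.t1\n"
)


class TestExtractIntron:
    def test_plus_strand_definition(self):
        seq = "A" * 10 + "CGCGCGCGCG" + "T" * 10
        genome = toy_genome(seq, GFF_PLUS)
        intron, coords = extract_intron(genome, "g1", 1, 2)
        assert intron == "CGCGCGCGCG"
        assert (coords["start1"], coords["end1"]) == (11, 20)
        assert (coords["start0"], coords["end0"]) == (10, 20)

    def test_minus_strand_reverse_complements(self):
        seq = "A" * 10 + "CCCCCAAAAA" + "T" * 10
        gff = GFF_PLUS.replace("\t+\t", "\t-\t")
        genome = toy_genome(seq, gff)
        intron, coords = extract_intron(genome, "g1", 1, 2)
        # exon ordinals count from the 3' genomic side on the minus strand
        assert intron == revcomp("CCCCCAAAAA")
        assert coords["strand"] == "-"

    def test_adjacent_exons_is_error(self):
        gff = GFF_PLUS.replace("21\t30", "11\t20")
        genome = toy_genome("A" * 30, gff)
        with pytest.raises(ValueError, match="adjacent"):
            extract_intron(genome, "g1", 1, 2)

    def test_missing_gene_is_error(self):
        genome = toy_genome("A" * 30, GFF_PLUS)
        with pytest.raises(KeyError, match="nope"):
            extract_intron(genome, "nope", 1, 2)

    def test_too_few_exons_is_error(self):
        genome = toy_genome("A" * 30, GFF_PLUS)
        with pytest.raises(ValueError, match="exons"):
            extract_intron(genome, "g1", 5, 6)


class TestExtractIntergenic:
    GFF = (
        "chr1\tsim\tgene\t1\t50\t.\t+\t.\tID=gA\n"
        "chr1\tsim\tgene\t151\t200\t.\t+\t.\tID=gB\n"
    )

    def test_sequence_between_facing_boundaries(self):
        seq = "A" * 50 + "G" * 100 + "T" * 50
        genome = toy_genome(seq, self.GFF)
        inter, coords = extract_intergenic(genome, "gA", "gB")
        assert inter == "G" * 100
        assert coords["start1"] == 51 and coords["end1"] == 150

    def test_argument_order_does_not_matter(self):
        rng = np.random.default_rng(0)
        seq = "A" * 50 + _random_seq(rng, 100) + "T" * 50
        genome = toy_genome(seq, self.GFF)
        assert extract_intergenic(genome, "gA", "gB")[0] == extract_intergenic(genome, "gB", "gA")[0]

    def test_overlapping_genes_is_error(self):
        gff = self.GFF.replace("151\t200", "40\t90")
        genome = toy_genome("A" * 200, gff)
        with pytest.raises(ValueError, match="overlap"):
            extract_intergenic(genome, "gA", "gB")

    def test_different_contigs_is_error(self):
        gff = self.GFF.replace("chr1\tsim\tgene\t151", "chr2\tsim\tgene\t151")
        genome = AnnotatedGenome(
            {"chr1": "A" * 200, "chr2": "C" * 300}, "##gff-version 3\n" + gff
        )
        with pytest.raises(ValueError, match="contig"):
            extract_intergenic(genome, "gA", "gB")


class TestLocalAlign:
    def test_self_hit_covers_everything(self):
        rng = np.random.default_rng(1)
        q = _random_seq(rng, 120)
        hits = local_align(q, q, min_score=30)
        top = hits[0]
        assert top.score == len(q)
        assert top.identity == 1.0
        assert (top.qstart, top.qend) == (0, len(q))

    def test_reverse_complement_found_on_minus_strand(self):
        rng = np.random.default_rng(2)
        q = _random_seq(rng, 150)
        hits = local_align(q, revcomp(q), min_score=30)
        assert hits[0].strand == "-"
        assert hits[0].score == len(q)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_heuristic_matches_smith_waterman_on_planted_homology(self):
        rng = np.random.default_rng(3)
        agree = 0
        n = 40
        for _ in range(n):
            q = _random_seq(rng, 300)
            mutated = list(q)
            for k in range(len(mutated)):
                if rng.random() < 0.10:
                    mutated[k] = "ACGT"[rng.integers(4)]
            subject = _random_seq(rng, 600) + "".join(mutated) + _random_seq(rng, 600)
            h = local_align(q, subject, min_score=25)
            s = smith_waterman(q, subject)
            assert h[0].score <= s[0].score + 1e-9  # heuristic never beats the optimum
            agree += h[0].score == s[0].score
        assert agree == n

    def test_strand_symmetry(self):
        rng = np.random.default_rng(4)
        q = _random_seq(rng, 200)
        subject = _random_seq(rng, 300) + q + _random_seq(rng, 300)
        fw = local_align(q, subject, min_score=25)
        rv = local_align(q, revcomp(subject), min_score=25)
        assert fw[0].score == rv[0].score
        assert {h.strand for h in fw[:1]} != {h.strand for h in rv[:1]}


class TestConservationFraction:
    def test_identical_sequences_give_one(self):
        rng = np.random.default_rng(5)
        q = _random_seq(rng, 400)
        assert conservation_fraction(q, q) == 1.0

    def test_random_subject_gives_near_zero(self):
        rng = np.random.default_rng(6)
        q = _random_seq(rng, 800)
        fractions = [
            conservation_fraction(q, _random_seq(np.random.default_rng(600 + s), 10000))
            for s in range(5)
        ]
        assert max(fractions) < 0.1

    def test_monotone_in_mutation_rate(self):
        rng = np.random.default_rng(7)
        q = _random_seq(rng, 600)
        fractions = []
        for rate in (0.0, 0.1, 0.2, 0.3, 0.4):
            mut = [
                ("ACGT"[rng.integers(4)] if rng.random() < rate else ch) for ch in q
            ]
            subject = _random_seq(rng, 200) + "".join(mut) + _random_seq(rng, 200)
            fractions.append(conservation_fraction(q, subject))
        assert fractions[0] == 1.0
        assert all(a >= b - 0.05 for a, b in zip(fractions, fractions[1:]))


class TestGenomeWideSearch:
    def test_relocated_element_found_on_other_contig(self):
        rng = np.random.default_rng(8)
        q = _random_seq(rng, 300)
        genome = AnnotatedGenome(
            {"chr1": _random_seq(rng, 2000), "chr2": _random_seq(rng, 500) + q + _random_seq(rng, 500)},
            "##gff-version 3\n",
        )
        hits = genome_wide_search(q, genome)
        assert hits[0].contig == "chr2"

    def test_mutation_tolerant_detection(self):
        rng = np.random.default_rng(9)
        found = 0
        for s in range(10):
            q = _random_seq(rng, 400)
            mut = "".join(
                "ACGT"[rng.integers(4)] if rng.random() < 0.10 else ch for ch in q
            )
            genome = AnnotatedGenome(
                {"chr1": _random_seq(rng, 1000) + mut + _random_seq(rng, 1000)},
                "##gff-version 3\n",
            )
            found += bool(genome_wide_search(q, genome))
        assert found >= 9.5 * 10 / 10  # >= 95% of trials

    def test_absent_element_gives_empty(self):
        rng = np.random.default_rng(10)
        q = _random_seq(rng, 500)
        genome = AnnotatedGenome({"chr1": _random_seq(rng, 3000)}, "##gff-version 3\n")
        assert genome_wide_search(q, genome, min_score=60) == []


class TestMotifScan:
    def test_planted_core_found(self):
        seq = "C" * 17 + "GGAT" + "C" * 10
        assert (17, "+") in motif_scan(seq, "GGAW")

    def test_minus_strand_only(self):
        # revcomp of GGAW is WTCC; plant ATCC (no GGAW on the forward strand)
        seq = "CCCCC" + "ATCC" + "CCCCC"
        hits = motif_scan(seq, "GGAW")
        assert hits and all(strand == "-" for _, strand in hits)

    def test_no_occurrence_gives_empty(self):
        assert motif_scan("CCCCCCCC", "GGAW") == []

    def test_invalid_iupac_letter_is_error(self):
        with pytest.raises(ValueError, match="IUPAC"):
            motif_scan("ACGT", "GGAX")


class TestSpeciesPanel:
    @pytest.fixture(scope="class")
    @staticmethod
    def panel():
        specs = {
            "sp_intact1": EnhancerSpeciesSpec(),
            "sp_intact2": EnhancerSpeciesSpec(),
            "sp_intact3": EnhancerSpeciesSpec(),
            "sp_intact4": EnhancerSpeciesSpec(),
            "sp_mut": EnhancerSpeciesSpec(mutation_rate=0.15),
            "sp_del": EnhancerSpeciesSpec(deleted=True),
        }
        return simulate_enhancer_panel(specs, seed=21)

    def test_planted_panel_pattern(self, panel):
        genomes, truth, queries = panel
        recipe = {sp: {"kind": "intron", "gene": "LMBR1", "exons": (5, 6)} for sp in genomes}
        records = {
            r.species: r
            for r in scan_species_panel(queries["zrs"], genomes, recipe=recipe)
        }
        for sp in ("sp_intact1", "sp_intact2", "sp_intact3", "sp_intact4"):
            assert records[sp].fraction > 0.95
            assert records[sp].motif_present
        assert 0.2 < records["sp_mut"].fraction < 0.98
        assert records["sp_del"].fraction == 0.0
        assert not records["sp_del"].motif_present

    def test_extraction_failure_is_recorded_not_fatal(self, panel):
        genomes, _, queries = panel
        recipe = {sp: {"kind": "intron", "gene": "MISSING", "exons": (5, 6)} for sp in genomes}
        records = scan_species_panel(queries["zrs"], genomes, recipe=recipe)
        assert all(r.status.startswith("extraction_failed") for r in records)
        # the genome-wide fallback still finds the intact elements
        by_sp = {r.species: r for r in records}
        assert by_sp["sp_intact1"].fraction > 0.95

    def test_intergenic_control_is_intact_everywhere(self, panel):
        genomes, _, queries = panel
        recipe = {sp: {"kind": "intergenic", "genes": ("DLX1", "DLX2")} for sp in genomes}
        records = scan_species_panel(queries["i12a"], genomes, recipe=recipe)
        assert all(r.fraction > 0.95 for r in records)
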