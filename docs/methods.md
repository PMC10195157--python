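# Methods

This note documents the models, their assumptions, the synthetic-data
conditions, and the numerical and design choices behind `caecevo`. It states
nothing the test suite or `scripts/acceptance.py` does not itself compute.

## Trees and topology comparison

Trees are stored rooted (dendropy carrier) with unique leaf labels and
non-negative finite branch lengths; missing lengths are recorded as absent,
never as zero. Robinson–Foulds distances are computed on the unrooted form:
one bipartition per internal edge, trivial splits excluded. Polytomies are
treated as hard — a polytomous tree contributes fewer bipartitions, so an
RF distance of 0 requires the gene tree to be both fully compatible with and
equally resolved as the reference. Branch-length units are deliberately not
interpreted by this layer: the family-dynamics model reads them as time
(million years in the default tree), the codon models as expected
substitutions per site.

## Phylostratigraphic classification

"Present" means gene count ≥ 1; the filters are about species representation,
not copy number. Filters are applied in a fixed order with first-match-wins
(amphibian-wide loss, then caecilian-only loss, then caecilian-absent but
amphibia+amniota present), which makes the classes disjoint and exhaustive by
construction. "Tetrapod" in the caecilian-only-loss filter means the
non-caecilian tetrapods (frogs + salamanders + amniotes); the clade
membership is explicit configuration, never hard-coded, so the species
universe can be redefined freely.

## Birth–death gene-family model

State space: family size 0..`max_count`, default truncation 2×(max observed)
+ 10; a truncation-stability check (log-likelihood change < 1e−8 when the
bound is grown) is part of the test suite. The transition kernel is the
closed-form equal-rate birth–death probability (zero is absorbing); the
likelihood is a pruning pass over count states with the root marginalised
against a Poisson prior. λ and the root-prior mean are estimated jointly by
bounded quasi-Newton on log scale, initialised from 1/tree-depth and the mean
tip count. A single global λ with equal birth and death rates is used; a
per-branch λ was considered and not implemented at this scale (one rate is
identifiable and sufficient for the synthetic conditions; the summary reports
would hide per-branch uncertainty otherwise).

Ancestral counts are **marginal** maximum-a-posteriori states from an up–down
pass; ties break toward the smaller count (numpy argmax keeps the first
index). Reconstruction is invariant to tip order.

Per-family significance is Monte-Carlo: p = fraction of null families whose
log-likelihood under the fitted model is at most the observed family's. Two
conventions matter and are deliberate:

* the null families are conditioned on **observability** (at least one
  non-zero tip), because an orthogroup table can only ever contain families
  observed somewhere; without this conditioning the all-zero profile is an
  atom of mass e^(−root mean) and the p-values cannot be uniform;
* each family gets an **independent** null sample (seeded), because sharing
  one null sample across families makes their p-values strongly correlated
  (the common Monte-Carlo error shifts all of them together) and visibly
  distorts uniformity at a few hundred families.

The exclusion rules run before significance testing: `no_net_change` when
every caecilian tip equals the reconstructed count at the amphibian MRCA
(checked first), then `insufficient_sampling` when fewer than
`min_species_present` (default 4 — a convention, flagged as such in reports)
species have non-zero counts.

## Branch-site codon models

Rate matrix: GY94 structure over the 61 sense codons — zero for
multi-nucleotide changes, π_j for synonymous transversions, κπ_j for
synonymous transitions, ω-scaled for nonsynonymous changes; reversible with
respect to π, so transition matrices come from a symmetrised
eigendecomposition rather than repeated `expm` calls. Each class/partition
matrix is divided by one common factor chosen so the expected rate over site
classes (at the background ω, under π) is 1; branch lengths are therefore
expected substitutions per site under the background mixture.

Site classes: M1Neutral has (ω₀=0, p₀) and (ω₁=1, 1−p₀). ModelA and its null
add classes 2a/2b whose background ω stays 0 or 1 while the foreground takes
ω₂ (free in [1, 50] for ModelA, [0, 1] for the null); p₂ = 1−p₀−p₁ is split
2a:2b in proportion p₀:p₁. ω₀ is fixed at 0 by default; an estimated-ω₀
variant is available through the `omega0` argument. Codon frequencies default
to F3×4 with a 0.5 pseudo-count and a 1e−6 floor (uniform mode provided for
oracle tests). Gaps and ambiguous codons are missing data, marginalised in
the pruning pass; in-frame stops are validation errors naming the sequence
and site.

Fitting: parameters are transformed to an unconstrained scale (log κ, log
scale, stick-breaking for proportions, log(ω₂−1) or logit ω₂) and optimised
with L-BFGS-B; site patterns are compressed before pruning. The nested chain
is fitted in order M1Neutral → ModelA-null → ModelA, each warm-started from
the previous optimum (with a small p₂ perturbation for the embedding), with a
single guarded restart if a fitted log-likelihood falls below its nested
predecessor. Note that ModelA (ω₂ ≥ 1) and ModelA-null (ω₂ ≤ 1) overlap only
at ω₂ = 1, so their log-likelihoods are not strictly ordered; the LRT
statistic is clamped at zero. Degrees of freedom: 2 for ModelA vs M1Neutral,
1 for ModelA vs its null, plain χ² (no boundary mixture) — the simplest
standard reading; the clamping makes the test conservative at the boundary.

Branch lengths are re-estimated through a single global scale on the input
tree (full per-branch optimisation would add ~2n parameters per fit for no
benefit under the concordance filter, which guarantees the input topology).

## Selection-scan filters

Single-copy decomposition: a species-specific duplication (duplicates
confined to one species and monophyletic on the gene tree, or no tree
available) drops that species; deeper paralogy cuts the gene tree into
maximal clades containing each species at most once (top-down traversal,
equivalent to largest-clade-first, input-order deterministic). Singleton
leftovers are kept only if caecilian-specific.

Alignment comparison uses homology statements — per column, residue~residue
or residue~gap facts keyed by (sequence, residue ordinal), hence invariant to
all-gap-column padding — and the symmetric-difference distance
d = |H₁ Δ H₂| / (|H₁| + |H₂|). The selection rule keeps the first candidate
(the consensus) unless the maximum pairwise distance reaches the 5%
threshold, in which case the candidate with the highest normalised
mean-of-pairs column score wins (identity for nucleotides, BLOSUM62 rescaled
to [0,1] for amino acids; ties keep input order). The mean-pairwise distance
is available via `metric="mean"`; max is the default because a single bad
candidate should be enough to trigger score-based arbitration.

Concordance filter: gene-tree leaves are relabelled to species, the species
tree is restricted to those species, and the family passes only with RF = 0
and ≥ 7 species. The Bonferroni family size m defaults to the number of
(family × lineage) tests actually run and is recorded in the output.

## Enhancer scan

Internally all coordinates are 0-based half-open; user-facing tables are
1-based inclusive with the convention named. Intron extraction counts exon
ordinals 5′→3′ in transcription order on the longest transcript and
reverse-complements minus-strand genes; intergenic extraction sorts the two
genes by genomic position and orients the window with the downstream gene's
strand, so argument order never matters.

The local aligner seeds on exact 11-mers, groups seeds by diagonal, and
polishes each candidate window with an affine-gap local alignment (match +1,
mismatch −2, gap open −2, gap extend −1 — blastn-like at desk scale; a gap of
length L costs open + L·extend). Non-overlapping hits are kept greedily by
score so query coverage is never double-counted. The full Smith–Waterman mode
is the correctness oracle; on planted-homology benchmarks the heuristic's top
score equals the optimum. Conservation fraction = query positions covered by
identically aligned residues across accepted hits (the bar heights in the
per-species report); the motif check (IUPAC, both strands; default ETS core
`GGAW`) runs only inside the recovered region, so an excised element scores
motif-absent even though short degenerate motifs occur by chance in any
random window. E-values are not computed; raw scores plus a minimum-score
threshold (default 30) gate reporting.

## Synthetic data: what it emulates, what it does not

One top-level seed is split per component through a fixed component-index
table (numpy `SeedSequence(seed, spawn_key=(index,))`), so adding a generator
never shifts existing draws. Truth tables are always written beside the data.

Default conditions: a 12-taxon time-scaled vertebrate tree (2 fish, 2 frogs,
3 caecilians, 5 amniotes; caecilian crown ~125 My, root ~430 My); family
turnover λ = 0.002 per gene per My with Poisson root mean 2.0 (typical CAFE-
scale turnover, giving a realistic mix of static and changing families);
codon simulations on an 8-taxon substitution-scaled tree with κ = 2.5, and
ω₂ = 5 carried by 15% of sites on the caecilian foreground for
positive-selection scenarios. Enhancer panels plant an 800-bp element (with
an ETS-like core) inside the intron between exons 5 and 6 of an LMBR1-like
8-exon gene and a 500-bp control between a DLX1/DLX2-like pair; per-species
treatments are point mutation at a stated rate, excision, relocation to
another contig, or a minus-strand gene arrangement.

The generators do **not** emulate: indel evolution inside codon alignments
(gaps are planted, not evolved), alignment-estimation error (the "true"
alignment is known), annotation noise in the count tables, repeat landscapes
or assembly artifacts in the toy genomes, or rate variation across branches.
Passing tests therefore demonstrate correctness and calibration of the
inference machinery under its own assumptions — not robustness to the
violations real genomes add.

The alignment perturbation used for decoys relocates gap characters by short
random shifts until the homology disagreement with the original reaches the
requested rate (so "rate" is on the same scale as the 5% selection
threshold), leaving ungapped sequences untouched.

## Problem sizes used in validation

Oracle checks run on ≤4-taxon count trees (exhaustive enumeration), 3-taxon /
3-codon alignments (61²-term enumeration), 70-state generator exponentials,
≤7-leaf tree pairs, and ≤2-kb planted-homology alignment instances.
Calibration uses 50 null alignments (8 taxa × 200 codons) for the branch-site
LRTs and 200 null families (100 Monte-Carlo replicates each) for the
family-dynamics p-values. Parameter recovery uses 500 families × 12 taxa
(5 seeds, median) for λ and 20 replicates of 600 codons × 8 taxa for ω₂.
These sizes were chosen as the smallest at which the statistical assertions
are stable across seeds.

## Known limitations

* Gene-family rates: one global λ; no error model for annotation noise and no
  gamma rate variation across families.
* Branch-site machinery: no Bayes-Empirical-Bayes site identification; plain
  χ² reference distributions (conservative at the ω₂ = 1 boundary).
* Local alignment: no E-value statistics; the heuristic can miss homologies
  with no exact 11-mer seed (mutation rates ≳ 30%).
* The Monte-Carlo family p-value is family-wide, not branch-specific; a
  per-branch transition-probability report
  (`BirthDeathFamilyResults.branch_pvalues`) accompanies it rather than
  replacing it, and neither is privileged.
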