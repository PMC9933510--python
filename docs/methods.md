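# Methods

## SSR detection and canonical motif classes

A microsatellite is reported when a perfect tandem repeat of an
irreducible 1–6 bp motif reaches the survey thresholds (defaults: 10
repeats for mononucleotide motifs, 6 for dinucleotide, 5 for tri- to
hexanucleotide; all configurable per motif length). Loci are maximal
perfect runs: left- and right-maximal, truncated to whole motif copies,
reported at the leftmost phase of the run with the motif as spelled
there. `N` breaks a run. A reducible motif (`ATAT`) is always reported
as its shortest period (`AT`). When one reported locus fully contains
another, the nested locus is suppressed, preferring the shorter motif
on identical spans; by the periodicity (Fine–Wilf) argument genuine
containment between threshold-passing loci of different periods is
essentially impossible, so this rule is defensive disambiguation rather
than a frequent code path. Neighbouring loci separated by at most
`max_interruption` bases (default 100 bp) share a compound-group label.
Coordinates are 1-based inclusive everywhere in memory and on disk; the
test suite checks the detector against an independent regex brute-force
scan on random and repeat-dense sequences.

The canonical class of a motif is `X/Y` where `X` is the
lexicographically smallest cyclic rotation of the motif or of its
reverse complement and `Y = revcomp(X)`; this partitions the 12
irreducible dinucleotides into 4 classes and the 60 trinucleotides into
10 classes of 6, and makes mining strand-invariant at the class level.

## Candidate polymorphic SSRs across assemblies

For each reference SSR, up to `flank_length` bases (default 100) are
taken on each side; a locus whose flanks are both shorter than 20 bp
carries too little anchor sequence and is skipped as unusable. Each
flank is located in every query assembly by infix edit-distance
alignment (edlib in HW mode); a hit requires both flanks in the same
query sequence, downstream after upstream, each with identity
≥ `min_identity` and query-span coverage ≥ `min_coverage` (defaults
95/95 — the published defaults of the reference pipeline for this step;
the method itself fixes no values). Ties break deterministically:
lowest total edit distance, then lowest sequence id, then leftmost.
The interval between the matched flanks is re-scanned for a repeat of
the same canonical class with the repeat floor relaxed to 3, because a
real query allele may shrink below the mining threshold; without the
relaxation shrinking alleles would register as misses and inflate the
miss rate. A locus becomes a candidate when the sample standard
deviation (n−1 denominator) of its available repeat counts exceeds 0
and its miss rate — missing queries over the number of query
assemblies — is at most 0.5. The reference always contributes a count,
so it is excluded from the miss-rate denominator.

## Diversity statistics

Per locus, with allele frequencies `p_i` estimated from the 2N allele
draws of the N typed accessions (missing calls excluded locus by
locus): Na = number of alleles; Ne = 1/Σp²; I = −Σp ln p (natural
log); Ho = heterozygous/typed; Nei = 1−Σp²; He = 2N/(2N−1)·Nei
(unbiased); PIC = 1−Σp²−Σ_{i<j}2p²_ip²_j (Botstein). These are the
definitions implemented by the standard population-genetics packages
for codominant data; printed tables round half-away-from-zero to two
decimals while full precision is kept internally. Identities such as
Ne·(1−Nei) = 1 and the biallelic PIC ceiling of 0.375 are enforced by
property tests.

## Core selection

*M strategy* — greedy set cover over (locus, allele) pairs: repeatedly
add the accession contributing the most uncovered alleles until all are
covered. Ties break by the larger resulting mean gene diversity, then
by lexicographic accession id, making the output deterministic. The
size is data-driven and coverage is 100% by construction.

*Simulated annealing* — fixed-size subsets explored by single-accession
swap moves under Metropolis acceptance with geometric cooling
(default 200 steps × one move per accession per step, cooling 0.95).
The initial temperature, when not given, is calibrated so that about
half of the worsening moves observed on a 50-move random prefix are
accepted (median worsening / ln 2). Objectives: total distinct alleles
(allele-number criterion) or mean per-locus Nei gene diversity
(gene-diversity criterion). The defaults solve 6-choose-3 instances to
the exhaustive optimum, which the tests verify.

*Mixed objective* — `w_MR · mean pairwise Modified Rogers distance +
w_SH · SH(subset)/SH(full)`, where SH = −Σ_loci Σ_alleles p ln p over
subset frequencies. Normalizing SH by the full collection's value puts
both terms on comparable scales (mean MR is already in [0, 1]); the
normalization constant is a design choice of this package. The
Modified Rogers distance between two accessions is
`sqrt((1/2L) Σ_loci Σ_alleles (x − y)²)` with within-individual allele
"frequencies" 0/0.5/1 and L the pairwise-typed locus count; it is a
metric on complete genotype vectors (property-tested).

## Evaluation

Core-vs-full comparison computes per-locus diversity on both sets and
runs a two-sided Welch t-test per parameter across loci (a paired test
is available behind a flag, since the loci are shared; with identical
means both variants agree on non-significance, which is the scientific
question being asked). Identical value vectors short-circuit to p = 1.
No multiple-testing correction is applied across the seven parameters,
matching how such comparison tables are conventionally presented.
PCoA is classical metric scaling — eigendecomposition of the
Gower-centered squared-distance matrix (delegated to scikit-bio behind
this module's interface) — with coordinates built from positive
eigenvalues only, negative eigenvalues reported, and truncation with a
warning when more axes are requested than positive eigenvalues exist;
the tests verify it against an independent hand-rolled
double-centering eigendecomposition and closed-form geometry.

## Synthetic data

The assembly generator emulates transcriptome assemblies of related
varieties: a reference unigene set (default 200 unigenes of
300–1500 bp) with planted SSRs (one per selected unigene; motifs drawn
from a pool; repeat counts uniform within per-motif-length ranges at or
above the detection thresholds), plus replicate assemblies where each
planted repeat shifts its count with probability `repeat_shift_prob`,
flanks carry per-base substitution noise, and whole unigenes drop out
with probability `dropout_prob`. Backgrounds and flanks are rejection
sampled to contain no threshold-passing SSR and planting is verified by
re-mining, so the truth table is unambiguous and mining the reference
recovers 100% of planted loci at exact coordinates. The shift rule
draws the repeat-count delta uniformly from the feasible subset of
{−2, −1, +1, +2} (feasible: the new count stays at or above the
threshold), so a shift always differs from the reference and the
probability a locus is truth-polymorphic is exactly
1 − (1 − p)^(n_assemblies − 1); the binomial-bound tests recompute
expectations from this rule. Noise rates default to 1% flank
substitution and 2% dropout — typical of the divergence between
de novo assemblies of closely related cultivars at homologous loci —
and shift probability 0.5 so polymorphic and monomorphic loci are both
well represented.

The genotype generator draws diploid calls per locus from specified
allele-frequency spectra (or flat-Dirichlet spectra over 2–5 alleles,
the allele range of narrow-base ornamental SSR panels) under
Hardy–Weinberg proportions; 160 accessions × 40 loci with 2% missing
data is the study-scale default used throughout the tests and the
acceptance script. `target_ho` instead draws heterozygote/homozygote
status as Bernoulli(target_ho) and the alleles from the HWE-conditional
distributions; this hits the observed-heterozygosity target exactly in
expectation, mirroring real SSR panels where Ho departs strongly from
HWE, at the cost of slightly distorting marginal allele frequencies
when the target is far from the HWE value — the frequency-convergence
guarantee is stated for the default HWE mode. All randomness flows from
the single config seed through one generator; outputs record the seed.

What the generators do not emulate: read-level sequencing error,
assembly chimerism or fragmentation, null alleles and allele dropout
correlated with genotype, linkage between loci, and population
structure among accessions. Passing tests therefore demonstrate the
correctness of the algorithms under the stated model, not robustness to
every artifact of real transcriptome or gel data.

## Problem sizes and numerical choices

Tests run the full stack at the study scale (160 × 40 genotypes;
tens of unigenes with planted SSRs) and use 10⁴-accession draws for
parameter-recovery checks, with delta-method standard errors (plus a
2/n curvature allowance where the first-order term vanishes, e.g. Ne at
equal frequencies). Annealing oracle checks use 6-choose-3 instances
where exhaustive search is exact. Frequency vectors must sum to 1
within 1e-9; PCoA distance reproduction is asserted at 1e-9;
eigenvalues below 1e-12 are treated as zero. Monomorphic loci are
valid inputs (all statistics 0 except Na = Ne = 1), and a locus with no
typed accession is an error rather than a silent NaN.
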