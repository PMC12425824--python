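# Methods

## Scope and model of the data

The package analyzes three desk-scale data modalities: a sparse peak × cell
scATAC-seq count matrix with peak GC content and motif membership, a sparse
gene × cell scRNA-seq count matrix with cluster labels, and a bulk cohort
table with survival outcomes. It is organized around one scientific
question: whether candidate transcription-factor motifs are preferentially
accessible where they co-occur with ETS-family motifs in a specific cell
state (the ERG⁺ intermediate, IM), and whether cell-state signatures carry
prognostic signal in bulk cohorts.

## Quality control

Boundary semantics are strict and deliberate. RNA: a cell is kept iff
`total ∈ [500, 100000]` and `mito_fraction < 0.40`; a zero-transcript cell
is treated as fully mitochondrial and removed with a warning rather than
raising, so degenerate synthetic inputs cannot abort a pipeline run. ATAC: a
cell is kept iff `tss_enrichment ≥ 4`, `fragments ≥ 1000` and
`reads ≤ 1e6`. Filtering is idempotent; all removals are counted in logs.

## Lineage assignment

Epcam positivity is defined as a detectable transcript (raw count ≥ 1); the
positivity threshold is not biologically canonical, so it is an explicit,
configurable choice. A cluster is epithelial when its Epcam⁺ fraction is
≥ 0.5 (inclusive). Expression is normalized as counts-per-10,000 + log1p —
a deterministic, conventional normalization chosen in place of
variance-stabilizing transforms, which are out of scope here. Signature
scores are mean per-gene z-scores of the normalized expression across cells;
zero-variance genes contribute 0, which gives the score two useful exact
properties (constant matrices score 0; adding a constant to the matrix
leaves scores unchanged). A simple mean z-score was preferred over
rank/bin-control scoring schemes because it is deterministic, needs no
control-gene sampling, and its value is exactly reproducible in tests.
Assignment takes the strictly maximal signature score among cells of flagged
clusters; exact ties and cells outside flagged clusters are `unassigned`.

Markers are derived label-vs-rest with the two-sample Wilcoxon rank-sum test
on log-normalized values, a log2 fold change of linear-scale group means
with pseudocount 1 (configurable), Benjamini–Hochberg FDR within each label,
and ranking by average log fold change among FDR-significant genes. BH is
used everywhere multiple tests are corrected. Signature selection keeps
genes with FDR < 0.05 and fold change strictly > 2; an empty result is an
empty signature with a warning, not an error.

## Motif accessibility deviations

For a member peak set S, raw deviation per cell is the ratio of observed
minus expected member counts to expected member counts, with the expectation
E_ij = row_i · col_j / total. The ratio form makes the statistic invariant
to global scaling of the matrix and free of extra per-cell depth weighting.

Background correction: peaks are embedded in standardized
(GC fraction, log1p mean accessibility) space; for each peak, one matched
partner per iteration is drawn uniformly from the tie-inclusive set of its
k nearest neighbors (self included; all peaks within the distance of the
k-th neighbor are candidates, so identical peaks are exchangeable — a
property the tests verify by chi-square). Defaults k = 50, B = 50
iterations, mirroring the cited method's conventions; both configurable.

The background set of iteration b is the **reflected** set
`{i : mapping_b(i) ∈ S}` — the peaks whose matched partner lies in S —
rather than the multiset of partners of S. Both constructions consist of
peaks GC/accessibility-matched to S (every source–partner pair lies within
the k-neighbor radius), but the reflected form has an exact closure
property: when S is the set of all peaks, every background set is again all
peaks, so the bias-corrected deviation of the all-peaks set is identically
zero on any matrix — the statistic provably reports no signal when asked
about everything. The partner-multiset form only satisfies this
approximately, because a multiset sampled with replacement is unbalanced.
d = y − mean_b(ỹ), z = d / sd_b(ỹ) with the sample (n−1) standard
deviation. Cells with zero background sd (or zero expected member mass) get
an undefined z recorded as missing, counted in logs, and excluded pairwise
downstream — silent NaN propagation would corrupt the rank tests.

Known limitation (shared by both background constructions): if a member set
forms an isolated island in matching space — e.g. every member peak far more
accessible than every non-member — backgrounds self-match into the member
set and absorb the signal. Realistic peak sets, and the synthetic
generator's, have overlapping accessibility distributions where recovery is
strong.

## Enrichment and retention filters

A cell is "motif-accessible" when its deviation z exceeds 0; the source
toolchain leaves this binarization implicit, so the threshold is an explicit
configurable stand-in. Per (motif, cell type) the upper-tail hypergeometric
p is computed from the accessible-cell overlap, BH-corrected across all
pairs; FDR < 10⁻²⁰ is a reporting cutoff (`enriched` flag) rather than a
hard filter, matching its display role. Candidate motifs are retained per
cell type only if the motif's gene has normalized mean expression strictly
> 1 there, and only if the Spearman correlation between the motif's
deviation z and its per-cell gene score is positive. The gene-score matrix
is an input: ATAC-derived gene activity or measured expression both work,
and which one was used is the caller's record. Differential accessibility
between cell groups uses the rank-sum test on depth-normalized counts with
the region rule FDR < 0.05 and log2FC ≥ 0.5 (inclusive at 0.5).

## Co-occurrence co-accessibility test

ERG/ETS/ETV/FLI memberships are OR-reduced to one ETS family column. For a
candidate motif the peaks carrying candidate and/or ETS are partitioned into
BOTH, CAND_ONLY and ETS_ONLY; each set's per-cell deviation z is computed
with shared backgrounds, and the one-sided Wilcoxon rank-sum (alternative
"greater") compares z_BOTH with each exclusive set over the cells of the
named subset. The test units are per-cell z values of peak sets; cells with
undefined z are excluded pairwise. P values are exact by full enumeration
when n+m ≤ 20 without ties, otherwise normal approximation with tie and
continuity corrections (continuity toggleable). FDR is applied across
candidates within each comparison direction — the family of tests reported
in one run. Deviations are computed on all cells by default so background
matching sees full accessibility profiles; a subset-only mode is available
(`compute_on="subset"`). An empty BOTH set is an error: the test is
undefined without co-occurring peaks.

## Survival analysis

A sample is ERG⁺ iff strictly more than 50% of its tumor cells are ERG⁺.
Bulk signature scores are mean per-gene z-scores across samples of log-scale
expression. Quartile stratification uses linear-interpolation percentiles:
top = score ≥ 75th percentile, bottom = score ≤ 25th percentile; coincident
cutoffs (constant scores) raise rather than silently producing overlapping
groups, and group sizes are logged. Kaplan–Meier curves and the log-rank
(Mantel–Cox) chi-square (1 df) are computed through lifelines; the tests pin
both against hand product-limit and table-by-table computations.
Analyses run separately within ERG⁺ and ERG⁻ strata by default, with
quartiles computed within each stratum (a full-cohort-quartile flag is
provided); no Cox modeling — the outcome claim is a log-rank comparison.

## Synthetic multiome generator

The generator's defaults are the study conditions the pipeline is validated
under: 200 cells over four epithelial states (basal/L1/L2/IM, 50 each),
2,000 peaks with GC ~ U(0.3, 0.7), Poisson fragment counts at base rate 0.2
per peak per cell, disjoint 200-peak programs per cell type with a 4×
multiplier (guaranteeing separable states for the lineage tests), motif
membership Bernoulli per (peak, motif), and 2× amplification of peaks where
a planted candidate (STAT3/NFKB2/NFATC1) co-occurs with ETS, applied only in
IM cells. Forced co-occurrence: after the independent Bernoulli draws, each
peak carrying a motif with a declared partner also receives the partner with
probability 0.5, guaranteeing a non-trivial BOTH set. The RNA modality
plants 10 marker genes per cluster at a 4× rate multiplier, Epcam⁺ cells at
a per-cluster fraction (default 0.9; positives are forced to ≥ 1 count,
negatives to 0), and Beta(2, 18) mitochondrial fractions realized by scaling
ten mitochondrial gene rates; cells violating QC thresholds can be planted
deterministically via fixed-total multinomial draws. The cohort draws
standard-normal signature scores, exponential survival times with log-hazard
log(2.5) per score SD over a 0.1 baseline hazard, Bernoulli(0.3) independent
censoring (censored samples observed at a uniform fraction of their event
time), and Bernoulli(0.5) ERG status on 200 samples.

Poisson rather than negative-binomial counts: the simplest model sufficient
to exercise the deviation statistics; an overdispersion knob could be added
later. Each modality draws from `default_rng([seed, stream])` with fixed
stream ids and a documented draw order, so identical configs are
bit-identical and the modalities are independent.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level structure and fragment files, doublets,
batch effects, overdispersion, trans-peak correlation beyond the planted
programs, realistic gene–gene covariance, and informative censoring.
Recovery rates measured here characterize the method under the planted
model, not field performance.

## Problem sizes and numerics

Validation sizes were chosen so the whole suite runs comfortably on a single
CPU: oracle equivalence on ≤ 10 × 10 matrices (loop-based brute force, 1e-12
agreement), hypergeometric enumeration up to population 30, rank-sum
enumeration up to n+m = 10, co-accessibility recovery over 20 generator
seeds at the default 200 × 2,000 scale with B = 50, survival calibration
over 2,000 null cohorts and 200 effect cohorts of n = 200, and the
deterministic demo pipeline at 100 cells × 600 peaks. Numerical choices:
BH via statsmodels; sample (n−1) sd over background iterations; Spearman of
undefined (constant) inputs treated as not-retained with a warning; quantile
ties resolved by the inclusive ≥/≤ rules above; all randomness flows from
explicit seeds with no hidden entropy sources.
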