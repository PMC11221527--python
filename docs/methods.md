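# Methods

This note documents the models, defaults and numerical choices behind
`hoodspot`, and what the synthetic-data validation does and does not
show about real tissue data.

## Spatial support and weights

Spots form a Visium-style offset hexagonal lattice: a spot exists at
array position (r, c) only when r + c is even, and lattice distance uses
doubled-width hex coordinates (dy + max(0, (dx − dy)/2)), so each
interior spot has six neighbors at distance 1. Analysis is restricted to
in-tissue spots. The default weights scheme links lattice-distance-1
neighbors and row-standardizes to 1/degree; a k-nearest-neighbor scheme
on pixel coordinates (symmetrized union, then row-standardized) is
provided for irregular captures. Degree-0 spots ("islands") have no
defined spatial lag and are excluded from inference and reported. The
weights scheme used by the original geospatial tooling is not
documented, so hex adjacency — the natural graph of the platform — is
the default.

## Local Moran's I and conditional permutation

For a value vector x over n non-island spots,

    z_i = (x_i − x̄) / √m2,  m2 = Σ_k (x_k − x̄)² / n,
    I_i = z_i · Σ_j w_ij z_j.

The population second moment (divisor n, not n − 1) is deliberate: with
row-standardized weights it makes mean_i(I_i) equal the global Moran's I
identically (verified to 1e-10 in the acceptance suite). The input is
the *normalized* expression matrix; the spatial statistics' contracts do
not depend on the normalization choice.

Significance is by conditional permutation: z_i is held fixed while the
other n − 1 values are permuted across the remaining spots n_perm times
(default 999), and pseudo p = (1 + #extreme)/(1 + n_perm). Four tail
conventions are exposed:

* `folded` (default) — one tail on the side of the observed statistic
  (the smaller of the two tail counts). This matches the convention of
  GeoDa-family tools, but note its null exceedance at level α is ≈ 2α
  by construction (it is a two-sided test reported at half scale).
* `greater` / `less` — fixed-direction tails, exactly calibrated:
  under a spatially exchangeable null the fraction of spots with
  p < α is binomially consistent with α (the discrete attainable level
  at n_perm = 999 and α = 0.05 is 49/1000).
* `two-sided` — twice the folded p, capped at 1.

Calibration claims in the test suite therefore use the directional
p-value, with the folded rate checked against its own 2α-scale level.

**Tie handling.** With equal row weights the permuted lag reproduces
the observed neighbor subset with probability 1/C(n−1, k), so the null
distribution has an atom exactly at the observed statistic. Ties within
1e-9 (statistics are O(1) after z-scaling) are counted as "at least as
extreme", the standard permutation-test convention; without this guard,
floating-point summation order splits the atom arbitrarily and the test
becomes anticonservative on small lattices.

The permutation engine draws one random permutation table per replicate
and gives each spot a random circular window into it; a window of a
uniform permutation is a uniform ordered sample without replacement, so
per-spot p-values are exact while the cost stays O(n_perm · n log n).
Monte-Carlo pseudo p-values at n_perm = 9,999 agree with exhaustive
enumeration over all (n−1)! conditional arrangements within 0.02 on
every lattice of ≤ 7 spots (the comparison uses the exhaustive tail
fraction on the smallest lattices, where the +1/(N+1) pseudo-p
normalization itself differs between enumeration sizes).

## Hotspot clusters, localized genes, and hotspot DE

Spots significant at α (strict inequality; α ∈ {0.05, 0.01} in the
study design) take their quadrant as a hotspot cluster: High-High → 1
("highest expression within the sample"), High-Low → 2, Low-High → 3,
Low-Low → 4; non-significant spots stay unassigned. P-values are not
adjusted across spots (an FDR column is available off the main path).
A gene is *localized* when the fraction of barcodes significant at the
chosen α is ≥ 0.05, inclusive ("5% or more"). Under a null with no
spatial structure this rule has limited specificity: with the folded
convention essentially every gene reaches 5% (per-spot rate ≈ 10%), and
even with the directional p about half do — the rule is a screen, not a
test, and downstream conclusions should rest on the per-spot maps.

Normalization is a documented stand-in: per-spot totals are scaled to
the median spot total and counts mapped through log2(1 + scaled)
(`log1p_median_scaled`). Zero-total spots are dropped with a warning.
Regularized-NB normalization is out of scope; the substitution is
recorded in the pipeline manifest.

Hotspot DE compares cluster-1 spots against the spots assigned to the
other clusters (`rest="assigned"`; `rest="all"` includes unassigned
spots) with a two-sided Wilcoxon rank-sum test — exact null
distribution when both groups have ≤ 50 tie-free observations,
otherwise the tie-corrected normal approximation — and a log2 fold
change from pseudocounted group means, log2(mean_t + 1) −
log2(mean_r + 1). Markers must pass |log2 FC| > 0.1 and unadjusted
p < 0.05; both over- and under-expressed markers are reported with
direction. The expression-fraction filter keeps genes detected in
strictly more than 10% of spots (a gene at exactly 10% is dropped);
"expression" is read as the nonzero-count fraction.

## Covariate screen

Per-sample mean expression (arithmetic mean over all in-tissue spots;
whether the original analysis used tumor-only spots is not stated) is
correlated with one covariate at a time by Pearson's r, with the exact
two-sided p from t = r√((n−2)/(1−r²)). Constant genes are skipped with
a warning; a constant covariate is an error. The packaged housekeeping
list is a small canonical symbol set (ACTB, GAPDH, B2M, …), matched
case-insensitively and user-overridable. Heatmap ordering clusters
genes by average linkage on Euclidean distances of log2(x + 1) values
(linkage and metric configurable — the ordering is presentation-only)
and orders samples by ascending violent-crime rate.

## Peak-set operations

Coordinates are 0-based half-open throughout. "Found in" means ≥ 1
shared base pair, and subtraction removes whole records (never
truncates), mirroring bed-style blacklisting; a minimum-overlap-fraction
option raises the removal threshold. Conservation is exact: the
specific set plus the overlapping records reconstitute the input.
Ranking uses the narrowPeak signalValue (column 7) or the BED score;
`top_fraction` keeps ceil(frac · n) records with ties broken
deterministically by (chrom, start). The KS comparison uses the exact
two-sample null when n·m ≤ 10,000, asymptotic otherwise.

A caveat measured by the acceptance suite: applying KS to the *top
decile* of the same score it compares is anticonservative under the
null (≈ 26% rejection at nominal 5% over 100 replicates) because top
order statistics of a common sample are compressed relative to iid tail
draws; the unselected comparison is calibrated (≈ 5–7%). Top-decile KS
p-values should therefore be read as descriptive contrasts, not
calibrated tests.

TSS annotation anchors each peak at its summit (narrowPeak column 10
when ≥ 0) or midpoint and takes the signed strand-aware distance to the
nearest TSS (positive = downstream in gene orientation; a −-strand
gene's TSS is its annotation end). Bins: promoter |d| ≤ 1 kb, upstream
1–3 kb and 3–10 kb, gene-body/downstream 1–10 kb, distal > 10 kb;
fractions partition the peak set. Signal clustering is Lloyd's k-means
with k-means++ and 10 restarts (default k = 7, mirroring a
seven-cluster binding panel); sklearn's implementation never leaves a
cluster empty (relocation on degeneracy).

## Synthetic data: what it emulates

* `simulate_expression` — negative-binomial counts, variance
  μ + μ²/θ, defaults μ = 5 and θ = 10: moderately expressed genes with
  the mild overdispersion typical of UMI-based spot counts (regularized
  NB fits to 10x data put θ in the tens for expressed genes). Hotspots
  are discs in hex distance with a multiplicative mean elevation;
  per-spot truth labels are returned. A fold of exactly 1 (no signal)
  must be requested explicitly (`allow_flat`) and is used for null
  calibration.
* `simulate_study` — 15 samples in three violence-exposure tiers (5
  each; violent crime per 1,000 drawn U(1,6)/U(8,16)/U(20,40) for
  low/mid/high — magnitudes plausible for city health-atlas zip-code
  data; the source study reports only the tier categories, so these are
  a stand-in, not a reconstruction). Covariate-linked gene means are
  baseline + slope·x + N(0, σ); the Pearson screen's empirical power
  over 200 replicates matches the exact noncentral-t power
  (ncp = slope·√SSx/σ) for this conditional-on-x model.
* `simulate_peaks` — peaks placed in disjoint slots (so records never
  overlap unless planted as shared at identical coordinates), N(4, 1)
  enrichment scores with an additive tumor shift, plus a random
  stranded TSS table. Counts are conserved exactly:
  |tumor| = n_peaks_tumor and |shared| = round(shared_fraction · min).

Every generator is a pure function of its spec including the seed; one
root `SeedSequence` spawns per-component substreams.

What passing on synthetic data does **not** show: real sections have
spatially varying cell-type composition, depth gradients and segment
boundaries rather than clean discs; covariates are correlated with each
other and with unmodeled confounders; real peak scores are heavy-tailed
and peak widths variable. The validation demonstrates correctness of
the statistics and calibration under the stated models, not robustness
to those features.

## Problem sizes and known limitations

The validation suite uses desk-scale problems chosen to exercise each
property well: 15×15 and 20×40 lattices (113 and 400 spots), 100-gene
null panels at n_perm = 999, exhaustive enumeration up to 7 spots,
200-replicate power studies, 100-seed KS sweeps, and a 3-sample
end-to-end study. Each is a study condition of the corresponding check
and is stated alongside its result in `results/acceptance.json`.

Known limitations: planted-disc recovery counts the full disc, and the
boundary ring (18 of 37 spots at radius 3) mixes elevated and
background neighbors, holding in-disc High-High recall to roughly
0.55–0.85 under realistic count noise even though precision and
interior recall are near 1 — a property of boundary spots under LISA,
not of the implementation. Each sample is analyzed on its own lattice
(no merged multi-sample spatial graph); bivariate/multivariate Moran
variants and Getis–Ord G* are out of scope; peak calling, motif and
pathway analysis are upstream/downstream of this package.
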