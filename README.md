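# hoodspot

Spatial hotspot analysis for spot-based tumor transcriptomics, with a
neighborhood-covariate correlation screen and paired tumor/normal
peak-set comparison.

Lung-tumor spatial transcriptomics studies of neighborhood adversity ask
three linked questions: *where* in a tissue section a gene's expression
forms coherent high-expression regions, *which* genes' average expression
tracks neighborhood-level exposures such as the violent crime rate, and
*how* a transcription factor's genome-wide binding (e.g. the
glucocorticoid receptor cistrome measured by CUT&RUN) differs between
tumor and matched healthy tissue. `hoodspot` implements that pipeline as
a tested, reusable library plus CLI, together with a synthetic-data
generator that reproduces the statistical structure of each input so the
whole analysis runs and is validated without any patient data.

## Methods at the core

**Local Moran's I (LISA) on the Visium hex lattice.** Spots live on an
offset hexagonal lattice (spot (r, c) exists when r + c is even; six
neighbors at lattice distance 1). For expression x on spots with
row-standardized weights w_ij,

    I_i = z_i · Σ_j w_ij z_j,   z_i = (x_i − x̄) / √m2,   m2 = Σ_k (x_k − x̄)² / n,

so that mean_i(I_i) equals the global Moran's I exactly. Significance is
by conditional permutation (the focal value held fixed, the remaining
n − 1 values permuted; pseudo p = (1 + #extreme)/(1 + n_perm), folded
min-tail by default, directional and two-sided alternatives available).
Significant spots are mapped to hotspot clusters by quadrant:
High-High → 1, High-Low → 2, Low-High → 3, Low-Low → 4. A gene is
**localized** when ≥ 5% of its barcodes are significant. Hotspot
differential expression compares cluster 1 against the remaining
clusters with a two-sided Wilcoxon rank-sum test, gated at
|log2 FC| > 0.1 and unadjusted p < 0.05.

**Covariate screen.** Per-sample mean expression is correlated with
neighborhood measures (violent crime per 1,000 residents, overall crime,
% poverty, racial/ethnic composition) by Pearson's r with the exact
t transform (n − 2 df, two-sided p < 0.05), after case-insensitive
housekeeping-gene removal; heatmap rows are average-linkage clustered on
log-transformed values and columns ordered by ascending violent-crime
rate.

**Cistrome comparison.** Peak sets (BED6 / ENCODE narrowPeak, 0-based
half-open, narrowPeak signalValue as the enrichment score) support
whole-record interval subtraction ("filter out regions also found in
…"), top-decile selection by enrichment, two-sample Kolmogorov–Smirnov
comparison of enrichment scores, strand-aware TSS-relative binning
(promoter ≤ 1 kb, upstream 1–3 and 3–10 kb, gene-body/downstream,
distal > 10 kb), and k-means clustering of site × condition signal
matrices.

## Worked example

Plant a 4-fold expression disc (radius 3) on a 20×20 lattice, detect it,
and test its markers:

```python
from hoodspot import (HotspotSpec, simulate_expression, make_hex_grid,
                      build_weights, normalize, local_moran,
                      assign_clusters, cluster_markers)

grid = make_hex_grid(20, 20)
hs = HotspotSpec(center=(10, 10), radius=3, fold_elevation=4.0,
                 affected_genes=["GENE0001"])
counts, genes, truth = simulate_expression(grid, 10, hotspots=[hs], seed=7)
norm = normalize(counts)
w = build_weights(grid)
res = local_moran(norm.matrix[0], w, n_perm=999, seed=7)
labels = assign_clusters(res, alpha=0.05)
de = cluster_markers(norm.matrix, genes, labels, target=1)
```

This prints (via `res.global_moran()`, label counts, and `de.head(3)`):

```
global Moran's I: 0.296
cluster-1 spots: 30 of 200
in-disc spots labeled cluster 1: 30 of 37
 gene_id    log_fc        p    p_adj
GENE0001  0.420145 0.000016 0.000162
GENE0008 -0.303158 0.000514 0.002569
GENE0004  -0.292539 0.020892 0.069641
```

The planted gene's disc produces strong positive spatial autocorrelation
(global I ≈ 0.30 against ≈ −1/(n−1) ≈ −0.005 expected under no
structure); 30 of the 37 in-disc spots are flagged High-High, and the
planted gene tops the cluster-1 marker list with log2 FC 0.42 at
p = 1.6e-5. (Genes with negative log2 FC are under-expressed inside the
hotspot relative to the rest — with one elevated gene, depth
normalization slightly deflates the others inside the disc.)

The same flow from a shell:

```bash
hoodspot simulate --out demo --seed 3          # writes a 3-sample study + config
hoodspot run-all --config demo/config.yaml    # all stages + run manifest
```

`run-all` produces per-sample localization and cluster tables, hotspot
DE tables, the correlation screen TSV and heatmap ordering, the
tumor-specific BED, KS comparison JSON, TSS-distribution TSV, k-means
site clusters, and a `manifest.json` of per-stage input/output SHA-256
checksums (reruns with unchanged inputs are skipped; identical seeds
reproduce identical checksums).

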