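# saspatial

Spatial-statistics detection of differentially expressed genes (DEGs) in
spatial transcriptomics (ST), for analysts working with 10x Visium-style
sections who want region-specific expression signals that classical
per-spot tests miss.

Classical DEG tests treat spots as exchangeable samples. Spots are not:
expression measured at nearby capture locations is correlated, and it is
precisely that spatial dependence that marks a biologically coherent
region (an ischemic core, a cortical layer, a tumor margin). `saspatial`
makes the dependence the signal:

1. **Gate genes on global spatial pattern.** For each gene with per-spot
   values $X_i$, deviations $Z_i = X_i - \bar X$ and spatial weights
   $\omega_{ij}$,

   $$I = \frac{n}{S_0}\,\frac{\sum_i\sum_j \omega_{ij} Z_i Z_j}{\sum_i Z_i^2},
     \qquad S_0 = \sum_i\sum_j \omega_{ij},\qquad E[I] = \frac{-1}{n-1}.$$

   The z-score $(I - E[I])/\sqrt{\nu[I]}$ (randomization-assumption
   variance by default) classifies each gene as **clustered**
   ($z > 1.65$, $P < 0.1$), **dispersed** ($z < -1.65$, $P < 0.1$) or
   **random**; only clustered genes proceed.

2. **Type every spot with Anselin local Moran's I (LISA).**

   $$I_i = \frac{X_i - \bar X}{S_i^2} \sum_{j \ne i} \omega_{ij}(X_j - \bar X),
     \qquad S_i^2 = \frac{\sum_{j\ne i} (X_j-\bar X)^2}{n-1}.$$

   Significance (conditional permutation by default) and the signs of the
   deviation and spatial lag assign each spot a cluster–outlier type:
   **H-H**, **L-L**, **H-L**, **L-H** or non-significant.

3. **Compare regions by counting.** For a region of interest (ROI, a
   barcode list or polygon) versus a reference region, the number of H-H
   spots (up-regulation) or L-L spots (down-regulation) forms a 2×2
   contingency table tested with Pearson's chi-squared; genes are ranked
   by p-value and the H-H rate difference between regions is the effect
   size. Getis-Ord Gi* z-scores provide hot/cold-spot maps for the hits,
   and a Wilcoxon rank-sum baseline (logFC > 0.25, p < 0.05,
   min.pct > 0.1) supports method comparison.

No GIS software is required; weights, statistics and permutation nulls are
implemented directly on sparse matrices.

## Worked example

Generate a fully synthetic section (a 12×12 lattice with one ROI-enriched
gene, one smooth-bump gene, one checkerboard gene and six unstructured
genes, as negative-binomial counts) and run the whole pipeline:

```bash
saspatial fixtures demo --seed 7
saspatial run demo/config.yaml
```

`demo/results/global_moran.csv` then starts:

```
gene,moran_I,expected_I,variance_I,z,p,pattern
roi_gene,0.31431,-0.00699,0.00378,5.22318,1.759e-07,clustered
bump_gene,0.11114,-0.00699,0.00377,1.92292,0.05449,clustered
checker_gene,-0.51687,-0.00699,0.00378,-8.29173,1.116e-16,dispersed
noise_00,-0.00762,-0.00699,0.00374,-0.01018,0.99188,random
```

The planted regional genes are clustered ($z > 1.65$), the checkerboard is
dispersed ($z < -1.65$) and the unstructured genes sit at the
no-autocorrelation reference $E[I] = -1/143 \approx -0.007$. The ranked
up-DEG comparison of the ROI against the rest of the section
(`bubble_core_vs_rest_up.csv`) reports:

```
gene,p,rate_difference
roi_gene,3.686e-10,0.33333
bump_gene,0.00384,0.10185
```

i.e. the ROI-enriched gene's H-H spots are 33 percentage points more
frequent inside the ROI than outside, and `method_overlap.csv` shows both
hits are also found by the Wilcoxon baseline (`both=2, spatial_only=0,
baseline_only=0`). Per-spot LISA tables and Gi* hot-spot maps for the top
genes are written under `results/local/` and `results/hotspot/`.

The same analyses are available as library calls (`global_moran`,
`local_moran`, `deg_chi2`, `gi_star`, …) and as the subcommands
`global`, `local`, `deg`, `hotspot` and `compare`.

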