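# Methods

## Model and procedure

`saspatial` treats a tissue section as a lattice of spots and a gene's
expression as an attribute field on that lattice. The working assumption
of all three stages is the first law of spatial statistics: nearby spots
are dependent, and the degree and sign of that dependence is informative.

**Stage 1 — global gate.** Global Moran's I measures section-wide
autocorrelation of one gene. Under the null of no spatial structure,
E[I] = −1/(n−1) and the variance ν[I] = E[I²] − E[I]² is computed under
either the randomization assumption (default; moments of I over all
permutations of the observed values, which involve the weight sums
S₀, S₁ = ½Σ(ωᵢⱼ+ωⱼᵢ)², S₂ = Σᵢ(ωᵢ·+ω·ᵢ)² and the sample kurtosis b₂),
the normality assumption, or an explicit permutation distribution
(seeded, default 999 draws). Classification uses z > 1.65 with P < 0.1
for clustered, z < −1.65 with P < 0.1 for dispersed, otherwise random;
only clustered genes are analyzed further, and every aborted gene is
logged with its pattern. P-values are two-tailed, matching the symmetric
±1.65 boundaries. Genes detected in fewer than `min_spots` spots
(default 10) are excluded up front: the Moran moments are dominated by
kurtosis for near-empty vectors.

**Stage 2 — local typing.** Anselin's local Moran's I decomposes the
association per spot. We use the leave-one-out scaling
S_i² = Σ_{j≠i}(X_j−X̄)²/(n−1). (An alternative transcription embeds ωᵢⱼ
inside the S_i sum; it is inconsistent with the statistic it scales and
with the standard local-Moran definition, so the standard form is
implemented. The `si_mode="global"` variant, S² = ΣZ²/n, is also
provided; under it the local statistics aggregate exactly,
Σᵢ Iᵢ = S₀·I, which the tests verify.) Significance defaults to a
conditional permutation null: the focal value is held fixed and the
remaining n−1 values are shuffled into the neighbor slots (999 draws,
seeded; a shared index pool with a fresh per-spot shuffle keeps draws
decorrelated across spots). Pseudo-p-values are two-tailed with the
(min tail + 1)/(m + 1) convention. An analytic z based on Anselin's
total-randomization moments is available for speed; it is derived for
the global-denominator scaling and is validated against the permutation
null in the test suite rather than trusted blindly. Each spot is then
typed H-H, L-L, H-L, L-H (by the signs of its deviation and spatial lag)
or NS when not significant at α (default 0.05, optional per-gene
Benjamini-Hochberg across spots; FDR typing is a subset of unadjusted
typing, which is asserted). Zero deviation or lag at a significant spot
is a tie and is typed NS with a log note.

**Stage 3 — regional counting.** For a comparison (ROI, reference,
direction), the H-H count (up) or L-L count (down) in each region forms a
2×2 table tested by Pearson's chi-squared with 1 df and no continuity
correction (counts on real sections are large; Yates is available). A
zero target count in both regions is untestable and flagged with p = 1;
expected cells below 1 are flagged `low_expectation`. Significant genes
(raw p < α by default, mirroring common practice; BH-adjusted mode
recommended for large panels) are ranked by ascending p, ties by
descending |rate difference| then gene name, truncated to the top 20.
Cross-section comparisons reuse each section's own local Moran field —
CO typing is always within-section because the statistic is undefined
across disconnected lattices — and only counts are compared. The default
reference for within-section comparisons is all other spots; a named
second region may be supplied instead. Supporting metrics: the ROI ratio
(H-H in ROI over all spots in the section) and per-region H-H shares
with a configurable region-specificity threshold (default 50%).

**Visualization statistics.** Getis-Ord Gi* (self-included, binary
neighborhood plus self weight 1) gives per-spot hot/cold z-scores, binned
at the 90/95/99% normal cutoffs (1.65/1.96/2.58). **Baseline.** The
classical comparator is a per-gene two-sided Wilcoxon rank-sum between
ROI and reference on log-normalized values with
logFC = ln((mean expm1 + 1) ratio), filters logFC > 0.25, p < 0.05 and
detection fraction (min.pct) > 0.1 — the conventional single-cell
FindMarkers-style criteria.

## Spatial weights

The weight ωᵢⱼ is never dictated by the statistics, so it is explicit
configuration. The default is a binary distance band at 1.05× the lattice
pitch (minimum nearest-neighbor pixel distance), row-standardized. On a
hexagonal Visium-like lattice this yields the 6-neighbor adjacency; on
square test lattices it yields rook adjacency, which enables the
closed-form checkerboard results. k-nearest-neighbor and rook/queen
contiguity schemes are available. Weights are binary before
row standardization; the diagonal is identically zero; isolated spots
keep empty rows (with a warning) so indices stay aligned with the
expression matrix. Gi* always uses the binary adjacency with a self
weight, independent of row standardization.

## Input handling and normalization

Two dialects are read into the same containers: the Visium-style
directory (MatrixMarket counts + barcodes/features TSV +
tissue-positions CSV; out-of-tissue spots dropped by default) and a flat
CSV pair (long barcode/gene/value table, pivoted with absent pairs as 0,
plus barcode/x/y coordinates, treated as pre-standardized unless flagged
otherwise — both z-scored and log-normalized inputs are acceptable
because Moran statistics center internally). Raw counts are normalized
by per-spot depth scaling to the median total count followed by log1p;
any monotone per-spot normalization would serve, and a `--no-normalize`
flag covers pre-normalized inputs. Array coordinates are 0-based lattice
indices; pixel coordinates are used for distances, polygons and
plotting. No projected-CRS offsets are applied: they are a mapping-tool
artifact with no effect on any statistic.

## Synthetic data

The generator produces the regimes the method must distinguish:
checkerboard (exactly dispersed, I = −1 on even rook lattices), iid
noise (random), Gaussian bumps, rings and row-layers (clustered), and
ROI-enriched genes for power studies; counts are negative-binomial with
variance μ + μ²/θ, the standard overdispersed UMI model. Every generator
is a pure function of (lattice, spec, seed). Default fixture effect
sizes emulate strong regional markers (~4-fold enrichment over baseline,
dispersion θ = 8); weaker markers are exactly the regime where the gate
is expected to abort genes. The generator does not emulate cell-type
mixtures within spots, segmentation noise, or the compositional coupling
of thousands of genes — with only ~10 genes, depth normalization lets
strongly patterned genes bleed weak inverse structure into flat genes,
an effect that shrinks as the panel grows. Passing tests therefore
demonstrate statistical correctness and calibration, not robustness to
every artifact of real sections.

## Numerical and design choices

- Permutation counts: 999 default (199 in the bundled fixture config to
  keep the demo fast); two-tailed pseudo-p floor is 2/(m+1).
- One global seed fans out via `SeedSequence.spawn` to stages and genes,
  so reruns are byte-identical; derived seeds are kept below 2³¹.
- Acceptance-style calibration studies use a 20×20 lattice, 500
  simulated fields and 199 conditional permutations per gene — small
  enough to run on one CPU in minutes while keeping Monte-Carlo error
  well inside the 3-SE/binomial-99% bands asserted.
- Type-I calibration of the counting stage is measured on iid H-H label
  fields (Bernoulli 0.15), which satisfy the chi-squared null exactly;
  spatially structured genes with randomly placed patterns do not (their
  regional rates genuinely differ), so they are not used as nulls.
- Degenerate inputs fail loudly and by name: constant genes, zero-depth
  spots, S₀ = 0 weights, empty ROIs, unknown barcodes, duplicate long
  rows.
- Config files are schema-checked before any I/O; unknown keys are
  rejected outright rather than ignored.

## Known limitations

- The analytic local-Moran variance is approximate under the
  leave-one-out S_i²; use the (default) conditional permutation null
  when the z-scores matter.
- Chi-squared p-values on small regions with few typed spots are
  unreliable; such results carry the `low_expectation` flag and should
  be read qualitatively.
- The ranking uses the chi-squared p regardless of the sign of the rate
  difference; filter on `rate_difference > 0` when strictly
  ROI-enriched hits are wanted.
- Cross-section comparisons assume sections were normalized comparably;
  no batch correction is attempted.
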