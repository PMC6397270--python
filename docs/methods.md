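# Methods

## Canonical pelt frame

Pelts differ in physical size, so all spatial work happens in a canonical
frame: columns span x ∈ [−1, 1] across the transverse axis, rows span
y ∈ [−1, 1] along the median sagittal axis with the head at y = +1, and the
origin at the axes' intersection. (row, col) are 0-based indices on a
configurable rectangular grid; distances are Euclidean in (x, y). Grid holes
(paws are discarded during pelt processing) are allowed and never imputed.
Pelts digitized at different raw grid sizes are matched across animals by
nearest-cell reassignment onto a common grid before compositing.

## Synthetic pelt generator

The generator exists because no gridded pelt dataset is publicly available;
it produces data with the documented structure of the four-otter study so
every downstream stage is testable.

Per pelt, the THg value at cell i of layer L is

    v_i = μ_L + σ_L√(1−ν) · (z_i + b_i) + σ_L√ν · ε_i,  truncated at 0,

where z is a unit-variance Gaussian random field with exponential covariance
exp(−d/ℓ) drawn exactly by dense Cholesky (grids are ≤ a few hundred points;
1e-10 diagonal jitter), b is a deterministic bump surface — a Gaussian bump
of amplitude +3 (field-sd units, radius 0.35) centred in the head region and
−3 at the tail — ν = 0.2 is the i.i.d. noise share of the layer variance,
and ε is standard normal. The topcoat and undercoat fields share the bump
geometry and have cross-correlation 0.3, which yields the weak-to-moderate
positive between-layer correlations seen in matched-cell comparisons.

Defaults are the per-pelt observed summaries of the study animals: topcoat
means (1.55, 4.60, 1.42, 4.44) µg/g and sds (0.20, 0.20, 0.37, 0.16);
undercoat means are topcoat × (1.41, 2.05, 2.01, 1.10) and undercoat
variances topcoat × (9.6, 121, 16.7, 31.6). The 12 × 9 default grid with
per-pelt corner holes (19, 10, 12, 13 cells, the discarded paws) gives
n = 89, 98, 96, 95 points. The within-pelt correlation length has no
published estimate; the default ℓ = 0.4 canonical units gives smooth
multi-cell clusters on a [−1, 1] pelt and is a declared free parameter.

MeHg is attached to topcoat points as fraction × THg + N(0, 0.05 µg/g),
truncated to [0, 1.3 × THg] (the overshoot allowance mirrors independent
analytical error in the two assays), with the true fraction defaulting to
0.957. Assays are restricted to a stratified subset — THg tertiles crossed
with anatomical region, one draw per non-empty stratum — matching how MeHg
subsamples are selected in practice; degenerate tertiles (ties) collapse
gracefully down to one concentration stratum per region.

Organ records are generated per animal from the topcoat point nearest the
head-region centroid, passed through the configured conversion model, with
optional lognormal noise (default zero). With zero noise the organ-prediction
error is exactly zero at the generating points, planting head/topcoat as the
known optimal sampling region for the end-to-end recovery check.

What the generator does **not** emulate: fur-region (dorsal/ventral)
concentration gradients, anisotropic spatial covariance, inter-animal
correlation of patterns beyond the shared bump geometry, and any dependence
of the MeHg fraction on concentration. Consequently the synthetic composite
topcoat and undercoat have statistically similar normalized distributions,
whereas field data show relatively stronger undercoat heterogeneity; passing
tests demonstrate that the machinery recovers planted structure, not that
field pelts look like the simulations.

## Semivariogram and neighborhood

The empirical semivariogram uses the Matheron estimator
γ(h) = Σ_{pairs in bin} (x_i − x_j)²/(2 N_h) on equal-width right-closed
bins; the default bin count is ⌈√(number of pairs)⌉ capped at 15. Pipeline
callers estimate γ only up to one third of the point-cloud diagonal (the
gstat convention): long-lag estimates rest on few pairs, and on pelts the
head-hot/tail-cold geometry produces a hole effect at long lags that would
otherwise distort the fit.

A spherical model (default; exponential available, parametrized by its
practical range) is fitted by weighted least squares with the per-bin pair
counts as weights. The fitted range becomes the Gi* band distance. When the
optimizer fails, the fitted range exceeds the maximum lag, or the partial
sill is indistinguishable from zero (pure nugget — range unidentified), the
range falls back to half the maximum lag and the result is flagged; under
the default generator the within-cutoff variogram often keeps rising, so the
flagged fallback band (≈ one sixth of the pelt diagonal) is the common,
deliberately conservative outcome.

## Local Gi*

Binary distance-band weights with self-inclusion (the "star" variant); ties
at exactly the band distance are neighbors, matching the spdep default. The
denominator uses the population (n-denominator) sd. Two degenerate cases are
defined explicitly: a constant field (sd ≤ 1e−12 relative) yields NaN scores
and all-neutral labels with a warning; a neighborhood covering all n points
is a 0/0 limit defined as z = 0. Raw z is thresholded at ±1.96 with no
multiple-testing correction — the convention of local-cluster maps — and the
threshold is exposed as a parameter. Semivariogram and band are computed per
pelt per layer, never pooled.

## Composite pelt

Min-max normalization is per pelt **and** per layer, so composite topcoat
and undercoat are each on their own [0, 1] scale; pelts with all-equal
values cannot be normalized and must be excluded by the caller. Composite
cell values are unweighted means over contributing pelts at each canonical
cell (a cell exists wherever at least one pelt has it — union rule); region
labels are taken by majority vote, ties resolved to the first pelt's label
and logged.

## Group statistics

The paired layer comparison is the ordinary paired t-test on per-cell
differences. (Field reports sometimes label this "Welch's paired t-test";
Welch's unequal-variance correction is undefined for a paired design, so the
paired t on differences is what is actually computable and is what this
package implements.) Variance comparisons use the two-sided variance-ratio
F-test; correlations are Pearson with Fisher-z 95% CIs; regional contrasts
are one-way fixed-effects ANOVA with Tukey HSD (studentized-range CIs and
adjusted p, via scipy). All p-values are two-sided; α = 0.05 default.

Caveat carried from the survey design: cells are treated as independent
observations although neighboring cells are spatially correlated, so these
p-values are anti-conservative and should be read alongside the cluster
maps.

## MeHg/THg fraction

Points with MeHg/THg strictly greater than 110% are removed before fitting
(a true ratio above 1 is impossible; modest overshoot is analytical error —
exactly 110% is kept). The slope of MeHg = β·THg through the origin is
β = Σxy/Σx², with se and CI on n − 1 residual df. R² uses the uncentered
total sum of squares (the no-intercept convention) — stated explicitly
because centred and uncentered R² are not comparable. Diagnostics: RESET
with powers 2–3 of the fitted values (F-form), Breusch–Pagan score test,
Shapiro–Wilk, and Durbin–Watson computed on residuals sorted by THg — the
samples carry no time index, so the regressor order is the deterministic,
disclosed choice; DW is reported as a statistic plus a bounds-style verdict
(positive < 1.5 < none < 2.5 < negative) since no closed-form p is used.

## Error surface and optimal region

Organ THg is predicted from fur THg per point: ŷ = a + b·fur on the linear
scale or ŷ = 10^(a + b·log10 fur) on the log10 scale. The observed organ
value is per animal (one measurement per organ) and is broadcast to all that
animal's fur points. Percent error |(ŷ − y)/y|·100 per organ is combined
with brain weighted twice, then point-wise weighted errors are averaged
across animals on the canonical grid (weighting per point first, then
averaging across pelts), and Gi* runs on the averaged surface. Fur points
outside the conversion model's domain (zero THg on a log10 scale, possible
after the generator's zero truncation) are excluded with a logged count.

Published conversion coefficients are **not** bundled: the default model is
a clearly labelled synthetic placeholder (log10 identity), and every
optimal-region report produced with it is flagged as a self-consistency
exercise rather than a field conclusion.

## Problem sizes and determinism

All simulation-based checks use modest, fixed problem sizes chosen for
desk-scale reproducibility: 100 replicates for hotspot recovery and the
i.i.d. false-positive ceiling, 300 replicates (n = 100, noise sd 0.05) for
MeHg parameter recovery, and 1000 null draws per test for type-I
calibration. Every stochastic path takes an explicit seed; the same
configuration and seed reproduce outputs bit-identically, and pipeline
outputs record package version, seed and a configuration hash.

## Known limitations

- The ANOVA/t-test stages ignore spatial autocorrelation (see caveat above).
- Zero-truncation in the generator biases low-mean/high-variance layers
  slightly upward; negligible at the default means.
- The variogram model family, binning and cutoff are declared defaults, not
  estimates; hotspot labels can shift with the band when the fitted range is
  weakly identified.
- No FDR control on Gi* labels (deliberate, to match the ±1.96 convention);
  on ~90-point grids a few percent of labels are expected false positives.
- Composite construction assumes the canonical-grid matching is meaningful;
  severe shape differences between animals would violate it.
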