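# Methods

## The synthetic trial

`synthetic_field.simulate_trial` draws a randomized complete block trial:
each replicate block receives an independent random permutation of the
genotypes into a roughly square grid of four-row plots (3.05 m rows, 0.76 m
spacing and alleys). The latent per-row "canopy vigor" trait is

    latent(plot i, row r) = mu + G_i + R_j + b·1[r in {1,4}] + e_ir,

with `G_i ~ N(0, genetic_variance)`, fixed replicate offsets `R_j ~ N(0,
0.05²)` drawn once per trial, border mean shift `b`
(`border_effect_mean_shift`), and row residuals `e_ir ~ N(0,
residual_variance + border_extra_sd²·1[r in {1,4}])`. Yield is
`2 + 10·mean(latent rows 2,3) + N(0, yield_noise_sd²)` — deliberately a
function of the inner rows only, because those are the harvested rows in
four-row plot practice; this is what makes inner-row features genuinely more
predictive of yield.

Default effect sizes (trait mean 1.0, genetic variance 0.04, residual
variance 0.01, border shift +0.15, border extra sd 0.10, alley-end shift
+0.10 within a 0.40 m end zone, measurement sd 0.05, yield noise 0.5) were
chosen once as values a field phenotypicist would call realistic: ~20%
genetic CV, a border effect visibly larger than within-plot noise but far
from dominating, and per-flight trait repeatability in the 0.65–0.96 range
across selections — comparable to well-run trials. The border shift is
*positive* (border plants grow larger through reduced competition from the
alley side). No quantitative border magnitude is established for
remote-sensing traits in the literature, so it is an explicit parameter, not
a constant.

## Rendering

Growth over thermal time uses the saturating scale `g = GDD/(GDD+300)`, zero
at emergence. Point clouds place a ground grid (z ~ N(0, 1 cm)) plus
canopy points per plant; plant height is `3.0 m · g · latent` with ±5%
per-plant noise, alley-end plants inflated by `alley_end_shift`, point count
proportional to `g · latent`, vertical profile `z = h·(0.15 + 0.85·u^0.6)`
so the 95th percentile sits near the plant top, and lateral spread clipped
into the row's 0.76 m strip. Every point carries a ground/canopy truth
label so trait extraction can be tested with perfect classification or with
its own minimum-elevation classifier.

Rasters paint per-plant discs (radius `0.22 m · g · sqrt(latent)`).
RGB (1 cm default GSD) gives vegetation pixels HSV colors inside the
vegetation window (hue 95–145°, saturation 0.45–0.8, value 0.3–0.6) and soil
pixels hue 20–40° — separable by the default thresholds but not
caricatured. Hyperspectral rasters (4 cm default GSD) carry the 15 bands
needed by the index formulary; soil is a featureless rising template,
vegetation a template with green bump, red absorption and NIR plateau whose
NIR bands scale with `0.6 + 0.4·latent`, so red/NIR contrast tracks vigor.
Two fixed template spectra, linearly mixed per pixel class, are the simplest
model under which every index is computable and the NDVI > 0.5 mask is
decidable. No radiative transfer, occlusion, or sensor noise model is
attempted; consequently, passing tests show the *analysis chain* is correct,
not that the renderer is photorealistic.

## Trait extraction

All traits pool points/pixels over the selected boxes before computing the
statistic; pooling and per-row averaging differ only when rows differ in
point counts, and pooling matches the "total points per row segment"
convention. Boxes are closed-open `[min, max)` intervals so adjacent rows
never double-count a point. Percentiles interpolate linearly between order
statistics. CC10's threshold is the 10th percentile of *nonground* heights
with *all* points in the denominator; the single-population reading is
definitionally ~0.9 for distinct heights and is available via
`population="all"`. OSAVI is implemented in its standard form with +0.16 in
the denominator. Thresholds compare strictly (`>`), ties breaking toward
non-vegetation/below. Empty cells (no nonground points, empty vegetation
mask) yield NaN-flagged traits and a log line, never an exception, so sweeps
survive degenerate cells.

## Direct trait-observation route

Replicated studies (50–200 simulated trials) do not re-render point clouds;
`simulate_trait_observations` generates the plot-level observation directly:
selection value = growth scale × (mean member-row latent + measurement
error), with errors drawn independently per (plot, selection, trim, flight)
cell at sd `measurement_sd/sqrt(n_member_rows)`. The `1/sqrt(n)` scaling
preserves the pooling advantage of multi-row selections; cell-independent
draws keep the factorial ANOVA's residual a valid yardstick for the trim
contrast (errors shared across selections within a trim level would act as
an unmodeled trim-block effect and inflate the trim type-I rate). Trimmed
and untrimmed observations share the same latent truth and differ only
through that noise — the generative claim that trimming is null when the
segment grid is anchored on early-season plant extent. A 200-trial
calibration run gives a trim rejection rate of 0.03 at nominal 0.05
(slightly conservative, because latent truth shared across flights cancels
in the trim contrast but contributes to the residual).

## Variance components and repeatability

The per-cell model has hybrid random and replicate fixed. Numeric REML
profiles the restricted likelihood over `lambda = sigma²_H/sigma²_e` after a
one-time eigendecomposition of `ZZ'`, optimizing `log lambda` by bounded
Brent search (xatol 1e-10) plus an explicit boundary check at `lambda = 0`.
For balanced complete data the estimates equal the RCB ANOVA estimators
`sigma²_H = (MS_hybrid − MS_error)/r`, `sigma²_e = MS_error` whenever the
interior solution applies; at the boundary, the hybrid variance is pinned at
0 and the residual re-estimated from the fixed-effects-only model, matching
REML exactly. `method="auto"` uses the closed form on balanced data purely
for speed. Negative estimates are truncated at zero, so H² is never
negative. Each flight yields its own H²; flights within a GDD window then
serve as replicates in the factorial ANOVA.

## Yield prediction

Entries are plots (replicates of a genotype are unique entries and are not
kept apart across folds). Features are standardized (mean 0, sd 1, ddof=1)
with training-fold parameters only; zero-variance columns are dropped with a
log line. Hyperparameters (sigma from {1e-4, 1e-3, 1e-2, 0.1}; cost from
{10, 50, 100, 150, 200, n_features}) are selected by an inner 5-fold grid
search run strictly inside each outer fold's training portion. Selecting
once per repeat was considered and rejected: any single search whose data
span other folds' test rows would let a test observation influence its own
fold's model, violating the no-leakage property that the canary test
enforces (a test-only outlier cannot change its fold's chosen
hyperparameters). Epsilon defaults to 0.1. Fold assignment shuffles within
each subpopulation and deals round-robin with a random starting fold, so
every fold's group composition differs by at most one entry.

## ANOVA and LSD

Sequential (type-I) sums of squares in the order trim, year, selection,
selection:year; the synthetic designs are balanced, making the order
irrelevant, and trim interactions are excluded as the trim factor is modeled
as a pure main effect. A constant response returns F = 0, p = 1 for all
terms. LSD uses `t(1−alpha/2, df_error)·sqrt(2·MSE/n)` with harmonic-mean n
under imbalance; letters come from the descending-means maximal-run
insertion algorithm and are checked against brute-force all-pairs decisions.

## Problem sizes

The shipped studies use 200 recovery trials (200 genotypes × 2 reps), 50
border-effect trials (100 genotypes × 2 reps × 2 years × 4 flights × 7
selections × 2 trims), and 20 prediction trials (50 genotypes × 2 reps,
k = 5, 10 repeats, a 2×2 hyperparameter subgrid) — sizes at which the Monte
Carlo error of every reported rate is a few percent and a full run completes
in about two minutes on one CPU. The pipeline's rendered route defaults to
2 cm RGB / 8 cm hyperspectral ground sampling for the same reason; the
renderer itself defaults to the native 1 cm / 4 cm.

## Known limitations

Rendered scenes have no occlusion, mixed pixels, shadows, registration
error, or weather-driven spectral variation; the border effect enters as a
single latent shift rather than an asymmetric competition model; phenology
reduces to three fixed GDD windows; and the trim-null result is a structural
property of a grid anchored on early-season plant extent — a grid re-drawn
per flight would not show it.
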