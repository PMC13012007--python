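# Methods

## Assay model

A PDT screen exposes each sample to two drugs in five-step, ten-fold
dilution series — oxaliplatin 0.012–120 µmol/L and SN-38 0.032–320 nmol/L —
with four technical replicates per condition and drug-free vehicle wells
(0.5% DMSO). Wells are imaged repeatedly over the culture; the classifier
readout is taken on day 7 (`readout_day`, configurable), with day 1 as the
per-well baseline. A culture counts as successful when its mean vehicle
relative total area on day 7 is at least 1.2 (boundary included).

The central modelling assumption is that tumoroid-covered area is a usable
proxy for viable cell mass, and that a well's net growth between day 1 and
day 7 summarizes its response. Growth is treated as geometric
(exponential-in-time): all per-day area trajectories in the synthetic
generator follow `area(d) = area(1) · g^((d−1)/6)`, where `g` is the day-7
relative total area. Within-week kinetics are otherwise unspecified and do
not enter the day-7 readout.

## Imaging stage

Best-focus projection assigns each output pixel the intensity of the z-plane
with the highest local intensity variance in an odd `window` neighborhood
(default 9 px). Local variance is computed with uniform filters
(mean-of-squares minus square-of-mean, floored at 0). This is the standard
variance-map definition of "best focus"; ties go to the lowest plane index.

Binarization defaults to Otsu's threshold on the projection, followed by
removal of objects smaller than `min_object_px` (default 50 px) and hole
filling. The threshold method is pluggable (`method="fixed"` with an
explicit threshold) because real acquisitions may need instrument-specific
pipelines; Otsu keeps the mask invariant to affine intensity rescaling.
Areas are reported in pixels unless a `pixel_size` is supplied — relative
total area is unit-free either way, so no instrument calibration is invented.
A constant image yields an empty mask with a warning rather than an error.

## Growth metrics

Relative total area is computed per well; the GR value per technical
replicate normalizes that well's growth to the mean of the sample's pooled
vehicle wells at the same readout day. Replicate GR values are then
averaged — the mean of per-replicate GRs, not the GR of mean growth rates,
avoiding the bias Jensen's inequality would otherwise introduce. Wells
missing the readout day are flagged and excluded from both condition and
control means, never imputed. A measured relative area at or below
`epsilon = 1e−3` (possible after aggressive segmentation) is floored to
`epsilon` with a flag, since the log transform needs positive growth rates;
a vehicle mean of exactly 1 (zero net control growth) leaves GR undefined
(NaN) — such a sample fails the success criterion anyway.

## Dose–response fitting

Both response lanes (GR and normalized relative total area) are fitted with
the same optimizer on different response columns: least squares on
`f(c) = GR_inf + (1 − GR_inf)/(1 + (c/GEC50)^h)` with the upper asymptote
pinned at 1. GEC50 is parameterized as log10(GEC50) for stability; bounds
are GR_inf ∈ [−1, 1], h ∈ (0, 10], log10(GEC50) within ±3 decades of the
tested range. Starts: GR_inf = min response, GEC50 = geometric mid-range,
and a small grid of slope starts h ∈ {1, 0.5, 2, 4}, keeping the lowest-cost
solution. Replicate-level points are fitted unaveraged by default
(`aggregate_replicates=True` switches to per-concentration means). A flat
response profile or optimizer failure produces a typed, flagged non-fit —
never a silent drop. The residual standard error `sqrt(SSR/(n−3))` is
reported per fit.

Inferred curves use 1,000 concentrations uniform in *linear* units over the
tested range. Linear spacing is the deliberate choice: with full inhibition
(response ≡ 0) the maximum area over the curve then equals the range width
(≈120 for oxaliplatin, ≈320 for SN-38), which matches the magnitude such
AOC summaries are reported at; log-uniform spacing could not produce values
of that order.

## Sensitivity readouts

GR50 (level 0.5 on the GR lane) and ED20 (level 0.8 on the area lane) use
the absolute method: the concentration where the *inferred* curve equals the
level. The crossing is located by Brent root-finding on the analytic fitted
curve (grid lookup would quantize GR50 by up to 0.12 µmol/L on the
oxaliplatin grid); the 1,000-point grid is used only for AOC and
visualization. A curve that never descends to the level within the tested
range is NOT_REACHED (NaN plus a flag); a curve already below the level at
the lowest tested concentration is clamped to that concentration, keeping
reached values inside the tested range. AOC is the trapezoidal integral of
`1 − response` over the grid.

Classification against library medians: lower GR50/ED20 than the median is
sensitive, higher AOC than the median is sensitive; NOT_REACHED GR50 is
resistant and excluded from the median computation; values exactly equal to
the median classify as resistant (a conservative tie rule — with continuous
data the case has measure zero). Treatment allocation uses AOC as the
primary classifier with relative distance `(AOC − median)/median`:
discordant calls pick the AOC-sensitive drug; both-sensitive picks the
largest relative distance above the median, both-resistant the smallest
distance below it; GR50 concordance is reported as supporting evidence only.

Library summaries report the median, IQR (linear-interpolation quartiles),
unscaled MAD (median absolute deviation without the 1.4826 factor), and a
percentile bootstrap 95% CI of the median with 5,000 resamples at fixed
default seed 20260304, resampling samples rather than replicates. The
GR50–AOC relationship is summarized by the Pearson correlation and linear
regression of log2(GR50) on AOC, excluding NOT_REACHED samples.

## Synthetic data

The generator emulates the study conditions: per-well geometric area growth
over the imaging schedule, the two dilution series above, four replicates,
DMSO vehicle wells, sample-to-sample growth heterogeneity, and multiplicative
log-normal measurement noise (areas are strictly positive and measurement
error plausibly scales with size; default sd 0.05). Control day-7 growth is
drawn log-uniform on [1.3, 4.43] — spanning the heterogeneity real libraries
show (control relative areas from about 1.07 to 4.43) while keeping every
sample above the 1.2 success threshold, since the analyses operate on
successful samples. True GEC50s are log-uniform over the middle three
decades of each drug's range (identifiable midpoints), GR_inf uniform on
[−0.3, 0.4], slopes log-uniform on [0.8, 2.5]. Treated-well growth is
constructed by inverting the GR formula, so a noise-free well's
per-replicate GR equals the sample's true GR(c) exactly; parameter recovery
by the fitting stage is therefore a real end-to-end check. All randomness
derives from one user-supplied seed recorded in the output metadata.

The ten idealized samples are defined purely by control growth rates
{10, 5, 4, 3, 2, 1.9, 1.8, 1.7, 1.6, 1.5} and a fixed 20%-per-step rule.
The reduction applies to the *net growth increment* (relative area − 1), so
the top step leaves relative area exactly 1 for every sample — complete
cytostasis (GR = 0). Reducing the relative area itself would drive it
toward 0, i.e. total area loss (cytotoxicity), which contradicts the
cytostasis endpoint; that alternative interpretation remains available via
`reduction_applies_to="relative_area"`. Replicates are generated but
identical, and only days 1 and 7 exist.

Synthetic z-stacks place disc "tumoroids", each sharp in exactly one plane
and Gaussian-blurred in proportion to plane distance elsewhere, with exact
rasterized ground-truth masks. They validate the projection/segmentation
chain; they do not emulate gel-droplet optics, meniscus artifacts, or
instrument metadata. Passing imaging tests therefore show the operators are
correct on well-posed inputs, not that segmentation is robust to real
acquisition artifacts.

## Bias study and paired tests

The idealized study fits both lanes from identical underlying areas and
compares the max/min spread (and CV) of GR50 vs ED20 across the ten samples;
an ED20 not reached in range is censored at the range ceiling with a flag
for the spread statistic. The fast/slow split orders samples by control
growth, assigns the extra sample to the slow half when n is odd, and counts
sensitive calls per half under the median-ED20 and median-GR50 cutoffs.
Paired classifications are compared with McNemar's test: exact binomial when
the discordant count b + c < 25, chi-square with continuity correction
otherwise (the variant switch is this package's documented choice).

## Problem sizes

Default analyses use a 16-sample library (704 wells per imaging day), the
ten idealized samples, 256×256×3 synthetic stacks, noisy-recovery
simulations of 200 runs at 5 concentrations × 4 replicates, and 5,000
bootstrap resamples — sizes chosen so the full pipeline and its tests run
comfortably on a single CPU while leaving the statistics stable.

## Known limitations

- Area is assumed to track viable cell mass; drug-induced morphological or
  metabolic changes can decouple the two.
- No positive-control wells are modelled, so NDR/NOGR-style metrics that
  require them are out of scope.
- The per-sample GR50/ED20 are point estimates; only the library medians
  carry bootstrap uncertainty.
- Under the default heterogeneous parameter distribution the GR50–AOC
  correlation of a synthetic library is weaker than for real libraries or
  for one-parameter curve families, because GR_inf and slope vary
  independently of GEC50; the correlation utilities are exercised on
  constructed families where the expected behavior is provable.
- The segmentation defaults are tuned to clean synthetic imagery; real
  acquisitions will need instrument-specific threshold configuration via
  the pluggable `method`/`threshold` options.
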