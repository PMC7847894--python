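# Methods

## Color traits

Colorimeter output is CIELAB *a\** (green–red) and *b\** (blue–yellow).
The intensity of green color is the ratio `IGC = −a*/b*`; the hue angle
is the standard quadrant-corrected CIELAB angle
`hue = degrees(atan2(b*, a*)) mod 360`, so the color anchors fall at 0°
(red), 90° (yellow), 180° (green), 270° (blue). The quadrant-corrected
form was chosen deliberately: it is the only convention under which
green pods (a\* < 0, b\* > 0) land in (90°, 180°), greener pods approach
180°, and the identity `hue = 90° + arctan(IGC)` holds exactly — the
identity the test suite asserts to 1e−9 degrees, and the reason hue and
IGC correlate at r ≈ 0.99 in any pod data set. Hue is reported without
negative angles so that the quality-index term (120 − hue) stays
interpretable. Calibration-tile checks default to a tolerance of 0.5
units per channel (configurable; instrument certificates rarely state
one).

## The quality index

`EHQI = (HPW/HPWmax) / ((120 − hue)(1 − IGC))` rises with pod weight
relative to the cultivar's own maximum in the same planting date and
environment (computed from the scored data itself, never user-supplied)
and rises as color approaches the 120° anchor. The raw formula is
undefined at hue ≥ 120° or IGC ≥ 1 — arithmetically reachable (a deep
green calibration tile has IGC = 1.85) though rare in pod samples. Two
policies are offered: `reject` (default) drops such rows with a
diagnostic and accounts for them in the run report; `clamp` clips into
(ε, 1 − ε) with ε = 1e−3, consistent with treating the index as a
beta-distributed quantity supported on the open unit interval. Values
≥ 1 from the raw formula are handled the same way.

## Phenology and thermal units

Dates are 1-based day-of-year within one season (planting < Ve < R1 <
harvest enforced). Growing degree days use the average-temperature
method, `max(0, (Tmax+Tmin)/2 − 7 °C)` per day, with the soybean base
temperature of 7 °C; no hourly interpolation. Intervals are half-open
`[start, end)` — the end day contributes nothing — which makes the
day-count and GDD decompositions exactly additive
(Ve→R1 plus R1→harvest equals Ve→harvest to 1e−9). Whether boundary
days belong in such sums is a genuine convention choice; half-open was
picked because exact additivity is what the screening variables assume.

## Response surface and harvest window

Per cultivar, EHQI is fit by OLS on raw scale (not logit) against
planting and harvest DOY and their squares, with no PD×HD interaction;
the surfaces therefore share their harvest-date curvature across
planting dates, and the window width is planting-date-free. Stepwise
term selection (below) is available; the full fit is the default in the
analysis drivers since a dropped linear harvest term would pin the
"peak" at DOY 0. The window at tolerance `t` is
`2·sqrt(t/|β_hd²|)`, validated against a 0.01-day grid scan; widths are
reported raw and rounded to whole days. The reference tolerances
shipped with the package (0.024/0.026/0.015 index units for
8080/R08-4002/R09-345) are the one-standard-error values published with
those surfaces; their provenance (residual vs mean-prediction SE) is
not documented, so tolerance is always an explicit argument rather than
derived from the fit.

## Stepwise selection

Classic bidirectional stepwise OLS: the candidate with the smallest
partial-F p-value enters while p ≤ 0.15; retained terms with p > 0.15
are removed; AIC (`n·ln(SSE/n) + 2(k+1)`, the linear-model form in which
constant offsets cancel; floor-guarded against perfect fits) is tracked after every accepted change
and the minimum-AIC model on the visited path is refit and returned.
Ties break alphabetically, making the result invariant to candidate
column order. Note the statistical consequence of the raw 0.15 entry
threshold: with k pure-noise candidates the probability that *some*
candidate enters is `1 − 0.85^k` (≈ 0.56 for k = 5), so spurious terms
are expected in roughly half of null datasets — the procedure screens
liberally by design. The twelve screening predictors contain exact
identities (Ve→harvest = Ve→R1 + R1→harvest for both days and GDD);
in non-strict mode a redundant candidate reduces SSE by nothing, earns
p ≈ 1 and never enters, so the full candidate list can be offered
as-is. Strict mode raises on exact collinearity instead.

## Neural screen

A single hidden layer of tanh units (default 10) with linear output,
trained by penalized least squares: smoothed L1 penalty
(`sqrt(w² + 1e−8)`) on all weights, L-BFGS optimization, multiple
random restarts ("tours"), and a random holdback validation split
(default 1/3); the restart with the lowest validation RMSE is kept, and
its training-loss trace is monotone non-increasing by the line-search
guarantee. Penalty strength defaults to selection by validation RMSE
over the fixed ladder 1e−4…1e−1. Randomness requires an explicit
integer seed. Variable importance is permutation-based: the *total*
effect of predictor j is the share of prediction variance destroyed
when j alone is permuted (interactions included); the *main* effect is
the first-order share retained when all other predictors are jointly
permuted (a Monte-Carlo first-order sensitivity index); both are
clipped to [0, 1] and total ≥ main is enforced. This is a documented,
portable replacement for proprietary "dependent resampled inputs"
importance schemes; orderings, not exact values, are the meaningful
output.

## Synthetic trials

The generator emulates a 2-year × 2-location staggered-planting trial:
3 planting dates (DOY 135/166/196), 3 cultivars (indeterminate MG3;
determinate MG5 and MG6), 3 blocks, harvests every 5 days from R5.8
until R7, at most 8. Weather is a sinusoidal seasonal mean (15.5 °C
mean, 11.5 °C amplitude, peak DOY 197) with AR(1) daily noise (ρ = 0.7,
σ = 2.5 °C) and a sampled diurnal range. Phenology is thermal-time
driven: emergence 5–8 days after planting; R1 when accumulated GDD
reaches a cultivar requirement (450/600/700 °C·day) reduced by a
short-day acceleration per day of planting delay; fixed R1→R5.8
durations; and an R5.8→R7 span that shrinks with planting delay, so
late plantings fit fewer harvests. Hundred-pod weight follows a
logistic rise (asymptotes 32/30/26 g) with, for the early cultivar
only, a linear decline after day 25 of the harvest sequence; hue decays
exponentially from just under 120° toward 90°, faster for later
plantings; Gaussian trait noise defaults to 2 g (HPW) and 1° (hue).
a\*/b\* readings are back-solved from the hue trajectory with b\* in
the typical 28–32 range, so the colorimetry module recovers the
generating curves exactly in the noiseless case. A 5-day harvest
cadence was adopted as the canonical staggered-harvest protocol
(configurable). All parameters land in a ground-truth ledger.

What the generator does *not* emulate: block- or plot-level random
effects, spatial correlation, weather-trait coupling beyond phenology,
measurement drift, or a calibrated planting-date → quality direction
(in the defaults, later planting *lowers* quality via faster color
decay, whereas multi-environment field results can show the opposite
through effects this generator does not model). Passing tests therefore
demonstrate correct estimation machinery under a plausible data
process, not field-calibrated predictions. Because plot quality depends
on days since R5.8 — which shifts with planting — the pooled quadratic
in calendar DOY is deliberately misspecified for the synthetic data,
and its fitted harvest curvature is weak; parameter-recovery tests
instead generate EHQI directly from a known quadratic (n = 500, noise
σ = 0.05), where coefficients are recovered within 3 standard errors
and window widths within a day.

## Numerical choices and problem sizes

OLS fits go through statsmodels/`numpy.linalg.lstsq`; rank deficiency
is detected and reported with the collinear terms named. AIC's log is
floored at SSE/n = 1e−300. The network trains with L-BFGS (maxiter
500). Test problem sizes (n = 200–2000 observations, 20 replicates for
selection-frequency checks, 1000 colorimeter readings) were chosen as
the smallest sizes at which the statistical claims under test are
well-resolved.
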