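# Methods

This note documents the models, parameter choices, and numerical decisions
behind `larix`, and what the synthetic-data tests do and do not demonstrate
about real field data.

## Microclimate covariates

VPD uses the FAO-56 Magnus saturation curve e_s = 0.6108·exp(17.27T/(T+237.3))
(kPa); VPD = e_s(T)(1 − RH/100). Daily reference evapotranspiration follows
the FAO-56 Penman–Monteith daily formulation with soil heat flux G = 0,
albedo 0.23, actual vapor pressure from daily mean RH and the
(e_s(Tmax)+e_s(Tmin))/2 saturation mean, net longwave from the standard
clear-sky ratio (clipped to [0,1]), and wind at the 2-m standard height (the
measurement height convention is assumed where a record does not state it).
Negative numerators (saturated, radiatively cooling days) clip to 0 —
physical non-negativity. Monthly Thornthwaite PET uses the heat index
I = Σ_(T>0)(T/5)^1.514, the cubic exponent a(I), and mean-daylength /
month-length corrections from standard solar geometry; months at or below
0 °C contribute nothing.

Sub-daily records aggregate to daily means (temperature, RH, VPD computed
per interval, wind, SWC averaged unweighted across depths — layer-thickness
weighting is not attempted) and daily sums (radiation, precipitation). Days
below a completeness fraction (default 0.9 of the modal interval count) are
flagged and masked, except precipitation, which always sums what was
observed so no water is silently lost. Gap filling is deliberately simple
and fully reported: linear interpolation for gaps up to a cap (default 6 h
at 10-min logging), precipitation gaps set to zero instead (interpolating a
gauge invents water); longer gaps stay missing. Imputation quality is not a
scientific claim here, so a deterministic, auditable rule is preferred over
a model-based imputer.

Elevational extrapolation uses constant local lapse rates (defaults
0.54 K and 12 mm yr⁻¹ per 100 m, the values measured on a nearby grassland
transect in the same valley); the precipitation increment is distributed
proportionally over observed events, which preserves event structure and
makes the operation exactly invertible.

## Stem signal

Circumference converts to radius by r = c/2π and is averaged to hourly
means before partitioning (the moving maximum is defined on the hourly
trace; running it at 10-min resolution changes nothing qualitatively but
admits more sensor noise). The partition is the cumulative running maximum;
it is exact, idempotent, and online-consistent, and the package tests it
against a from-scratch quadratic-time oracle.

Daily radius change (DRC) is defined on daily *mean* radii — robust to the
diurnal shrink-swell phase — rather than daily maxima; both daily maximum
and minimum TWD are emitted (models typically use the maximum, growth-period
screening the minimum). Growth-period detection reads "continuously
increasing growth line, high rate, minimum TWD near zero" as: trailing
5-day GRO rate at or above 20% of the season's maximum rate AND daily
minimum TWD ≤ 30 um; the longest contiguous run of qualifying days wins,
and a mid-season drought that breaks the run leaves the longer fragment.
All three thresholds are parameters; externally tabulated growth windows
can simply bypass detection.

## Gompertz phenology

The growth-parameter form y = A·exp(−exp((μe/A)(λ−t)+1)) is used because
its parameters are the quantities compared across sites and years and the
inflection point is analytic (I_p = λ + A/(eμ), y(I_p) = A/e) — no numeric
argmax, exact testability. Fitting is bounded trust-region least squares
with data-driven initials (A = max increment, μ = max daily difference,
λ = first day above 5% of max) and a small seeded multistart (8 starts).
The series is shifted to zero increment at the season start using the mean
of the first five readings; anchoring at the single first reading would
inject that one observation's noise into A and λ directly. Degenerate
inputs (flat, short, all-zero) return an honest non-converged flag with NaN
parameters rather than a fabricated fit. On noise-free curves parameters
recover to at least four significant digits; at σ = 20 um of additive noise
on a 150-day season, A recovers within 2% and λ within 2 days in ≥ 90% of
seeded replicates.

## Sap flow

Rates are per unit circumference, so tree scaling is multiplication by
C_eff = C − 2π·t_bark; bark + phloem thickness has no hidden default — it
is a required geometry input. Multi-sensor trees (north/south) average
sensors per timestamp before scaling; single-sensor periods are used as-is.
Negative night-time rates clip to zero with a count. Daily sums use step
integration at the logging interval (1 kg = 1 l); incomplete days are
flagged and excluded from site means, which are arithmetic means ± SE over
trees present that day.

## Ring widths and chronologies

Tucson RWL reading auto-detects the 0.01-mm (999 terminator) and 0.001-mm
(−9999) dialects per series; writing supports both. All statistics operate
on total ring width.

Detrending is conservative two-stage ratio standardization: stage 1 fits
w = a·e^(−bt) + k with a > 0, b ≥ 0, k ≥ 0, falling back to a linear fit
with non-positive slope and finally to the horizontal mean whenever the fit
fails or predicts non-positive widths; stage 2 fits a cubic smoothing
spline to the stage-1 ratios with the penalty λ = (p/2π)⁴ chosen so the
frequency response is 50% at wavelength p = (2/3)·series length (the
standard amplitude-of-a-sinusoid calibration of the penalized cubic
spline). Indices are ratios at both stages, so an exact negative-
exponential series yields RWI ≡ 1 and simulated trend × lognormal noise
yields mean index within 0.02 of 1.

Prewhitening fits AR(p), p = 0…3, by conditional least squares with a
constant, conditioning every order on the same three initial years so AIC
values are comparable, and returns residuals plus the series mean (level
preserved). Pure AR rather than full ARMA keeps the order search
identifiable on ~100-yr series. AIC is known to overfit white noise with
probability ≈ P(χ²_p > 2p) per extra lag, so order 0 is the modal but not
near-certain choice on white noise (~70% of runs); what matters downstream
— residual lag-1 autocorrelation below 0.1 on AR(1) input, output ≈ input
on white input — holds and is what the tests assert.

The chronology is a per-year Tukey biweight robust mean (c = 9, median
start, ≤ 10 iterations, MAD-degenerate years return the median) with sample
depth recorded. Mean sensitivity and first-order autocorrelation are
computed on raw widths (per series, then averaged); rbar is the mean
pairwise Pearson correlation of prewhitened indices over common years
(minimum overlap 30 yr), feeding SNR = N·rbar/(1−rbar) and
EPS = N·rbar/(N·rbar+1−rbar).

Crossdating QC correlates each prewhitened 50-yr segment (lag 25) against
the biweight master of all other series. A segment fails when its
correlation at dating position falls below the one-tailed critical r at
α = 0.01, or when some lag within ±10 yr beats the dated position by more
than 0.05 — the latter is what actually catches a coherent but mis-dated
series, whose absolute correlation can remain above the critical value.
Flagged segments carry the best lag as the suggested correction.

## Response functions

The predictor matrix holds monthly mean temperature and monthly
precipitation totals from previous-year June through current September
(16 months × 2 variables = 32 columns; the window is configurable and spans
every month the analyses report). Columns are standardized; the
eigenvector rotation is computed **once** from the full-sample correlation
structure (SVD), components retained by the Kaiser rule (eigenvalue > 1;
a cumulative-variance rule is available), the standardized chronology
regressed on the retained scores, and coefficients back-rotated to the
monthly predictors. The bootstrap resamples years with replacement
(default N = 1000), re-estimating only the regression on the fixed scores;
percentile intervals at α give significance (CI excluding zero). This
fixed-rotation design is the classical response-function algorithm, and it
is also statistically the right one here: re-running component selection
inside every resample shrinks the bootstrap distribution's center toward
zero and makes the test measurably conservative (null false-positive rate
≈ 0.017 instead of the ≈ 0.05 the fixed rotation delivers), while basic or
bias-corrected intervals overshoot (≈ 0.13). When all components are
retained the back-rotated solution equals OLS on the standardized
predictors to machine precision — a dual-route check the tests enforce.

Moving windows (default 25 yr, step 1, α = 0.1) rerun the static analysis
per window, each window drawing an independent substream of the seed so
results do not depend on which windows get evaluated; windows with mean
sample depth below 5 trees are excluded when depth is supplied.

## Upscaling

CWD = annual precipitation − annual Thornthwaite PET. Cells below −2.5 °C
mean annual temperature are beyond larch's cold limit regardless of CWD.
The two CWD cut points are *calibration outputs*, never constants: the five
transect site climates are synthesized from the valley station normals
(528 mm, 6.6 °C at 1570 m) with the local lapse rates and a synthesized
seasonal cycle (±9 K around the annual mean, July peak — a typical
continental-alpine amplitude, used wherever a monthly cycle must be built
from an annual mean), and the cuts are placed at the CWD midpoints between
the site pairs that must straddle them. Warming scenarios add a uniform ΔT
to every month (the scenario source gives only an annual figure) and scale
annual precipitation; classification commutes with pre-transforming cells.

## Synthetic data

The generators define the study conditions and are pure functions of
(spec, seed). Weather is valley-wide: one seed drives one synoptic
realization (AR(1) daily temperature anomalies, φ = 0.8, σ = 1.5 K; a
two-state precipitation occurrence chain with gamma amounts scaled to the
site's annual normal; radiation as a clear-sky envelope times a rain-tied
cloud factor; RH anticorrelated with the temperature anomaly; a single-
bucket soil with temperature-driven demand), and sites differ by the
deterministic lapse structure plus scripted droughts — so elevational
contrasts are exact by construction. Scripted droughts suppress rain,
ramp the soil to a floor within the first third of the episode (shallow
alpine soils deplete fast), and break with a two-day convective rain pulse,
because the tested TWD relaxation ("back near zero within days") requires
the drought to end in rewetting, as real episodes in such records do.

Dendrometer traces realize the zero-growth reading by construction: the
Gompertz rate integrates into the radius only while the drought shrinkage
is at or below 10 um (growth lost in an episode is not caught up); diurnal
shrinkage is proportional to the day's VPD with a daylight bell that
returns to zero at night, so nightly maxima trace the growth line. Sap
flow is qmax·sat(PET)·sat(SWC−wilt) daily amplitude (saturating
Michaelis-type responses, k_PET = 1.5 mm, k_SWC = 0.08 m³ m⁻³) under a
daylight bell with lognormal day-to-day noise; the high-elevation variant
drops the soil term, reproducing the observed decoupling of sap flow from
soil moisture where water is ample. Ring widths are
age-trend × exp(s·(βz_climate + AR(1) background + individual noise)) with
the background variance solved so the expected interseries correlation
equals the rbar target given the individual noise; monthly temperature
anomalies persist month-to-month (ρ = 0.5) so the predictor matrix is
genuinely collinear — the premise of principal-components regression. Two
cores per tree add small lognormal measurement noise; widths are rounded
to whole micrometres so RWL round trips are lossless.

What passing these tests shows: the algorithms are correct on data whose
generating process is known, at realistic noise levels and sample sizes.
What they do not show: robustness to the pathologies of real records —
sensor jumps and drifts, bark hygroscopicity, missing-ring and double-ring
errors beyond the simulated one-year shifts, non-stationary age effects,
disturbance pulses (e.g. defoliator outbreaks), or imputation bias in long
gaps. The pipeline's defaults (2 dendrometer trees per site, 8–10 ring
trees, 70–90 yr, 100–200 bootstrap resamples in orchestrated runs; 1000 in
standalone analyses) are chosen so a full run completes in seconds while
keeping every statistic well inside its asymptotic regime; all are config
keys.

## Numerical details and degenerate inputs

Empty traces, all-zero seasons, constant series, zero-variance indices,
single-sensor trees, single-tree sites, MAD-zero biweight years, segments
shorter than the crossdating window, cells with all months below freezing:
each has an explicit, tested behavior (error, flag, or exact closed-form
result) rather than a silent default. Partition exactness is bitwise
(running maximum and subtraction; the identity r = GRO − TWD is exact in
floating point for realistic positive radii). Bootstrap and generator
randomness always flow from explicit seeds; identical seeds give
bit-identical outputs, including file hashes in the pipeline manifest.
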