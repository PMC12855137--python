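# Methods

## Signal model

The LPCP probe output pressure P_p (kPa) is inversely related to leaf
turgor. Two diurnal regimes are distinguished:

* **State I** (no/mild stress): a unimodal curve with a single principal
  maximum around midday and nocturnal minima, passing through four
  sequential stages — valley fluctuation, rapid rising, peak fluctuation,
  decay.
* **State II** (severe stress): a troughed curve with a pronounced daytime
  minimum, in 'N', 'M' or 'V' shapes. Physiologically the probe signal in
  this regime reflects bulk internal gas-volume changes after stomatal
  closure rather than fine turgor variation, which motivates both the
  flattened curve shapes and the saturated soil-water response in the
  generator (below).

## Classification

The rate rule computes the mean P_p rise rate over 05:00–10:00 and the
mean fall rate over 15:00–20:00 (fall rate is the negated slope, so both
rates are positive on a unimodal day). "Mean rate" is operationalised as
the least-squares slope of P_p against clock time over the half-open
window — robust to single-sample noise; an endpoint-difference variant is
available via `ClassifierPolicy(rate_method="endpoint")`. Both rates
negative → II-V; exactly one negative → II-N; both positive → provisional
State I.

Manual screening of provisionally unimodal days is formalised as a
deterministic extrema screen: the daytime segment (06:00–20:00) is
smoothed with a 35-minute centred moving average, and local maxima with
prominence above 10% of the daily range are counted; two or more such
maxima override the label to II-M. Prominence (rather than raw height)
encodes "separated by a deep trough". A rate within 1e-12 of zero is
resolved by the tie policy (counts as positive) and flagged; completely
flat days are refused by stage segmentation. Classification is
deterministic and invariant to adding a constant to the whole curve.

Stage segmentation of State-I days: the valley ends when the smoothed
derivative first exceeds +0.5 kPa/h (`eps`); the rise ends when the
smoothed curve enters the band within 5% of the daily range below the
smoothed maximum (`delta_frac`); the peak stage lasts while the curve
stays in the band; the rest is decay. Both thresholds are configurable.

Gap policy: a day is excluded from classification when any rate window,
the daytime segment, or the whole day is missing more than 5% of its
5-minute slots; smaller gaps are filled linearly. The rate rule needs
dense windows, so exclusion is preferred over imputation of long gaps.

## Thresholds and correlations

The stress thresholds are the empirical support boundaries of the
state–SWC relationship: U is the largest SWC carrying a State-II day, L
the smallest SWC carrying a State-I day; [L, U] is the ambiguous band
where both states occur. Integer rounding is applied only for reporting.
Correlations between P_p and each environmental factor are Pearson
coefficients over instantaneous 5-minute samples within a state scope,
with two-sided significance at α = 0.05 from the t-transform of r; no
multiple-testing correction is applied (per-pair flags, six pairs). A
daily-mean option exists for interday analyses.

## Predictive models

Four combinations pair the input set (Rs, T, RH, WS, VPD, optionally SWC)
with the output mode (whole-state vs substate P_p). Substate models fit
one regressor per diurnal state and route prediction by the row's day
label; substate metrics are pooled over the union of per-state held-out
predictions so all combinations are scored on identical rows. The split
is a seeded uniform random 80/20, stratified by state in substate mode; a
chronological split is available for leakage-aware use.

Metrics follow the standard definitions R² = 1 − SSE/SST, MSE = SSE/n,
RMSE = √MSE, MAE = Σ|Y−y|/n, implemented directly and cross-checked in
the tests against scikit-learn's implementations to 1e-9.

Hyperparameters are fixed and recorded rather than searched by default:
random forest with 300 trees considering all features per split (the
forest is variance-limited, more trees only help); XGBoost at its library
defaults (100 rounds, depth 6, learning rate 0.3); RBF-kernel SVR with
C = 10, ε = 0.1 behind a standardising pipeline. Fixed settings keep every
report bit-reproducible at a given seed and the 48-configuration
experiment matrix tractable on one CPU; `tune=True` runs the small
recorded grids with 3-fold cross-validation on the training partition.
Kernel SVR scales quadratically in n, so its training partition is
subsampled (seeded) to 3,000 rows; the tree ensembles use all rows.
Feature importances are normalised impurity importances for the tree
ensembles and labelled permutation importances for SVR. A degenerate
(zero-variance) training target produces a warned constant predictor
rather than an error, so one broken configuration cannot abort the
matrix.

## Sensitivity scenarios

"SWC increased or decreased by 5%" is interpreted as **absolute
percentage points** of volumetric soil water (20.93 → 25.93), because
baselines and thresholds are quoted in points; a relative mode (×1.05) is
selectable. Scenario predictions are compared against the predictor's own
baseline predictions, never against measurements, so each delta isolates
the modelled soil-water response; perturbed SWC is clipped to
(0, θ_f]. Shifted predictions keep the baseline day labels for state
attribution; re-classifying the predicted curves is available as a
diagnostic. Tree-ensemble predictors clamp rather than extrapolate
outside the training SWC support, so responses attenuate (but keep their
sign) once a shift leaves the observed range.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
not greenhouse physics:

* **Meteorology.** Net radiation is a daylight half-sine (exactly zero at
  night) with day-to-day amplitude jitter (s.d. 12%) and a 15% chance of
  an overcast day at 25–50% amplitude; daylight windows are 06:00–19:00
  (summer tomato) and 06:30–18:30 (winter celery). Temperature is a
  diurnal sinusoid peaking at 14:30 whose daily mean tracks the radiation
  amplitude; relative humidity runs anti-phase with temperature, bounded
  [20, 100]%; wind is a small positive flow calmest around midday (still
  greenhouse air under midday stagnation), giving the observed negative
  wind–P_p association. VPD is always derived from simulated T and RH
  with the same closed form the ingest stage uses — never drawn
  independently — so the feature set is internally consistent. Sensor
  noise is small (T 0.05 °C, RH 0.3%) so that instantaneous meteorology
  carries the time-of-day information a real logger record carries.
* **Soil water.** Daily SWC decays exponentially between irrigation
  events and steps up at each event in proportion to depth, capped at
  field capacity θ_f (32% tomato, 38% celery). Without an explicit
  schedule a 25-day cycle spans the crop's characteristic drawdown range
  (14–26% tomato, 12–24% celery), sampling densely near the state bounds.
* **States.** Days with SWC above U* (20% tomato, 19% celery) are planted
  State I, below L* (18%, 16%) State II, and inside the band a seeded
  Bernoulli draw (p = 0.5; the mixed-zone frequency is a free parameter).
  State-II subtypes default to a stress-depth rule — N just below L*, M
  at moderate deficit, V at severe deficit — making the day's curve a
  function of observable soil water; an unconditional mixture draw with
  the renormalised N/M/V frequencies is available
  (`subtype_mode="mixture"`), but two equal-moisture days with different
  subtypes would then carry irreducible prediction error by construction.
* **P_p curves.** Each state/subtype has a fixed diurnal template
  (monotone-cubic through clock-hour knots; the State-I template encodes
  the four stages). The curve level is
  `night_base · (1 + level_coef · s)` with night_base = 20 kPa,
  level_coef = 7 and s the normalised drying stress
  (θ_f − SWC)/(θ_f − L*), so the probe output drifts strongly upward over
  a drying cycle — the dominant interday feature of real records and the
  reason soil water ranks first in feature importance. On State-II days
  the level response saturates (slope factor 0.3 beyond s = 1) and the
  diurnal amplitude is flattened to 35%, reflecting signal collapse; this
  also makes every environmental association weaker within State II than
  within State I. The amplitude is `40 kPa · (1 + 0.5·s) ·` (that day's
  radiation peak / nominal). Deficit treatments scale the daily minimum
  and maximum (tomato T0 ×1.5/×1.3, celery CDI ×1.38/×1.3), placing the
  State-I extrema elevations in the middle of the observed
  full-vs-deficit contrast ranges. Additive Gaussian noise has s.d. 0.3%
  of the daily range by default; all samples stay positive.
* **Fixed scenarios.** Four benchmark seasons ship with explicit state
  plans — tomato-TB-2021 (65 days, 61 State I), tomato-T0-2021 (65 days,
  10 State I), celery-CFI-2022 (60 days, 42 State I), celery-CDI-2022
  (60 days, 35 State I); season lengths are back-derived from the
  reference State-I percentages. Plan-consistent SWC draws each
  same-state run as a linear drawdown that passes through the ambiguous
  band on both sides, so the same soil-water value can carry either
  state; that overlap is what makes substate modelling genuinely
  outperform whole-state modelling rather than trivially tie it.
  Ground-truth labels are emitted beside the data and never consumed by
  the pipeline under test.

## What passing tests do and do not show

The generator produces noise-free-classifiable template curves, state
labels tied to soil water by construction, and meteorology without sensor
drift, data gaps, probe slippage or leaf-to-leaf variability. Perfect
label recovery at zero noise and ≥95% at 2%-of-range noise therefore
validates the classifier logic, not its field performance; the benchmark
accuracy figures show that the modelling pipeline attains the reference
accuracy class on data with the assumed structure, not that it would do
so on new field records. Threshold recovery demonstrates the estimator is
consistent with the planted bounds under dense sampling near the band —
with sparse SWC observations the support boundary is biased inward (the
README's worked example shows a single 65-day season recovering a
conservative lower bound for exactly this reason).

## Problem sizes and numerical choices

Benchmark runs use the four fixed seasons (250 days, 72,000 grid rows)
with per-treatment models; the experiment matrix (4 combinations × 3
techniques × 4 treatments) completes in a few minutes on one CPU, and
threshold studies use 200-day single-treatment seasons. Ties in daily
extrema resolve to the earliest slot; template evaluation uses monotone
cubic (PCHIP) interpolation to avoid overshoot between knots; seeded
streams are spawned per generator component, so a season is byte-identical
across runs at a fixed seed.

## Known limitations

No probe drift or recalibration events; single-depth (profile-mean) soil
water; no temporal blocking in the default split (use `split` options for
leakage-aware evaluation); per-treatment models do not transfer across
treatments; the per-scenario kPa magnitudes of the sensitivity analysis
depend on the data a model was trained on, so only the direction of the
soil-water response is asserted, never particular kPa values.
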