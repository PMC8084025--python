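# Methods

This note documents the models implemented in `hydricniche`, the
reasoning behind the open design choices, the synthetic-data conditions
under which the package is tested, and known limitations.

## Development-rate model

Embryonic/larval development rate is modelled as a five-parameter
unimodal function of temperature. With the scaled deviation
*v* = (*T* − *b*₃)/(*b*₃ − *b*₂):

- *T* ≤ *b*₃:  r(T) = *b*₁ · 10^(−v²)
- *T* > *b*₃:  r(T) = *b*₁ · 10^(−v²) · max(0, 1 − (*b*₄+*b*₅)·v²)

Parameters: *b*₁ peak rate (% development day⁻¹, > 0); *b*₂ a lower
reference temperature (°C) setting the curve width (*b*₂ < *b*₃); *b*₃
the temperature of peak rate, i.e. the thermal optimum (°C); *b*₄, *b*₅
dimensionless shape parameters of the supra-optimal flank (*b*₄+*b*₅ > 0).
The sub-optimal limb is a log₁₀-scale Gaussian in *v*: development
merely slows at cold temperatures and the curve never reaches zero
below the optimum. The supra-optimal limb multiplies that envelope by a
concave quadratic that reaches zero at

  T₀ = *b*₃ + (*b*₃ − *b*₂)/√(*b*₄ + *b*₅),

giving the curve a genuine finite upper limit. The functional form was
designed to satisfy four structural requirements — r(*b*₃) = *b*₁
exactly, unimodality with argmax *b*₃, a strictly decreasing
supra-optimal flank, and a finite fall-to-zero temperature — and its
zero locus was calibrated so that the packaged *Geocrinia* parameter
sets place the fall-to-zero temperature at the species' published
CT_max values (29.59 °C vs 29.6 °C for *G. alba*; 30.06 °C vs 30.0 °C
for *G. vitellina*). *b*₄ and *b*₅ enter the zero locus only through
their sum, which is why *b*₅ is conventionally fixed (at 0.4) when
fitting: freeing both leaves the pair weakly identified, consistent
with the very large standard errors reported for *b*₄-type shape
parameters in this kind of fit.

### Rate summation

Duration under a temperature regime is predicted by accumulating
r(T_t)·(Δt/24) per step (default Δt = 1 h) until cumulative development
reaches 100%, interpolating linearly inside the final step. Hourly
series shorter than the incubation are recycled periodically, so a
single 24-h diel cycle suffices for a sine-wave regime. For constant
regimes the computation reduces exactly to 100/r(T). A regime whose
temperatures all lie outside the viable range raises a non-completion
error rather than returning infinity.

### Fitting

`fit_rate_curve` minimises residuals between observed and predicted
durations with scipy's bounded trust-region least-squares solver.
Residuals are on the duration (days) scale by default — the scale on
which the raw observations live and on which a residual sum of squares
of a few tens of days² is interpretable — with a rate-scale option
(100/duration residuals) for users who prefer to weight fast regimes
more heavily. Constant regimes use the closed form; fluctuating regimes
go through rate summation of the recorded hourly series, not through
their mean temperature, because Jensen's inequality makes the mean
temperature a biased summary of a fluctuating regime near the curve's
bends. Five jittered starts (deterministic in the `seed` argument)
guard against the flat high-temperature tail; standard errors come from
a central-difference Jacobian at the optimum (the solver's internal
Jacobian is unreliable once bounds enter the trust region) via the
usual (JᵀJ)⁻¹·RSS/(n−p) covariance. Fixed parameters (any subset,
`{"b5": 0.4}` by default in the pipeline) are honoured exactly and
excluded from the covariance.

### CT_max rule

CT_max is located by scanning a 0.01 °C grid upward from *b*₃. Because
this functional form reaches exactly zero, the first grid point with
zero rate is reported (rule `exact-zero`); for curve forms that never
vanish, the first grid point at or below ε·*b*₁ is used instead
(ε = 0.01 by default). The rule actually applied — criterion, ε, grid
step — is recorded in the returned thresholds object. The estimate is
monotone non-increasing in ε and converges at first order in the grid
step.

## Water balance and the absorption threshold

Fluxes are area-normalised as 1000·Δm/SA/Δt (mg cm⁻² h⁻¹) with
SA = 9.9·mass^0.56 cm² evaluated at the frog's *standard mass* (fully
hydrated, empty bladder). Standard mass, not instantaneous mass, is
used because a single area must normalise a 2-h trial during which mass
changes, and standard mass is the one well-defined per-animal covariate.
Trials in which the frog urinated or defecated carry an `excluded`
flag set by the experimenter; no detection algorithm is attempted.

The absorption threshold is estimated from per-treatment mean fluxes.
The default `bracket` method scans from the wettest treatment downward
and interpolates linearly between the first adjacent pair of means that
bracket zero — mirroring how a two-treatment refinement experiment
localises the crossing between neighbouring water potentials. An
`isotonic` option first projects the means onto the best monotone
(non-decreasing in ψ) fit before interpolating, which is robust when
noise makes the raw means non-monotone. Treatment water potentials are
taken as exact. Dehydration/rehydration rates are the interpolated
slope of the mass series between two hydration fractions (defaults
1.0 → 0.9; the mirror 0.89 → 1.0 analyses rehydration), returned as a
magnitude in g h⁻¹ and % standard mass h⁻¹.

## Soil water retention

Conversions between volumetric water content θ (%) and water potential
ψ (kPa ≤ 0) use the van Genuchten form
θ(ψ) = θr + (θs−θr)·[1+(α|ψ|)ⁿ]^(−m), m = 1−1/n — the standard
laboratory retention model — and its closed-form inverse. The packaged
curves are *synthetic calibrations*: plausible θr/θs/n values for a
sandy (4/40/1.6) and a clayey (10/48/1.25) soil with α solved
analytically so each curve passes exactly through its anchor
(10.5% VWC ↔ −50 kPa for sand, 27.6% ↔ −50 kPa for clay). They are
faithful at the anchor by construction and qualitatively reasonable
elsewhere; site-specific laboratory curves should replace them for real
analyses (any curve can be supplied as config data). ψ is in kPa
throughout; hysteresis and temperature dependence are not modelled.

## Microclimate exceedance

Sensor series are summarised per site over a July 1–June 30 window (the
austral year, so one summer dry-down falls wholly inside each window).
A calendar day exceeds the absorption threshold when any non-missing
30-min ψ reading is strictly below it, and a temperature threshold when
any reading is strictly above — breaching a physiological limit at any
time of day is the biologically conservative reading of "a day
exceeding". A `daily-mean` rule is exposed for sensitivity analyses
(`daily-extreme` is an accepted alias of `any`, to which it is
mathematically identical). Ties exactly at a threshold never count.
Days with no readings drop out of the denominator; days with partial
readings count normally; nothing is imputed, so removing readings can
never increase an exceedance count. Partial windows are reported with
their `n_days_observed` rather than rescaled. The
exceedance-vs-population-size association uses Spearman rank
correlation (average ranks for ties, two-sided t-approximation
p-value), pairing sites by id and failing loudly on unmatched ids.

## Trend statistics

Mann–Kendall: S = Σ sign(x_j − x_i) over ordered pairs, variance with
the standard Σt(t−1)(2t+5)/18 tie correction, Z with the ±1 continuity
correction (the usual convention; it can be disabled), two-sided normal
p-value; τ = S/(n(n−1)/2). Sen's slope is the median of all pairwise
slopes (x_j − x_i)/(year_j − year_i) — year gaps enter the denominators,
so missing years are handled naturally — with the rank-based 95% CI at
indices (N ∓ z₀.₉₇₅√varS)/2 into the sorted slopes (lower floored,
upper ceiled: a conservative convention, recorded here because several
are in circulation). Decadal slopes are 10× annual. Anomalies are
deviations from the 1961–1990 mean (the WMO climate-normal reference),
optionally as percent of that mean. Percentile ranks use the mid-rank
convention — the mean of the < and ≤ conventions, so full ties score
50 — recorded in this note because conventions differ. Year windows
("past 30 years") are closed ranges supplied by the caller. A lag-k
autocorrelation utility with ±1.96/√n white-noise bounds supports the
usual pre-check; serial-correlation-corrected Mann–Kendall variants are
out of scope.

## Field water loss

Percent mass loss per hour is 100·(m_out − m_in)/m_out divided by the
deployed hours, standardised to a common 9-h daytime exposure by
multiplication. A standardised loss above 100% is unphysical (it would
extrapolate past the model's total water content), so it is capped at
100 and flagged (`n_capped` in summaries) rather than silently altered;
with realistic loss rates the cap never binds. Group summaries report
mean ± SE and n per habitat (default: only 25 m and 50 m deployments,
since 0 m models sit on the habitat boundary) or per cover-type ×
size-class; groups emptied by filtering are reported with n = 0, and
single-member groups carry SE = NaN. Cross-group inference
(ANOVA/Tukey) is deliberately left to standard statistical packages —
this module's contract ends at correct reductions.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of a `GeneratorConfig` (truth
parameters + seed); identical configs give bit-identical output, and
each generator draws from an independent seeded stream.

- **Incubation**: durations are rate-summation predictions from the
  truth curve (default: the packaged *G. alba* parameters) at the seven
  study regimes — constant 15/18/20/21/25 °C and 24-h sine-wave
  21 ± 2.5 and 25 ± 5 °C — plus Gaussian noise (SD 1 day, chosen to
  match the scale of the published *b*₃ standard error of 0.7 °C), four
  split clutches per regime.
- **Water flux**: mean flux is piecewise linear in ψ, zero at the truth
  threshold (−50 kPa), with slopes 0.08 (wet limb) and 0.05 (dry limb)
  mg cm⁻² h⁻¹ kPa⁻¹ — giving ~4 mg cm⁻² h⁻¹ uptake in free water and
  losses of a few mg cm⁻² h⁻¹ on dry paper, the magnitudes typical of
  small myobatrachid frogs — plus per-measurement Gaussian noise
  (SD 0.3), 10 frogs across 10 treatments from 0 to −200 kPa.
- **Microclimate**: 30-min series over one austral year. Soil is
  saturated (−5 kPa) through the wet–cool winter and dries down over a
  150-day summer window as a raised-cosine bump on log₁₀|ψ| to a
  site-specific minimum (−20 … −200 kPa across the eight default
  sites); temperature is an annual sinusoid (winter ~12 °C; site summer
  maxima ~19.5–30 °C so that some sites breach the thermal optimum and
  only the driest site grazes CT_max) plus a 2.5 °C diel sinusoid
  peaking mid-afternoon. Noise is Gaussian on log₁₀|ψ| (SD 0.05) and
  additive on temperature (SD 0.3 °C). Within the noiseless skeleton ψ
  is constant within each day, so exceedance-day counts are exactly
  computable from the formula — the basis of the construction tests.
  Default calling-male counts decline from the wettest to the driest
  site, so the exceedance–population correlation is strongly negative
  by construction.
- **Climate**: linear trend plus Gaussian noise; defaults −10.9 mm yr⁻¹
  on a 1000 mm base over 1990–2019 with SD 80 mm.
- **Deployments**: per-group truth means (6.4 / 13.5 / 31.0% per 9 h for
  frog / adjacent riparian / adjacent terrestrial habitat; 4.5–6.5%
  under cover vs 26% in the open), juveniles scaled ×1.3, adult and
  juvenile model masses 1.97 ± 0.16 g and 0.46 ± 0.07 g, loss noise
  SD 2% per 9 h, exposures 9–11 h.

What passing tests on these data do **not** show: real soils have
autocorrelated weather-driven noise, rain pulses and sensor drift, none
of which the seasonal skeleton contains; real flux data have per-frog
random effects rather than i.i.d. noise; real incubation noise is
likely heteroscedastic across temperatures. Recovery under the
synthetic conditions demonstrates correctness of the estimators, not
field-data robustness.

## Numerical choices and degenerate inputs

Grid scans use 0.01 °C steps; the CT_max scan stops at 60 °C and raises
if the criterion is never met. The fitter clips starts into bounds,
penalises the infeasible region b₂ ≥ b₃ − 0.5 smoothly, caps predicted
durations at 10⁶ days where a regime is (nearly) non-viable, and raises
a diagnostic error with final cost and gradient norm if no start
converges. The bracket threshold estimator takes the first sign change
scanning from the wettest treatment; an exactly-zero treatment mean is
returned as the threshold itself. Retention-curve conversions are
undefined at and below θr (an out-of-range error), and saturation maps
to ψ = 0 exactly. Sensor validation requires increasing, non-duplicate
timestamps and non-positive ψ. Mann–Kendall with all-tied values
returns Z = 0, p = 1 rather than dividing by zero.

## Problem sizes

Default test and pipeline sizes — 28 incubation observations, 100 flux
measurements, eight one-year 30-min sensor series (~17.5k readings
each), 30-year climate series, 200-replicate recovery and calibration
loops — were chosen so the full suite and the acceptance script each
run in seconds on a single CPU while leaving estimator standard errors
well inside the tolerances they are tested against.

## Known limitations

- The development-rate curve is one defensible unimodal form; other
  forms (β-type, Lactin) fit such data comparably and would shift the
  extrapolated CT_max by a few tenths of a degree. CT_max here is a
  curve-extrapolation construct, not an observed lethal endpoint, and
  acclimation effects (±1–2 °C) are not modelled.
- Embryonic mortality is not modelled; the rate curve treats all
  clutches as surviving to stage 39.
- The packaged retention curves are anchored at a single point each;
  they are placeholders for laboratory-determined curves.
- Population estimates assume exactly two frogs per calling male.
- No body-temperature biophysics: soil temperature stands in for frog
  temperature, which is conservative (evaporative cooling would lower
  actual body temperature).
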