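# Methods

This note documents the models, numerical choices and limitations behind
`brockmet`; everything quantitative stated here is computed by the package's
tests or by `scripts/acceptance.py`.

## Gas exchange

An open-circuit (flow-through) respirometry chamber is supplied with
incurrent air at flow FR (ml·min⁻¹, STP) containing O2 and CO2 fractions
FiO2 and FiCO2; the animal's O2 uptake and CO2 release change both the
excurrent fractions (FeO2, FeCO2) and the excurrent flow itself, because the
two exchanged gas volumes do not cancel unless RQ = 1. With excurrent flow
unmeasured, the standard corrected equations are used:

    V̇O2  = FR·[(FiO2 − FeO2) − FeO2·(FeCO2 − FiCO2)] / (1 − FeO2)
    V̇CO2 = FR·[(FeCO2 − FiCO2) − FeCO2·(FiO2 − FeO2)] / (1 − FeCO2)

These are first-order-exact in the fraction differences: against the
simulator's explicit volumetric bookkeeping (below) the residual error is of
order FeO2·FeCO2·(V̇CO2 − V̇O2), about 0.02% at the depletions this design
targets; the test suite bounds it at 0.1%.

Energy uses the oxyjoule factor (15.97 + 5.164·RQ) J·ml⁻¹ O2, whole-animal
rates are reported in kJ·d⁻¹, and the unit bridge
kJ·d⁻¹ ↔ ml O2·h⁻¹ ↔ ml CO2·h⁻¹ ↔ mass-specific variants is exactly
invertible (round-trip < 1e−9 relative). kcal converts at 4.184 kJ·kcal⁻¹
throughout.

Conventions: fractions are proportions internally, percent only in files;
flow is assumed already STP-corrected (the flow meter reports STP); default
incurrent fractions are 0.2095 (the outside-air calibration value) and
0.0004 for CO2 — the incurrent CO2 is a package default, not a measured
value, and is overridable. RQ outside [0.7, 1.0] warns but is never clamped:
clamping would silently distort the energy values. Water-vapour dilution and
barometric corrections are out of scope.

## Trace processing

**Drift.** Analyser drift is assumed linear in time; the measured-minus-true
ambient offset at the pre- and post-session baselines is interpolated to
each reading and subtracted. A single constant baseline is expressed by
giving both readings the same gas values.

**Stable segment.** "Stable value" is operationalised as a window of at
least 15 min whose least-squares O2 slope is ≤ 0.0005 %O2·min⁻¹ in magnitude
and whose O2 range is ≤ 0.01 %O2 (all three configurable). Among qualifying
windows the one with maximum mean excurrent O2 — minimum O2 consumption —
is selected, ties broken by latest start; the window mean (not the last
point) is the segment statistic, for noise robustness. On a monotone
washout these tolerances admit windows slightly before full equilibration,
a ≲1.5% bias at the loosest defaults; analyses that need tighter accuracy
(e.g. the anaesthesia phase comparison) pass a slope tolerance of
0.0001–0.0002 %O2·min⁻¹.

**QC.** The flow is chosen to hold O2 depletion between 0.2 and 0.8
percentage points; measurements outside the band are flagged
(`depletion_out_of_band`), never silently dropped. QC flags abort a run only
under `--strict`.

**Anaesthesia sessions.** Phase marks partition a session into
before/during/waking/after; the waking phase (intermittent movement) is
transitional and yields no RMR. An "after" measurement is flagged
(`recovery_lag_short`) unless its phase begins ≥ 120 min (configurable)
after the waking mark.

**Lower critical temperature.** From ordered (temperature, RMR) pairs the
LCT estimate is the lowest temperature attaining the series minimum — RMR
stops decreasing with warming at the lower edge of the thermoneutral zone.
Constant series resolve to the lowest temperature by the same rule.

## Allometry

The four literature power laws ship as presets (Iversen 1972 large
mustelids, Kleiber 1961 mammals, White & Seymour 2003, McNab 2008
carnivores), each evaluated in its native mass/output units and converted to
kJ·d⁻¹; ml O2·h⁻¹ outputs convert at a default RQ of 0.76, the study-average
value. Scaling fits are OLS of log10(RMR) on log10(mass), reported as the
antilogged intercept (mass scaling coefficient) and slope (exponent).
Percentage *error* is (measured − predicted)/predicted; percentage
*difference* between two adjusted means is the absolute difference over
their arithmetic mean (symmetric, bounded in [0, 200)). Comparisons run a
Welch ANOVA over the measured group plus one predicted group per model at
the same masses, then Dunnett many-to-one contrasts with the measured group
as control. Juveniles are excluded by the caller: growth elevates metabolic
rate relative to any basal prediction.

## Statistical engine

Implemented directly on numpy/scipy (statsmodels and pingouin appear only as
oracles in the test suite).

**OLS/ANCOVA.** Minimal formula language (`y ~ a + b + a:b`), treatment
coding with documented reference levels (summer, before-anaesthesia, F,
adult; overridable). Exact least squares via `lstsq`; rank-deficient designs
raise an error naming the collinear columns (pivoted QR). The AIC includes
the full Gaussian constant and counts the variance parameter
(AIC = −2ℓ + 2(p + 1)); only differences matter for selection.

**Adjusted means.** Level means are fitted responses at a common covariate
value — numeric covariates at their grand means over the fitted data (an
explicit evaluation mass may be supplied), other factors averaged at their
observed level proportions (the "effects"-style convention; the evaluation
point is recorded in the output). SEs come from the coefficient covariance
of the corresponding linear combination. The n-weighted average of the
adjusted means equals the fitted grand mean for additive models.

**Contrast families.** Tukey (all pairs) and Dunnett (many-to-one) families
compute each contrast's t statistic on the residual df, then a family-wise
adjusted p from the Monte-Carlo distribution of the maximum absolute
component of a multivariate t with the contrasts' correlation matrix
(singular families handled via the eigendecomposition; a common chi-square
scale gives the t tails). Defaults: 10⁵ draws, seed 20150909 — adjusted
p-values are bit-reproducible given (seed, draws), with MC standard error
near 0.001. A single-contrast family needs no adjustment and returns the
unadjusted p; adjusted p is floored at the unadjusted p so MC noise can
never invert their order. Degenerate zero-spread groups return p = 1 (null
contrast) or 0 (non-null with zero SE) rather than NaN.

**Welch ANOVA.** Groups weighted by n/s²; Welch–Satterthwaite denominator
df. For two groups this equals the classical F exactly; for k ≥ 3 it
divides by the small-sample correction 1 + 2(k−2)/(k²−1)·λ, so it
deliberately does not coincide with the classical statistic even under
equal variances. Zero-variance groups are an error (weights undefined).

**Random intercept (REML).** y = Xβ + b_g + ε with b_g ~ N(0, σ_b²) per
animal. The restricted likelihood is profiled to one dimension in
λ = σ_b²/σ_e²: block structure makes V⁻¹ a per-group rank-one update, β(λ)
is GLS, σ̂_e² is closed-form, and λ is optimised on log scale
(bounded [e⁻¹², e¹²]) with an explicit λ = 0 boundary check, so the fit
collapses exactly to OLS when the boundary wins. Wald tests use a t
reference with n − p denominator df — mixed-model small-sample df are
convention-dependent and this conservative choice is stated in the summary
rather than guessed. BLUPs are λn_g r̄_g/(1 + λn_g).

**Stepwise AIC.** Bidirectional from the intercept (plus forced terms),
best single add/drop per step, marginality respected (interactions require
their main effects), alphabetical tie-break — fully deterministic given the
data; the visited path is returned. Note that AIC admits a pure-noise
term with probability P(χ²₁ > 2) ≈ 0.157, so intercept-only recovery under
a null is ≈ (1 − 0.157)^m for m candidates, not a near-certainty.

**Anaesthesia summary.** State means are fixed-effect predictions at the
grand-mean body mass; the awake reference pools the before and after means
weighted by their observation counts (with 6 before and 8 after this
n-weighting, not the unweighted mean, reproduces the published 25.5%
reduction), and the reduction is the during-anaesthesia shortfall as a
percentage of that pooled value.

## Simulators

**Chamber.** Well-mixed balance V·dC/dt = FR_in·C_in − FR_out·C ∓ exchange,
with FR_out = FR_in − V̇O2 + V̇CO2 — the volumetric bookkeeping whose steady
states satisfy the flow equations above. Integration is the exact
exponential update of the linear mixing dynamics on sub-steps of ≤ 0.25 min
(uptake evaluated at sub-step midpoints), so there is no solver tolerance.
A deliberately naive equal-flow variant (FR_out = FR_in) quantifies the bias
the dilution terms remove (> 0.1% at default settings). Defaults: 235 L
chamber, 46.12 L·min⁻¹ flow (time constant V/FR ≈ 5.1 min), reading noise
0.002 %O2 (1 SD), linear drift −0.02 %O2·h⁻¹, 2-min sampling, 100-min
sessions. The default metabolic profile is a resting V̇O2 of 110 ml·min⁻¹ —
chosen jointly with the default flow to put O2 depletion mid-band at
≈ 0.23 percentage points — plus an initial activity excess of 60 ml·min⁻¹
decaying with a 25-min time constant, which reproduces both the
dip-then-rise trace shape and stabilisation times inside the observed
86.9 ± 44.4 min band. Anaesthesia sessions run during (0–120 min) → waking
(120–245 min, square-wave movement bursts) → after (245–365 min), the
"after" onset 125 min past waking; the anaesthetised rate defaults to 0.745
of the recovered rate. Thermoregulatory feedback is not modelled — V̇O2 per
phase is specified, not derived from temperature.

**Cohort.** 37 animals in the study's season/age/sex composition (18
summer with one cub, 11 autumn with one cub, 8 winter adults), truncated-
normal masses per cell (e.g. summer adults 8.80 ± 2.15 kg, summer cubs
3.58 ± 0.38 kg), and RMR = 766 + 164.93·mass + season offset + N(0, σ) with
offsets (0, −237, −521) kJ·d⁻¹ for summer/autumn/winter, mirroring the
published adjusted-mean spacing. The residual σ = 230 kJ·d⁻¹ is calibrated
so the mass-only regression explains ≈ 46% of the variance on average at
n = 37; the replicate-to-replicate spread of R² at that n is wide
(roughly 0.2–0.67 central 95%), which is inherent to the sample size.
A companion generator produces the repeated-measures anaesthesia design
(8 adults, during/after for all, before for 6) with a per-animal random
intercept. All generators are bit-reproducible given their seed.

**What passing tests do and do not show.** The generators share the
package's own steady-state algebra and a Gaussian error model; real traces
have autocorrelated noise, imperfect mixing, and animals that move at
unscripted times, and real cohorts violate normality and homoscedasticity
in ways the diagnostics of a live analysis should check. Recovery and
calibration results here validate the arithmetic and the statistical
machinery under the stated error model, not field performance.

## Problem sizes and reproducibility

Simulation-based checks use 500 cohort replicates for adjusted-mean
coverage, 1000 replicates for Welch and Tukey type-I calibration (2×10⁴ MC
draws per Tukey family there; 10⁵ at the user-facing default), and single
fixed-seed sessions for pipeline recovery. Every random quantity flows from
an explicit `numpy.random.default_rng(seed)`; reports embed the seed,
package version and configuration hash, and identical inputs give
byte-identical outputs.

## Known limitations

- Per-animal results that depend on the original study's raw data (its
  regression coefficients, Table-wise error distributions and p-values)
  can only be reproduced qualitatively from synthetic cohorts unless the
  deposited dataset is placed under `data/`, where an optional integration
  test picks it up.
- The stable-segment rule trades a small early-window bias for robustness;
  see Trace processing.
- Mixed-model inference reports Wald t statistics with residual df, not
  Kenward–Roger/Satterthwaite adjustments.
- Multi-animal chambers, streaming acquisition, water-vapour corrections
  and phylogenetically informed allometry are out of scope.
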