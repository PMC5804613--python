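# Methods

## Problem and scope

`pkbias` evaluates how well an open-loop compartmental pharmacokinetic
simulation predicts measured plasma fentanyl during surgery. Given
per-patient dosing records and timed arterial samples, it (i) simulates
the predicted plasma concentration at every sampling time, (ii) applies
the clinical study's exclusion rules to form usable measured/predicted
pairs, and (iii) computes the predictive-accuracy statistics: fixed bias
(mean measured−predicted difference) with 95% CIs, performance error and
MDAPE, ±0.5 ng/mL exceedance counts, correlation and OLS regression,
stage-binned analysis, and the Fisher-z correlation power calculation.
The package does not estimate PK parameters from data, model effect-site
kinetics, or implement target-controlled infusion; it analyses the
accuracy of a fixed published model.

## Pharmacokinetic model

Disposition follows a linear mammillary three-compartment model with
central volume `V1` (L) and micro rate constants `k10, k12, k21, k13,
k31` (1/min). The unit-bolus plasma response is the tri-exponential

    c(t) = Σᵢ aᵢ exp(−λᵢ t),   Σᵢ aᵢ = 1/V1,

where the hybrid rates λ₁ ≥ λ₂ ≥ λ₃ > 0 are the negated eigenvalues of
the disposition matrix and the amplitudes follow from the
partial-fraction identities `aᵢ = (k21−λᵢ)(k31−λᵢ) / (V1 Πⱼ≠ᵢ(λⱼ−λᵢ))`.
Predictions superpose this impulse response over all dose events
(boluses as scaled impulses, zero-order infusions as its running
integral). Units are locked to µg, L, min and ng/mL; since µg/L ≡ ng/mL
no conversion factor appears anywhere.

Numerical choices:

- Eigenvalues come from `numpy.linalg.eigvals` on the (structurally
  reduced) disposition matrix; a peripheral compartment with zero inflow
  is dropped before decomposition, so one- and two-compartment limits
  are exact rather than numerically fragile.
- Near-repeated eigenvalues (relative gap < 1e−9) raise a degeneracy
  error and `predict_concentration` transparently falls back to the
  numerical ODE path. These inputs form a measure-zero set but the
  fallback keeps the engine total.
- A bolus at time *t* contributes from *t* onward, inclusive
  (right-continuous). This convention must be fixed for the 10-min
  post-bolus exclusion rule to have testable boundary behaviour.
- The independent check path, `ode_oracle`, integrates the amount-space
  ODEs with LSODA at rtol 1e−10 / atol 1e−13, injecting boluses as state
  jumps and infusions as piecewise-constant source terms. It exists for
  cross-validation (tests, the `--oracle` CLI flag) and as the
  degenerate-parameter fallback; the analytic path is the
  implementation. The two agree to better than 1e−6 relative tolerance
  on randomized three-compartment instances.

The packaged parameter file ships the adult fentanyl population set of
Shafer and colleagues (`shafer_fentanyl`: V1 = 6.09 L, k10 = 0.0827,
k12 = 0.471, k21 = 0.225, k13 = 0.161, k31 = 0.0077 min⁻¹), transcribed
from the published model as used by the STANPUMP/TivaTrainer simulators;
its central volume is fixed, not weight-scaled. The file format also
accepts `v1_per_kg`, multiplied by patient weight at load time (rate
constants are weight-invariant, the standard convention for this model
family). Self-contained generic parameter sets (`generic_3cpt`,
`generic_1cpt`) are included for tests and examples that must not depend
on any published model.

## Exclusion rules and pairing

Three exclusions are applied in a fixed order so every raw sample lands
in exactly one accounting category: (1) samples before the patient's
first fentanyl dose (pre-dose assay controls); (2) samples drawn within
10 min after a bolus — read as *strictly* less than 10 min, so a sample
at exactly 10.0 min is retained (the boundary is not specified
clinically; a fixed, testable convention was chosen); (3) samples below
the LLOQ of 0.05 ng/mL, which are excluded rather than imputed (the
simplest defensible default; the study design makes such samples rare,
and the path is config-gated). The report reconciles exactly:
`usable = raw − pre-dose − post-bolus − below-LLOQ`.

Elapsed time is measured from the first fentanyl dose, while dosing
records are anchored at anesthesia induction; the join computes the
per-patient offset because the two clocks genuinely differ. Stages are
half-open 90-min bins of elapsed time: [0, 90) → 1, [90, 180) → 2,
[180, 270) → 3, [270, ∞) → 4.

## Statistics

- **Fixed bias**: mean difference with the two-sided Student-t interval
  `mean ± t₁₋α/2,n−1 · sd/√n`. A normal-quantile variant is available;
  t was chosen as the stricter default and at the study's cell sizes
  (n ≥ 19) the two differ by < 0.01 ng/mL after rounding.
- **Performance error**: (measured − predicted)/predicted × 100%;
  MDAPE is the median absolute PE per cell. A non-positive prediction at
  a usable sample time is an error, never a silent NaN.
- **Exceedance**: counts of differences strictly beyond ±0.5 ng/mL and
  their pooled fraction.
- **Regression**: Pearson r and OLS via `scipy.stats.linregress`;
  constant predictors raise. The difference-vs-time regression accepts a
  `time_unit` divisor for the abscissa (published slopes of this kind
  are sometimes quoted per 10 min; the default is per minute).
  Constant differences return the degenerate flat line (slope 0, r 0)
  rather than NaN. p-values are computed via the t-transform and
  reported only.
- **Power**: minimum n to detect a correlation,
  `n = ⌈((z₁₋α/2 + z_power)/atanh(r))² + 3⌉`; for r > 0.5, power 0.90,
  α 0.05 this gives n = 38, and a vectorised bivariate-normal
  Monte-Carlo check at that n reproduces 0.90 ± 0.02 empirical power.
- **Stage table**: one row per non-empty (procedure, stage) cell; empty
  cells are omitted (a short procedure simply has no stage-4 samples).
  Report rounding: 2 decimals on the ng/mL scale, whole percent for
  MDAPE.
- **Characteristics table**: per arm and variable, a Shapiro–Wilk test
  at α = 0.05 selects `mean ± SD` (plausibly normal) or
  `median (q1, q3) [min, max]` formatting; constant variables summarise
  with SD 0 rather than crashing.

## Synthetic cohort generator

No patient-level data are distributable, so a generator emulates the
study's structure: 30 mastectomy patients (weight 52.9 ± 7.7 kg,
anesthesia 160.8 ± 39.5 min, normal durations) and 20 laparoscopic
prostatectomy patients (64.1 ± 9.3 kg, right-skewed durations with
median 251.5 min, modelled log-normally since that arm is summarised by
medians), weights truncated at the 80-kg eligibility cap. Each patient
receives an induction bolus of 1–3 µg/kg a few minutes after induction,
then maintenance boluses drawn from {25, 50, 100} µg. Arterial samples
run every 30 min from the first dose until 30 min past anesthesia end;
two pre-dose control samples per patient exercise the exclusion
accounting end to end.

Maintenance boluses are placed 1–8 min *after* a blood draw — the
clinical pattern (dose after sampling) that keeps almost all samples
clear of the 10-min exclusion window; a small per-interval probability
(0.03) of an unscheduled mid-interval bolus produces the handful of
excluded samples a real dataset shows. Purely random bolus timing would
exclude roughly a third of all samples, which no observed cohort of this
design does, so alignment to draws is a structural feature of the
generator, not a tuning knob.

Measured values are generated as

    measured = (predicted(t) + b₀ + b₁·elapsed + ε) · (1 + cv·η),

with ε ~ N(0, 0.45 ng/mL), assay CV 4%, censoring below 0.05 ng/mL.
The bias is injected additively on the concentration scale — the scale
of the difference-based analysis — so the PE statistics *emerge* rather
than being injected. Defaults: mastectomy b₀ = 0.32 ng/mL, b₁ = 0 (flat
positive bias); prostatectomy b₀ = 0.43 ng/mL, b₁ = −0.0023 ng/mL/min,
the line through per-stage mean differences of roughly +0.3, +0.2, −0.15,
−0.34 ng/mL at the stage midpoints, emulating the dilution-like drift of
the long procedure. The generator does not model fluid dilution
mechanistically (that mechanism is hypothesised, not established); the
additive drift stands in for it. Residuals are independent across
samples by default; a patient-level random-intercept hook
(`patient_intercept_sd`) exists because real repeated measures are
correlated within patient, but no value for that correlation is
available to default to.

What passing tests show — and do not show. With a fixed seed the
generator is byte-deterministic, produces per-arm usable counts in the
observed range (~150–210), and the full pipeline recovers the injected
(b₀, b₁) per arm: across 20 seeds the mean recovered slope is within
±0.0008 ng/mL/min of truth and the qualitative pattern (flat positive
vs sign-reversing bias) is reproduced in ≥ 90% of seeds. This validates
the *pipeline arithmetic*, not the biology: real data add
within-patient correlation, model misspecification beyond an additive
linear drift, venous/arterial site differences and assay artefacts that
the generator deliberately omits.

## Problem sizes

Defaults were chosen at the study's own scale, where everything is
cheap: one cohort is 50 patients / ~430 samples (milliseconds to
generate and analyse), the recovery study uses 20 seeded cohorts, the
engine cross-validation 50 randomized instances, the power check 5000
Monte-Carlo replicates and the CI coverage check 2000 resamples of
n = 25 cells. The acceptance script runs the whole set in a few seconds.

## Known limitations

- The injected bias is linear in time; the real stage profile need not
  be, and the generator cannot distinguish dilution from clearance
  drift.
- Below-LLOQ handling is exclusion only; no substitution or censored
  likelihood.
- The mastectomy arm occasionally produces a small stage-4 cell at
  extreme duration draws, whereas a short procedure may show none at
  all; the stage table simply reports the cells that exist.
- The Shafer fentanyl parameters are transcribed constants; no
  uncertainty in the population model is propagated.
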