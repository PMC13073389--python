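# Methods

## Model structure

`ckdrisk` models kidney-function decline as a discrete-time stochastic
process on annual eGFR measurements. An individual's state is the pair
(age *a* in integer years, eGFR *g* in mL/min/1.73 m²). Each year the
state advances by

    g  <-  max(0, g + μ(a, g) + z · σ(a, g))

where μ and σ are the mean and SD of the annual eGFR *change* (signed;
negative means decline) in the individual's current sex/age-band/eGFR-band
stratum, after multiplicative covariate factors, and z is a standard
normal individual random effect. Key structural assumptions:

- **One z per individual, fixed for life.** Heterogeneity is entirely
  between-person: a person one SD below the mean decline this year is one
  SD below it every year. This makes the threshold-crossing event
  monotone in z (see below) and is what allows an exact probability via
  bisection rather than path-level Monte Carlo. Annual re-drawing of z
  (within-person variability) is deliberately not implemented; it would
  change the probabilities and remove the bisection structure.
- **Annual time step, no sub-annual interpolation.** The stratum
  parameters are annual slopes; fractional starting ages are truncated to
  whole years.
- **eGFR floor at 0; no competing mortality.** The model projects kidney
  function only. Probabilities at high target ages are therefore risks
  *conditional on survival*, which overstates absolute lifetime risk in
  elderly patients.
- **Strata below eGFR 30 reuse the 30–39 band** (implemented as a lookup
  at max(g, 30)), because decline statistics below 30 are typically not
  separately estimable from checkup data. Ages outside the tabulated
  range, and eGFR above the top band, are clamped to the nearest band —
  projections routinely run past the table's last age band, and erroring
  there would make 40-year horizons impossible.
- **Bands are half-open [lo, hi)**, for both axes, everywhere: a value on
  a boundary belongs to the band whose lower edge it equals.

## Covariate effects

Effects enter as constant multiplicative factors on the stratum mean
(α) and SD (β), applied only when the corresponding covariate is present:

| factor | default | applies when | units |
|---|---|---|---|
| α_ARB (RASi) | 0.7 | on RASi | dimensionless |
| α_SGLT2 | 0.5 | on SGLT2i | dimensionless |
| α_smoke | 1.2 | current smoker | dimensionless |
| α_smoke_ceased | 1.0 | ceased smoker | dimensionless |
| α_prot / β_prot | 2.0 / 1.3 | proteinuria | dimensionless |
| α_BP / β_BP | 1.0 / 1.0 | high BP category | dimensionless |

The RASi (−30%), SGLT2i (−50%) and current-smoking (+20%) factors are
literature-anchored trial/meta-analysis effect sizes. The ceased-smoker
default of 1.0 assumes full attenuation of the smoking excess; the
sensitivity sweep scales it as α_smoke·(1−r) for cessation effect r. The
proteinuria factors are **synthetic defaults** — the stratified source
estimates behind them are unpublished — and the blood-pressure factors
default to 1.0 (no effect), matching the absence of a detectable BP
gradient in the source strata. All factors are configurable per run.
Because all factors are constant and mutually independent multipliers,
treatment scenarios compose by simple products (RASi+SGLT2i = 0.35) and
implicitly assume immediate, sustained, interaction-free effects — no
biphasic "initial dip" dynamics.

## Crossing probability by bisection

The event is first passage: eGFR strictly below the threshold (default
30) at any annual evaluation up to and including the target age (default
80), the starting point included. With a shared z and σ ≥ 0, the yearly
update is non-decreasing in z, so the event indicator is a step function
of z: it holds for all z below a critical z\* and fails above. The
probability is then Φ(z\*). The engine brackets z in [−8, 8] — Φ(±8)
differs from 0/1 by ~10⁻¹⁵ — and bisects to a z-tolerance of 10⁻⁶
(probability error < 4·10⁻⁷); events present at z = +8 or absent at
z = −8 report probability exactly 1 or 0.

Monotonicity in z is a theorem only for tables where the per-year map
g ↦ g + μ(g) + zσ(g) is monotone; a pathological table with large
between-band jumps could break it. In strict mode (the default for
scalar calls) each call checks the indicator on a 33-point z grid and
falls back to a seeded Monte Carlo estimate with a logged warning on
violation; the batch path used for cohorts and heatmaps skips the check
for speed (every synthetic table used in the tests is verified monotone
by the scalar path and by the trajectory-level property test).

`mc_probability` is the independent cross-check: n draws of z, each
projected through the same engine, event fraction reported. On a flat-μ,
constant-σ table the path is linear in the year count, giving the closed
form z\* = ((threshold − g₀)/years − μ)/σ used as an analytic oracle.

Derived outputs:

- **50% boundaries** (`boundary_egfr`): the probability is non-increasing
  in baseline eGFR, so an outer bisection over eGFR (default range
  [5, 120], eGFR tolerance 0.05, probability tolerance 10⁻³) finds the
  iso-probability baseline; `None` is returned when the whole range sits
  above or below the target probability, and for zero-SD tables (a 0/1
  probability step) the flip point is returned.
- **Heatmaps** (`risk_heatmap`): the batch engine evaluates the full
  age × eGFR product in one vectorised bisection; rows are eGFR values,
  columns ages.
- **Scenarios and sweeps**: probability per profile × scenario with
  differences and percent reductions versus the first (reference)
  scenario; one-way effect-size sweeps hold all other factors at their
  defaults.

## Decision analytics

- **age+eGFR heuristic**: the plain sum, *decreasing* in risk. When fed
  to ROC routines it must be negated so that higher = riskier; the
  package does this internally wherever it computes discrimination for
  the heuristic. Categories: ≥115 low, [100, 115) moderate, <100 high.
  Conventional comparator on eGFR alone: ≥60 low, [45, 60) moderate,
  <45 high. Boundary values belong to the lower-risk side in both
  schemes.
- **Decision curves**: rules here are fixed binary thresholds, not risk
  probabilities, so TP and FP are constant across p_t and only the
  false-positive penalty p_t/(1−p_t) varies; treat-all and treat-none
  references are always included, over p_t = 0.05–0.60 by default.
- **Reclassification/NRI**: 3×3 conventional-by-new count matrices split
  by event status; upward moves are correct for events, downward for
  non-events; additive NRI sums the event and non-event net proportions,
  absolute NRI pools all individuals. The packaged reference counts
  (`data/reclassification_counts.json`) reproduce, by exact integer
  arithmetic, correct/incorrect/net of 6388/2643/3745 (events) and
  9362/11251/−1889 (non-events), additive NRI 14.82% and absolute NRI
  1.53% (percentages rounded half-up to two decimals).
- **Calibration**: equal-frequency prediction strata (quantiles with
  duplicate edges collapsed) with mean predicted vs observed rate.
- **Discrimination**: ROC/AUC via scikit-learn; `c_statistic` is an
  independent rank-based (Mann–Whitney) implementation, ties counted ½,
  kept separate so the AUC ≡ c-statistic identity remains a genuine
  dual-route check.

## Synthetic data generator

The source stratum table (sex × 10-year age bands 40–80 × 10-unit eGFR
bands, estimated from paired checkup creatinine measurements ten years
apart in a pre-RASi/SGLT2i-era cohort of ~120 000 adults) is not
deposited. `TableSpec` therefore generates a stand-in with the same
shape: decline magnitude = base + age_gradient·(decades over 40) +
egfr_gradient·(bands below the top) + male excess (+ optional seeded
jitter), negated into μ_base; SDs follow the same band structure.
Defaults — base 0.5, age gradient 0.10/decade, eGFR gradient 0.08/band,
male excess 0.05, SD 1.0 + 0.03/band — give ≈ −1.0 mL/min/1.73 m²/yr in
the 50–60 eGFR stratum of a young male, consistent with published
general-population slopes (≈ −0.8 to −1.4), and keep all magnitudes in a
0.3–2.5 envelope. `proteinuria_stratum=True` emits the
proteinuria-stratified variant (slopes ×2.0, SDs ×1.3). `CohortSpec`
defaults emulate a checkup population: 2:1 female:male, ages uniform on
[40, 80), eGFR truncated-normal (75 ± 15 on [15, 120]), 5% proteinuria,
25% current smokers, no renoprotective treatment.

What passing tests on these synthetics do and do not show: they validate
the *machinery* — probability calculus, monotonicity and dominance
structure, estimator correctness, parameter recovery — under the model's
own assumptions. They cannot validate the clinical numbers (e.g. the
headline 50%-boundary eGFR values or intervention risk reductions), which
depend on the unpublished stratum estimates; on the synthetic defaults
the 40-year-old male 50% boundary lands near eGFR 77 rather than the
high-50s obtained from the historical data. Real eGFR decline also shows
within-person variability, non-normal (skewed, AKI-driven) shocks and
informative dropout, none of which the single-z normal model represents.

Two cohort variants are used in the stochastic checks: the default
population above, and a "mid-risk analysis cohort" (eGFR 60 ± 12
truncated to [40, 85], ages 40–65) restricted to the screening-relevant
CKD G2–G3a region where crossing probabilities are away from the 0/1
tails and binomial-SE comparisons are well-behaved.

## Numerical and testing choices

- Bisection tolerances: 10⁻⁶ in z (inner), 0.05 eGFR / 10⁻³ probability
  (outer boundary search); ~24 vectorised engine passes per batch call.
- Parameter-recovery testing uses a flat (gradient-free) table so the
  recovered stratum means have no band-switching attenuation and the
  3-SE criterion is exact; the gradient-table variant is tested
  separately with a doubled (6-SE) allowance, since a 10-year decline of
  ~10–15 units crosses one to two 10-unit bands and biases the recovered
  mean toward neighbouring strata.
- Simulation sizes (20-profile × 10⁵-draw Monte Carlo panel, 10⁴-person
  cohorts for calibration/recovery) were chosen as the smallest sizes at
  which the 3-SE comparisons are informative.
- CSV round-trips use pandas' `float_precision="round_trip"` parser so a
  written table reads back bit-identically.
- Degenerate inputs: zero-SD tables give exact 0/1 probabilities and a
  step-function boundary (flip point returned); constant predictions
  collapse calibration to a single stratum; empty recovery strata are
  reported with n = 0 and NaN statistics rather than raised.

## Known limitations

No competing mortality; constant, interaction-free treatment effects; no
biphasic treatment dynamics; normal random effect (under-represents
extreme decliners); cross-sectional stratum parameterisation rather than
longitudinal individual-level fitting; synthetic default parameters are
placeholders for the unpublished source strata, so absolute risk numbers
from the default tables are illustrative, not clinical estimates.
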