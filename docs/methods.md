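# Methods

## Scope and model

`fraxforge` synthesises a country-specific FRAX-style fracture-probability
model from (emulated) registry inputs and compares two such models on
exhaustive clinical scenario grids. The statistical core is:

- a proportional-hazards individual risk model
  `h(a | x, T) = h0(a) · exp(Σ_c β_c x_c) · g^(−T)`
  for each of three outcomes (hip fracture, combined non-hip MOF,
  death), where `x` is the vector of six dichotomous clinical risk
  factors, `T` the femoral-neck T-score and `g` the gradient of risk
  (relative risk per SD decrease in BMD);
- population calibration: for each sex and integer age, the baseline is
  `h0(a) = observed hazard(a) / E[exp(βᵀx) · g^(−T)]`, where the
  expectation runs over independent Bernoulli CRFs (so it factorises into
  `Π_c (1 − p_c + p_c e^{β_c})`) and a normal age-conditional T-score
  distribution (lognormal moment `exp(−βμ(a) + β²σ²/2)`, `β = log g`).
  The population-mean individual hazard then reproduces the observed
  incidence and mortality identically at every age — calibration rescales
  absolute risk without touching the relative importance of the
  coefficients;
- a discrete competing-risk integration of the 10-year first-fracture
  probability with hazards held constant within each step:
  `P = Σ_t S(t)·h_f/(h_f+h_d)·(1 − e^{−(h_f+h_d)Δt})`,
  `S(t+1) = S(t)·e^{−(h_f+h_d)Δt}`. Fracture is absorbing (no refracture
  within the horizon); death any time before fracture precludes it.

MOF is treated as a first-event composite: its hazard is the sum of the
hip hazard and a separately calibrated combined non-hip hazard (clinical
spine + forearm + humerus). This "sum of site hazards" construction makes
`P(hip) ≤ P(MOF)` hold for every profile by construction, even though the
hip gradient of risk is steeper than the non-hip one.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| age bands | [50,55) … [85,90), 90+ | years | 5-year registry reporting; 90+ midpoint fixed at 92.5 to avoid unbounded extrapolation |
| breakpoints | men {62, 87}, women {62, 82} | years of age | segmented log-incidence regression knots |
| region weights | Southeast 0.42, Northeast 0.28, South 0.14 | population share | renormalised over the covered regions before combining |
| engine time step | 1 year (monthly optional) | — | matches hazard-table granularity; the micro-simulation test bounds the discretisation error |
| comparison knot | 30 | percentage points | fixed knot of the updated-vs-original segmented regression |
| T-score distribution | mean −0.02·(age−50), SD 1 | SD units | mild average bone loss with age; used only to integrate the BMD term |
| BMI effect | log-RR 0.03 per kg/m² below 25 | — | applied only to profiles without BMD, as in FRAX's with/without-BMD duality |
| updated-model scale | 0.55 | — | the reference run's downward incidence revision |

## The synthetic-data generator

The generator emulates a three-city retrospective hip-fracture registry:
counts per city/sex/band are Poisson with mean
`scale · λ(band midpoint, sex) · person-years / 100,000`, where the true
surface λ is continuous piecewise log-linear in age. Defaults are chosen
to be realistic for a middle-income country with registry-level (updated)
incidence: rates around 25/100,000 (men) and 22/100,000 (women) at
age 50–54 rising exponentially to roughly 900–1,300/100,000 at 90+, with
women overtaking men from about age 70 (average excess ≈1.5 above 70,
near-parity below). City scales 0.6/1.0/1.4 reproduce the
lowest/intermediate/highest regional ordering. Per-band person-years
default to 250,000 per city — registry denominators are not published, so
this is an explicit, arbitrary choice. Mortality is Gompertz
(`0.004·e^{0.085(age−50)}`, male excess e^{0.45}); non-hip:hip site ratios
decline exponentially with age (forearm dominance in the 50s, hip
dominance in the 80s, total MOF:hip strictly decreasing); CRF
coefficients are drawn once per seed from documented ranges (fracture RR
1.2–2.5, death RR 1.0–1.8, prevalence 0.02–0.35, hip gradient 1.4–2.6).

What the generator does **not** emulate: hospital non-admission and
conservative-management bias, refracture bookkeeping, CRF correlation
structure, ethnicity or regional mortality differences, secular trends.
Passing tests therefore demonstrate the correctness of the synthesis and
comparison machinery under idealised registry sampling, not the fidelity
of any particular country's epidemiology.

## Numerical choices

- Segmented fits use the truncated power basis
  `[1, a, (a−k₁)₊, (a−k₂)₊]`, which enforces continuity at the knots by
  construction; coefficients come from `numpy.linalg.lstsq`. Unweighted
  least squares on log rates is the default; an inverse-variance
  (count-weighted) mode is available.
- Zero-count bands are excluded from the log-rate regression by default
  (`zero_policy="exclude"`); `"add-half"` substitutes half the smallest
  positive rate instead. No silent pseudo-counts.
- Band-level rates are carried to integer engine ages (50–110) by
  log-linear interpolation between band midpoints, extrapolating the
  terminal segment slopes beyond 52.5/92.5. Fractional attained ages in
  the monthly engine interpolate the same way.
- Calibration divides observed hazards elementwise by the population-mean
  relative risk; a zero observed rate yields a zero baseline with a
  warning rather than an error.
- Tolerance intervals: the 95% TI around the updated probability at the
  original median adds the empirical 2.5th/97.5th percentiles of the
  comparison-regression residuals to the regression prediction
  (nonparametric, reproduces asymmetric intervals); a normal-theory
  alternative (Howe's tolerance factor × residual SD) sits behind
  `ti_method="normal"`. The point estimate can also be read from the
  paired scenario nearest the median (`method="nearest"`).
- If every scenario falls on one side of the 30% knot, the comparison
  regression falls back to a single straight line and flags it.
- Correlations are computed on untransformed probabilities.

## Design decisions that were genuinely open

- **Rank preservation under incidence rescaling.** When two models differ
  only by a fracture-incidence scale factor, Spearman correlation is
  exactly 1 *provided all profiles share the same death relative risk*
  (the probability is then monotone in the fracture relative risk alone).
  With death-affecting CRFs, near-tied scenarios can cross ranks — a
  correct property of competing-risk probabilities, observed here at
  ρ ≈ 0.9999. The exact property is asserted for fracture-only
  coefficient sets; the full model is asserted at the reported level
  (ρ > 0.99).
- **Calibration is profile-independent**: the BMD term is always
  integrated over the age-conditional T-score distribution when computing
  the population-mean relative risk, whether or not an individual profile
  supplies a T-score. Profiles without BMD receive the population-average
  BMD factor plus the BMI term.
- **Death coefficients are age-constant**, applied identically at every
  age.

## Known limitations

- The first regression segment (ages 50–62) contains only two age bands.
  At realistic early-50s incidence (tens per 100,000), segment-1 slope
  estimates carry ~4–7% relative error at 10⁶ person-years per band even
  pooling three cities; reliable (<10% in ≥95% of replicates) recovery of
  all slopes needs several-fold more exposure (achieved at 8×10⁶
  person-years per band in the consistency test).
- Authentic FRAX coefficients are proprietary/unpublished; all coefficient
  sets here are generated stand-ins, so absolute probabilities are not
  comparable to published FRAX outputs — only the synthesis and
  comparison machinery is.
- "Secondary osteoporosis" is not modelled as BMD-interacting; the six
  CRFs are plain dichotomous inputs.
- No secular projection of incidence or mortality over the 10-year
  horizon; no age-standardisation of city rates.

## Problem sizes

The default reference run uses three cities × two sexes × nine bands at
250,000 person-years per band, 512-scenario grids at ages 50/60/70/80 for
both sexes and outcomes (16,384 scenario evaluations per model), and a
61-age calibration grid per sex. The micro-simulation oracle in the test
suite uses 200,000 simulants with monthly steps for 20 profiles; slope
recovery uses 100 Poisson replicates.
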