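# Methods

## Standardized monthly incidence

Cases are tallied by calendar month of diagnosis. Because months differ
in length, each raw count is divided by the month's length in days and
multiplied by the average month length (30.4375 = 365.25/12); February
is counted as 28.25 days, averaging over the leap cycle regardless of
the actual mix of leap years in the data window. Adjusted counts are
then divided by their mean so the average month has incidence 1 — this
makes amplitudes comparable across strata of very different size.
Adjusted counts are carried at full precision; rounding to whole counts
happens only in display.

Two invariances are maintained and tested: normalization is scale
invariant (multiplying all raw counts by a constant changes nothing
downstream), and the adjustment is the identity when all month lengths
equal the target length.

## Cosinor model

The single-component cosinor with known period P = 12 months is

    y_t = M + A cos(θ_t − φ) + e_t,   θ_t = 2π(t − 1)/12,

linearized as `y = M + β_c cos θ + β_s sin θ` and fitted by ordinary
least squares. Derived quantities:

* amplitude `A = √(β_c² + β_s²)` — half the fitted peak-to-trough
  difference (so the "peak is X% above the trough" figure is
  `100·2A/M`);
* acrophase `φ = atan2(β_s, β_c)` in [0, 2π) — the angular timing of
  the fitted maximum, mapped to the **peak month** as the calendar month
  whose angle is circularly closest to φ (an exact halfway tie goes to
  the earlier month); the trough month is the peak plus six, mod 12;
* seasonality test — the joint 2-degree-of-freedom F-test of
  `β_c = β_s = 0` against the mesor-only model, the standard
  zero-amplitude test for a single-component cosinor;
* amplitude standard error and 95% CI by the delta method on
  `(β_c, β_s)` with the OLS covariance, the lower bound truncated at 0.
  For the complete one-per-month design the regressors are orthogonal,
  so the fit equals the closed-form projection
  `β_c = (1/6) Σ y_t cos θ_t`, `β_s = (1/6) Σ y_t sin θ_t` — kept as an
  oracle equivalence test at 1e-10.

The month-angle convention `θ_t = 2π(t−1)/12` (January at angle 0) is
arbitrary; the amplitude is invariant to it and the peak month is
convention-independent by construction (tested by refitting under a
cyclically shifted convention). With only 12 aggregated observations the
delta-method CI has 9 residual degrees of freedom and should be read as
approximate; a bootstrap over cases would be the heavier alternative.

Group amplitudes (e.g. north vs south of the median-county latitude)
are compared in one stacked regression with a group main effect and
group × cos, group × sin interactions, giving each group its own trig
coefficients; the difference of the two implied amplitudes gets a
delta-method SE from the joint covariance and a two-sided Wald test.
Both constant series together are rejected as degenerate (the amplitude
difference is undefined at A = 0, where the delta method breaks down).

Subgroup analyses fit the cosinor to each stratum's own standardized
series (strata are not modelled jointly), and the resulting p-values are
adjusted by the Bonferroni–Holm step-down method with monotonicity
enforcement and capping at 1.

## Registry conventions

* Latitude quartiles are computed over **distinct counties**, not cases;
  cutpoints are the latitudes of the first county of quartiles 2–4 after
  sorting, with half-open lower-inclusive intervals. The north/south
  split reuses the middle cutpoint (38.05 °N in the reference cohort),
  "north" being lower-inclusive. Where the cutpoint should sit between
  adjacent counties is not determinable from published values alone; the
  chosen convention (cutpoint at a county's latitude) is fixed and
  documented, and the reference cutpoints 34.19/38.05/41.68 °N are
  treated as constants, not a recomputation target.
* Winter = September–February, summer = March–August (meteorological
  autumn+winter vs spring+summer).
* Exclusion rules run sequentially, each recording (rule, removed,
  remaining); the two small-registry removals are one parameterized rule
  since both registries are dropped for the same reason. Missing month,
  age or stage are legal states of a loaded record, removed by the
  cascade rather than rejected at parse time; missing values in CSVs are
  "" or "NA".

## Cox proportional-hazards core

The partial likelihood is maximized directly. Ties are handled by the
Efron correction by default — follow-up is recorded in whole months, so
ties are heavy — with Breslow available as a cross-check (the two
coincide exactly when no ties exist, which is tested). Covariates:
age at diagnosis and year of diagnosis continuous; sex, histology and
Ann-Arbor stage treatment-coded with references female,
nodular-sclerosis (the modal subtype) and stage I. Reference levels and
functional forms are this package's choices, swappable via
`encode_covariates`.

Newton–Raphson starts at β = 0 with step-halving on any likelihood
decrease and at most 50 iterations. Convergence requires the gradient
max-norm below `tol × max(1, |ℓ(0)|)` with `tol = 1e-9`: the scaling is
necessary because for cohorts of tens of thousands of cases the
log-likelihood is of order 10⁴ and an absolute gradient cutoff of 1e-9
sits below what double precision can attain. Standard errors are from
the inverse observed information; CIs are two-sided Wald at 95%
throughout. Columns are centered internally (coefficients and their
covariance are invariant to this in a Cox model). Constant or collinear
columns and designs without events are rejected up front;
non-convergence raises rather than returning silently.

Follow-up is administratively censored at a horizon of 36 months (60 as
a robustness check): `time = min(survival, horizon)`, an event only if
death occurred at or before the horizon.

## Seasonal-risk formulations

1. **Dichotomous**: a winter-diagnosis indicator added to the covariate
   set; its hazard ratio compares mortality after winter vs summer
   diagnosis.
2. **Latitude interaction**: season term, latitude/10 main effect and
   their product. The latitude main effect is retained by default
   (hierarchical principle; droppable by flag) — whether the original
   analyses retained it is not documentable, and the interaction
   coefficient is invariant to shifting all latitudes by a constant
   (tested), so the choice affects only the season main effect.
3. **Sinusoid scan**: `x₁ = cos(2π(M − M_max)/12)` replaces the
   dichotomy, one fit per integer `M_max` in 1..12, the best peak month
   maximizing β₁. Since `x₁(M, m+6) = −x₁(M, m)`, β₁(m+6) = −β₁(m)
   exactly, HRs six months apart multiply to 1 and share p-values; this
   structure is asserted to 1e-10 on arbitrary data. The scan is
   month-resolved because diagnosis timing only exists at month
   resolution; finer grids would interpolate spuriously.

## Synthetic registry generator

`SimConfig` defines the ground truth; `simulate_registry` draws from it
reproducibly via one `numpy.random.default_rng(seed)`:

* **Diagnosis month**: `p_m ∝ (1 + a_eff·cos(2π(m − m₀)/12))·(days_m /
  30.4375)` with `a_eff = a + slope·(lat − 38.05)/10`. Defaults
  `a = 0.077`, `m₀ = 3`, `slope = 0.06` per 10° — the seasonal
  structure a US-wide HL registry exhibits.
* **Covariates**: drawn from marginals typical of population-based HL
  (male 54.8%, nodular sclerosis 59.5%, stage II 39.4%, the young-adult
  age peak); age and year uniform within their drawn bins.
* **Counties**: a fictional 40-county table, 10 per quartile band over
  30–48 °N, whose distinct-county cutpoints are exactly
  34.19/38.05/41.68 °N — quartile and north/south logic is exercised
  without real geography.
* **Survival**: exponential with rate `λ·exp(lp)`; `lp` holds log-linear
  covariate effects (age +0.04/year above 40, male +0.20, stage II/III/IV
  +0.2/0.6/1.0, subtype offsets, year −0.02/year after 2000 — realistic
  prognostic gradients for HL) plus the seasonal term
  `γ·x₁(M, m_mort)` and interaction `δ·x₁·(lat − 38.05)/10`. Defaults
  `λ = 0.002`/month (≈15% three-year mortality at average covariates),
  `γ = ln 1.06`, `m_mort = 11`, `δ = ln 1.10`. A dichotomous-injection
  mode (`seasonal_form="winter"`) substitutes the winter indicator for
  `x₁`, for validating the winter/summer models under their own
  generating form. The interaction is centered at the reference latitude
  so γ keeps its meaning at mid-latitude; the analysis-side interaction
  coefficient is shift-invariant, so this choice does not bias recovery.
* **Censoring**: random exponential loss to follow-up (0.002/month)
  competing with a 120-month administrative horizon. Death times are
  floored to whole months by default, deliberately inducing the tie
  structure of real data (disable `floor_months` for no-ties oracle
  tests).

The generator injects seasonality through the same functional forms the
analyzers fit, which makes parameter recovery a well-posed check of the
estimators — it is **not** a misspecification study, and passing
recovery tests says nothing about robustness to non-sinusoidal
seasonality, non-proportional hazards, informative censoring or
geographic confounding in real registries.

## Problem sizes in the test suite

Parameter-recovery checks use 40,000–50,000 simulated cases, matching
the scale at which the corresponding registry analyses operate;
distributional checks use 50,000–200,000; structural and oracle checks
use toy data (8–4,000 cases). The scan test asserts recovery of the
injected peak month and CI coverage of the injected hazard ratios,
within Monte-Carlo error at those sizes.

## Known limitations

* Single-component cosinor only; no harmonics, no continuous-time event
  model (diagnosis timing exists only at month resolution).
* The cosinor amplitude CI is asymptotic (delta method on 12 points).
* The Cox layer has no time-varying covariates, stratified baselines,
  frailties or formal proportionality diagnostics.
* The generator does not model EBV status, bulky disease, prognostic
  scores, treatment-era structure or real county geography.
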