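# Methods

This note documents the models implemented in `drscreen`, the
assumptions behind them, the synthetic data the test-suite runs on, and
the design decisions taken where the problem was genuinely open.

## Progression model

Time to referable diabetic retinopathy (RDR) is modelled from screening
records in which the event time is never observed exactly: disease is
found at a screen, so the onset lies between the last negative and the
first positive screen (interval censoring), or after the last screen
attended (right censoring). Because partial likelihood is unavailable
under interval censoring, a Cox model cannot be used; the model is a
fully parametric Weibull proportional-hazards regression

    S(t | x) = exp(−λₓ tᵖ),   λₓ = exp(β₀ + x'β),   h(t | x) = p λₓ t^{p−1},

with time in years from the first (disease-free) screen. The
log-likelihood sums `log[S(left|x) − S(right|x)]` over interval-censored
records and `log S(left|x)` over right-censored ones, computed in log
space throughout (`log S` and `log1p`/`expm1` identities) so survival
underflow at long horizons degrades to a diagnosable `−inf` rather than
a NaN.

*Estimation.* The likelihood is maximised by L-BFGS over
`(log p, β₀, β)` — the log-parameterisation keeps `p > 0`
unconstrained — with continuous covariates standardised internally and
coefficients reported on the original scale. Five restarts from
dispersed starting points guard against local optima (the first start
uses a crude events-per-exposure rate). The covariance is the inverse
observed information of the original-scale likelihood at the optimum; a
non-positive-definite information matrix is reported, not hidden.

*Family comparison.* Gompertz (`h = a·e^{bt}`, PH multiplier; the
`b → 0` limit handled by series expansion) and lognormal (AFT on log
time, location `μ − x'β`, scale `σ`) alternatives are fitted to the same
records and compared by AIC = 2k − 2ℓ. Ties break toward fewer
parameters, then toward Weibull; non-converged candidates are excluded
with a warning and never chosen silently.

*Covariate selection.* Forward addition of the most significant
candidate (largest Wald |z| among those with p < α, default α = 0.05),
followed by backward removal of any coefficient with Wald p ≥ α. A
covariate removed twice is barred from re-entry; this hysteresis rule
guarantees termination, and the full add/remove trace is attached to
the returned fit. Candidates nearly collinear (|r| > 0.999) with an
included covariate are rejected with a message.

*Derived quantities.* Median time `(ln 2/λₓ)^{1/p}`; per-cycle
transition probability `1 − S(t+Δ|x)/S(t|x)` (constant in `t` when
`p = 1`, strictly increasing when `p > 1`), which telescopes exactly to
the cumulative risk over consecutive cycles.

## Longitudinal covariate prediction

GP measurements are taken at appointments, not screens. Each analyte is
modelled independently as a quadratic function of time with
subject-level random coefficients,

    y_ij = (β + b_i)'(1, t_ij, t_ij²) + ε_ij,  b_i ~ N(0, Σ),  ε ~ N(0, σ²),

fitted by marginal maximum likelihood (statsmodels `MixedLM`). Times
are centred at the grand mean before fitting to reduce collinearity of
the polynomial basis; per-subject centring was rejected because it
changes the meaning of the fixed effects (there would no longer be a
single population curve). Predictions at screening dates are
`(β + b̂_i)'(1, t, t²)` with `b̂_i` the posterior-mean (shrunken)
coefficients; subjects absent from the estimation sample get the same
shrinkage through the closed form `b̂ = ΣZ'V⁻¹(y − Zβ)`,
`V = ZΣZ' + σ²I`. Degenerate designs (constant response, or fewer than
three distinct observation times) return an explicit degenerate or
intercept-only fit with a warning rather than a rank-deficient answer.
Predictions outside a subject's observed time range are flagged as
extrapolations. In the pipeline, the HbA1c value entering each hazard
row is the prediction at the *left* endpoint of the censoring interval
(the last event-free screen) — a choice the source analyses leave open.

## Markov cost-utility model

A cohort enters disease-free at the first screen and is propagated in
6-month cycles over a lifetime horizon (age 100 or cohort extinction)
through 29 states:

* `NoDR → MinBDR → ModBDR` (pre-referable grades; all three feed the
  RDR onset hazard from the survival model),
* ten RDR severity states — `PreProlif, Mac, PreProlif+Mac, ETP,
  ETP+Mac, HRP, HRP+Mac(VI), SevereProlif, SevereProlif+Mac(VL),
  SevereLossOfVision` in a strict total order — duplicated into an
  *undetected* zone and a *hospital eye service* (HES) zone,
* three absorbing treated states, two severe-vision-loss residence
  states (home / care home), and death.

Per-cycle matrices compose four mechanisms as independent competing
risks (death first; survivors follow disease dynamics); every row sums
to one within 1e−10 and any negative composed entry is a hard error
naming the offending cells.

*Detection and knockback.* Undetected RDR progresses untreated through
the same severity transition matrix used in HES ("unidentified
progression"). Detection is only possible at cycle boundaries where the
strategy screens — every 2nd cycle under annual recall, every 4th under
biennial — so disease arising early in a biennial interval progresses
for up to two years before referral. At HES entry 50% of the mass of
every non-minimal severity state moves one step down the order
(`knockback`), modelling false-positive referrals discharged after the
first HES appointment; the operator conserves mass exactly and
stochastically dominates toward lower severity. Detection transfers
mass to HES within the same cycle; treatment assignment begins the
following cycle (the first HES appointment is assessment). The
alternative — transfer at the next cycle — is a one-line change and was
not taken because referral on a positive screen is immediate in
practice.

*Treatment.* Each HES severity carries a per-cycle treatment
probability and an expected procedure bundle (OCT, laser, anti-VEGF,
vitrectomy) charged once at treatment. Treated people are stationary
thereafter apart from mortality. Treatment is deliberately
*utility-neutral*: pre-proliferative disease is monitored (treatment
probability zero), `PreProlif+Mac` routes to the maculopathy treated
state, and each treated state's utility equals the utility of every
severity that routes into it. This makes detection weakly beneficial —
the health value of screening comes from knockback and from halting
progression, never from a bookkeeping jump in utility — and is what
makes "annual never yields fewer QALYs than biennial" a structural
property rather than a numerical accident.

*Mortality.* Annual life-table probabilities are multiplied by a
diabetes-type factor (capped at 1) and converted to per-cycle
probabilities by `q = 1 − (1 − qx·m)^{0.5}`, which compounds back to
the adjusted annual figure exactly.

## Economics

Unit costs (2018 GBP, NHS + personal-social-services perspective):
screening visit £33, HES visit £106, OCT £117, laser £131, anti-VEGF
£822, vitrectomy £989, sight loss £1,483/year at home and £6,972/year
in care (pro-rated per cycle). Screening-visit costs are charged to
community states at screening cycles; an HES visit per cycle while
untreated in HES plus one at referral; treatment bundles once at
treatment entry. EQ-5D weights for the RDR states run from 0.7915
(pre-proliferative) to 0.6218 (severe loss of vision); the
pre-referable weight (healthy with diabetes) is a configurable 0.80 —
a non-study default, as is everything listed under *Synthetic fixtures*
below. QALYs accrue as start-of-cycle occupancy × weight × 0.5 years.

Discounting is discrete at 3.5%/year (1.5% in sensitivity analysis),
applied at cycle midpoints by default; no half-cycle correction is
applied (a flag switches discounting to cycle starts). Incremental
results are biennial minus annual. When biennial saves money and loses
QALYs the ratio is a DCER (GBP saved per QALY forgone) and the decision
rule is reversed: cost-effective iff DCER ≥ £20,000/QALY, boundary
inclusive (the boundary case never arises in practice; inclusivity is a
recorded convention). The remaining quadrants are classified dominant /
dominated / ICER in the usual way.

## Sensitivity analysis

Deterministic grids fix the HbA1c (accepted in % or mmol/mol, converted
by the IFCC↔NGSP relation) or diabetes-duration value entering the
hazard for the whole horizon — scenarios are "at" a level, with no
drift — and re-run the full comparison per cell; a monotonicity report
(DCER non-increasing in HbA1c and duration) accompanies the grid.

The PSA follows standard health-economics convention, since no
distributional choices are published: Gamma costs (SD 20% of the mean),
moment-matched Beta utilities (SD capped at the feasible bound), a
multivariate-normal draw of `(log p, β₀, β)` using the delta-transformed
fit covariance (sampling on `log p` keeps the shape positive), and
Dirichlet rows (concentration 200) for the HES severity matrix with
structural zeros preserved. Draw `i` uses an independent generator
seeded by `(seed, i)`, so draws are order-independent and extending a
run preserves its prefix; degenerate specifications (all CVs zero,
sampling off) reproduce the deterministic base case bit-for-bit.

## Synthetic data and fixtures

The cohort generator reproduces the demographic structure of the Welsh
screening population analysed for progression (1,232 Type 1 / 26,812
Type 2 by default): covariate means and SDs, treatment-flag and smoking
proportions, entry ages 22.7/62.3 years, durations 7.8/4.2 years.
Covariates are independent truncated normals (±4 SD plus physiological
floors); only the published margins are available, so no correlation
structure is imposed (configurable). The generating Weibull laws
(T1DM: p = 1.4, β_HbA1c = 0.50, β_dur = 0.10; T2DM: p = 1.3,
β_HbA1c = 0.45, β_dur = 0.075) were calibrated once to the published
median-time-to-RDR gradients — about 20/13/8 years at HbA1c
6.5/8.0/9.0% for Type 1, slower for Type 2 — and are not adjusted
thereafter. Screening recall is annual with uniform ±0.15-year jitter
(observed recall drifts past 12 months; the exact interval distribution
is unpublished, so this is a modelling choice); GP visits occur every
~0.6 years with HbA1c drifting along a small per-subject quadratic.

What the generator does **not** emulate: covariate correlations,
measurement-process informativeness (visits are independent of disease
state), non-attendance, grading error beyond the knockback construct,
and secular drift in care. Passing tests therefore demonstrate the
*correctness of the machinery* (likelihoods, estimators, matrix
composition, accounting) under the stated laws — not the fidelity of
any particular published estimate to real data.

Several inputs of the original analyses live in supplementary tables
that are not reproduced in the main text: the HES severity transition
matrix, treatment probabilities and procedure bundles, the RDR entry
mix, the sight-loss home/care split (0.9/0.1 here), the pre-referable
utility (0.80) and the mortality multipliers (3.0 Type 1, 1.5 Type 2).
These ship as clearly-labelled synthetic fixtures in the documented
file schemas; a user holding the published tables can transcribe them
into `transitions.yaml`/`utilities.yaml` and rerun. With the fixtures,
headline results agree with published analyses in *structure and
direction* — biennial screening produces a DCER near the threshold for
Type 1 diabetes that falls below it at 1.5% discounting or at high
HbA1c/long duration, remains clearly cost-effective for Type 2
throughout, and shows far greater PSA certainty for Type 2 — and that
is all the fixtures are claimed to support.

## Numerical and scale choices

* Occupancy is tracked in double precision with conservation enforced
  to 1e−10 per cycle; no rounding until reporting.
* The life table shipped for fixture runs is a Gompertz–Makeham
  national-style table (`qx = 2·10⁻⁴ + 3.5·10⁻⁵·e^{0.09·age}`, ages
  12–100), a synthetic stand-in in the same single-year-age layout as
  the national tables.
* The microsimulation used to validate the cohort trace lives in the
  test suite only. Its acceptance band is 3 binomial standard errors
  per state per 10th cycle plus a three-simulant floor, because the
  normal approximation is meaningless for states whose expected count
  falls below about one.
* `scripts/acceptance.py` runs the Type 1 cohort at its full analysis
  size (1,232) and down-samples the Type 2 cohort to 6,000 of 26,812;
  the estimators are unbiased at either size, only standard errors
  differ. PSA uses 300 draws there (1,000 is the library default).
* Strategy schedules: screens at every cycle boundary divisible by the
  recall interval; the "two prior negative screens" gate is available
  as a flag that adds a year-one screen under biennial recall, and is
  off in the base comparison.

## Known limitations

* One-eye, cohort-level model: no individual heterogeneity within a
  stratum beyond the covariates entering the hazard, no visual-acuity
  continuum.
* The three treated states compress ten severities; treatment
  effectiveness is stationarity, not regression of disease.
* Pre-referable grade dynamics are cosmetic (the utility weight is
  shared), serving only to keep the screening pathway's state structure.
* Costs are a fixed 2018 price year; no inflation or currency
  conversion, no societal perspective.
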