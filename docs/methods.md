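# Methods

## The disposition model

`uadyn` implements a semi-mechanistic, whole-body turnover model of uric
acid. A single well-mixed serum compartment holds the amount S_UA (mg);
uric acid enters at a production rate k_P (mg/h) and leaves by two
parallel first-order routes:

* **intestinal secretion**, proportional to an intestinal clearance
  CL_I (L/h) and the serum concentration [S]_UA = S_UA / V_UA (mg/L),
  with V_UA (L) the volume of distribution;
* **renal excretion**: serum is filtered at the glomerular filtration
  rate GFR (L/h internally; mL/min at clinical boundaries, × 0.06), the
  proximal tubule reabsorbs most of the filtered urate, and the fraction
  escaping reabsorption — the fractional excretion coefficient F_E — is
  what appears in urine:

```
dS_UA/dt = k_P − CL_I·[S]_UA − GFR·F_E·[S]_UA
dU_UA/dt = GFR·F_E·[S]_UA
```

Urine appearance is equated with proximal-tubule escape (all known human
urate transporters are proximal), so there is no downstream delay term.
The model is deliberately coarse: it aggregates all tubular transport
into the single coefficient F_E and makes no attempt at intra-renal
spatial resolution.

Setting dS_UA/dt = 0 gives the steady state and its inverse relations,
used everywhere for baseline back-calculation:

```
[S]_UA = k_P / (CL_I + GFR·F_E)         X_UA = k_P·GFR·F_E / (CL_I + GFR·F_E)
k_P,0  = [S]_UA·CL_I + X_UA             F_E,0 = X_UA / ([S]_UA·GFR)
```

Two consequences drive the treatment-planning results. First, the steady
state is linear in k_P, so the *percent* serum reduction achieved by a
production inhibitor (xanthine oxidase inhibitor) is the same for every
(GFR, F_E, k_P) combination. Second, the renal and intestinal routes
compete, so the benefit of raising F_E (a uricosuric) grows with GFR and
shrinks as baseline F_E rises — the synergy quantified by the nomograms.

## Drug effects

Both effects are saturable (Emax) functions of plasma drug concentration:

* production inhibitors multiply the production rate:
  `k_P = k_P,0·(1 − R_max·C/(C + P50))`;
* reabsorption inhibitors add to the excretion coefficient:
  `F_E = F_E,0 + F_max·C/(C + P50)`.

Shipped parameter defaults (the published estimates): CL_I 0.27 L/h,
V_UA 19 L; oxypurinol R_max 0.84, P50 14,000 ng/mL; febuxostat R_max 1,
P50 87 (120 for hyperuricemic gout subjects) ng/mL; lesinurad F_max 0.56,
P50 11,000 (23,000 hyperuricemic) ng/mL; residual SDs 0.45 mg/dL + 15%
for serum, 50 mg + 29% for urine. Half-maximal concentrations differ for
hyperuricemic subjects, selected by a group-level flag.

Exposure enters through `ConcentrationProfile` objects. Two providers are
built in: a one-compartment, first-order-absorption PK model with dose
superposition, and a natural cubic spline through observed concentrations
(clipped at zero). The PK model is a stand-in authored for this package —
its parameters per drug were chosen once to reproduce clinically reported
exposure scales (daily-average oxypurinol ≈ 10,000 ng/mL on 300 mg
allopurinol, with the allopurinol→oxypurinol conversion absorbed into the
apparent volume and clearance; lesinurad 200 mg Cmax ≈ 9,000 ng/mL with a
3–4 h half-life; febuxostat 80 mg comfortably saturating its P50). Every
consumer accepts any profile object, so a mechanistic PK model can be
dropped in without touching the rest of the package.

The oxypurinol interaction correction: co-administered lesinurad lowers
daily-average oxypurinol exposure by 32%, weakening production inhibition.
The correction factor is the ratio of the Emax terms at 0.68·C versus C
(≈ 1.116 at C = 10,000 ng/mL), applied multiplicatively to the predicted
on-treatment serum level.

## Simulation

`run_simulation` integrates the two-state system with LSODA
(rtol 1e-8, atol 1e-10); the system is linear and mild, so a stiff/
non-stiff switching solver is more than sufficient. Initial conditions
are always the drug-free analytic steady state (predose profiles are
flat). Grid points are forced at dose times, urine-interval bounds and
observation times. Urine is tracked as a continuous cumulative amount;
per-interval amounts are differences at the interval bounds, equivalent
to resetting the collection at each interval start. 24-h summaries use
trapezoidal integration of the dense solution, and the on-treatment
fractional excretion is recovered from the 24-h mean concentration and
total urine amount through the steady-state back-calculation — the same
computation applied to measured data.

## Estimation

Fitting targets multi-group trial data with a combined
additive + proportional Gaussian residual model,
`y = f + sqrt(a² + (b·f)²)·ε`, with separate (a, b) for the serum and
urine streams and `f` the model prediction (not the observation). All
observations are weighted equally across groups, and the serum/urine
error parameters are shared across groups (one set each). Group
covariates (GFR, baseline F_E,0, baseline serum concentration) are
treated as known; the group production rate k_P,0 is recalculated from
the baseline concentration and the *current* CL_I at every objective
evaluation, so baseline mass balance holds exactly throughout the search.

Numerics: parameters are estimated on the log scale (positivity by
construction; SEs mapped back by the delta method). The default search
runs five starts — the stated initial values plus log-uniform
perturbations within a factor of three — each a capped Nelder-Mead
exploration followed by an L-BFGS-B polish. Standard errors come from the
inverse observed information (finite-difference Hessian on the log
scale); relative SE = 100·SE/estimate. Non-finite predictions yield a
large penalized objective with a warning rather than an exception.
Effective F_E values are clamped at 1 during fitting (a proposal can
push past it; the clamp keeps the trajectory physical).

Inside the likelihood the serum equation is solved on a fine fixed grid
(default spacing 0.05 h) by an exponential integrator: per step the
coefficients are frozen at midpoint values and propagated with the exact
constant-coefficient solution. This preserves true steady states to
machine precision, carries second-order error for time-varying exposure
(≈1e-4 relative against the adaptive reference, far below residual
noise), and makes one likelihood evaluation a handful of vectorized
array operations (~1 ms for a twelve-group design). The test suite
cross-checks this fast path against the LSODA reference.

Adequacy diagnostics follow the usual pharmacometric conventions:
parameters with relative SE ≥ 30% are flagged, and weighted residuals are
binned against time and against the prediction; a bin mean exceeding
three standard errors flags a systematic trend (the smoothed-mean
excursion a reviewer would see in a residual plot).

## Synthetic data

The generator is the package's stand-in for the proprietary clinical
datasets and defines the study conditions of every simulation experiment.

**Populations.** GFR uniform over a stated range (healthy volunteers
80–120 mL/min; renal-impairment style cohorts 22–164; hyperuricemic
cohorts 30–120); baseline F_E,0 log-normal, median 0.07 / geometric SD
1.4 for normals (the 7–12% healthy range) and median 0.04 for
hyperuricemic underexcreters; baseline serum urate normal (5.5 ± 0.8
mg/dL healthy; 9.0 ± 1.5 truncated above the 6.8 mg/dL solubility limit
for gout cohorts). Each subject's k_P,0 is back-calculated from their
baseline concentration, so every subject starts exactly at steady state.
Violating draws are resampled. These distributions are package defaults,
not calibrated to the unpublished trial covariates.

**Phase-I-style trials.** Groups are defined by regimens (drug, dose,
dose times), a serum sampling schedule and 6-h urine collection
intervals. One population subject provides the group-typical physiology;
each of the group's virtual subjects (default 15 per group, emulating
~278 subjects over 18 groups) contributes an independently noisy copy of
the schedule, with combined-error noise applied per observation and
negative values truncated at zero. Separate seeded generator streams are
used for population draws, serum noise and urine noise, so extending one
part of a design leaves the others' draws unchanged.

**Phase-III-style cohorts.** Hyperuricemic subjects receive a steady
daily-average uricosuric concentration (log-normal, median 8,000 ng/mL,
geometric SD 1.6); the on-treatment F_E follows the Emax model, the
observed on-treatment serum value is the mean of six noisy monthly
steady-state observations, and the measured on-treatment F_E carries
additive noise (SD 0.01). A configurable fraction carries background
allopurinol, with the oxypurinol-interaction inflation built into their
generated serum levels — the same physiology the predictor corrects for,
so noise-free cohorts fall exactly on the identity line.

What the generator does *not* emulate: between-subject parameter
variability within a group (group arms are mean-typical by construction),
dropout, adherence, dose titration, circadian production, diet, and
PK interactions beyond the fixed 32% oxypurinol-exposure reduction.
Passing recovery tests therefore demonstrate internal consistency of the
estimator under the stated noise model at realistic trial sizes — not
robustness to the full heterogeneity of real trial data.

## Qualification procedures

**Renal impairment.** Baseline F_E,0 and k_P,0 are interpolated against
GFR with nonlinear least squares on `α + β·exp(γ·GFR)`; when the
exponential fails to improve the residual sum of squares by more than 1%
over a constant (beyond a numerical floor), the constant is selected
automatically — the per-study choice is thereby made by criterion rather
than inspection. Fitted interpolations evaluate only inside the fitted
GFR range (an exponential extrapolated outside the data is meaningless,
and one published form grows unboundedly with GFR). The interpolated
baselines plus a spline through each subject's observed drug
concentrations drive a 24-h simulation from which relative serum/urine
changes are computed.

**Hyperuricemic patients.** Subjects are retained only if serum urate
decreased from baseline (compliance proxy) and measured F_E increased
(measurement-error proxy); exclusion counts are reported by reason. For
each retained subject the predicted relative change reduces to
`(CL_I + GFR·F_E,0)/(CL_I + GFR·F_E,on) − 1` — the baseline concentration
cancels — with the oxypurinol correction applied for subjects on
background allopurinol (exposure fixed at 10,000 ng/mL for all corrected
subjects; per-subject oxypurinol PK is not attempted).

## Nomograms

Grids are evaluated on the steady-state closed forms over
(production-inhibition × excretion-increment), default 101 × 101 over
[0, 0.9] × [0, 0.15], anchored at the patient's stated baseline serum
concentration (k_P is re-derived from it, per CL_I value). The required
inhibition for a target reduction has the closed form
`1 − (1 − target)·(CL_I + GFR·(F_E,0+ΔF_E))/(CL_I + GFR·F_E,0)`, floored
at zero. Along a fixed-target contour the daily urine amount reduces to
`[S]_base·(1 − target)·GFR·(F_E,0+ΔF_E)·24`, independent of CL_I — which
is why the urinary side of the CL_I sensitivity band (default 0.19–0.36
L/h, ±30% of the estimate) collapses to zero width wherever the required
inhibition is interior, while the required-inhibition band is widest at
low baseline F_E where the intestinal route dominates elimination.
Percent values in emitted tables are rounded to integers; full precision
is kept internally.

## The recovery experiment

`uadyn.experiments.recovery_experiment` is the package's reference
simulation study, sized to run on one CPU in minutes. Twelve groups:
single-dose lesinurad 50/100/200/400/600/1600 mg (11 serum samples over
24 h, four 6-h urine intervals each), and once-daily 7-day arms of
lesinurad 400, allopurinol 300, lesinurad 200/400 + allopurinol 300,
febuxostat 80, and lesinurad 400 + febuxostat 80 (day-1 and day-7
sampling). The main fit frees CL_I, V_UA, the oxypurinol, lesinurad and
febuxostat half-maximal concentrations and the four residual SDs, with
the effect maxima fixed at their published values; a second fit on the
lesinurad-monotherapy subset re-estimates F_max jointly with P50,
mirroring how that maximum was originally anchored on a wide monotherapy
dose range. The multiple-dose uricosuric arms are what identifies CL_I:
at the on-drug quasi-steady state the serum level depends on the ratio of
baseline to on-drug total clearance, in which the intestinal route
competes directly with the enhanced renal route. Twenty replicates
(population, noise and optimizer seeds all derived from one seed) give
mean estimates within a few percent of truth and 2-SE coverage of 90% or
better per parameter.

## Known limitations

* The PK stand-in is structural plumbing, not an estimated model; drug
  exposure scales are plausible rather than fitted.
* Group arms are mean-typical: no inter-individual random effects, so
  the estimator is a group-mean ML fit, not a mixed-effects analysis.
* The exponential GFR interpolations are descriptive regressions valid
  only on the fitted range.
* Effect clamping (F_E ≤ 1) makes the likelihood non-smooth in the far
  tail of parameter space; in practice optimizers never end there.
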