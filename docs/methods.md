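# Methods

## The diffusion-limited growth law

The package models a subcutaneous xenograft tumor as a sphere of volume
`V` (cm³) whose proliferative status is set by nutrient diffusion.
Nutrient enters from the surface; below the critical radius `R_c` the
whole tumor is nourished and grows exponentially at the net rate
`lambda_net` (day⁻¹). Above it, a necrotic core of radius `R_n` forms,
and the steady-state spherical diffusion balance — uniform consumption in
the live shell, no flux into the core — fixes `R_n` through

    R² − 3·R_n² + 2·R_n³/R = R_c².

The growth fraction is the live-shell volume fraction
`G = 1 − (R_n/R)³`, and the volume obeys

    dV/dt = lambda_net·G·V − lambda_nec·(1−G)·V − k_drug·c(t)·G·V,

with `lambda_nec` (day⁻¹) the breakdown/removal rate of necrotic
material and `k_drug` (kg·mg⁻¹·day⁻¹) the potency of a drug at plasma
concentration `c(t)` (mg/kg) that kills only living (proliferating)
cells.  Dividing the constraint by `R²` shows `u = R_n/R` solves
`(1−u)²(1+2u) = (R_c/R)²`, so `G` is a function of `V/V_c` alone, with
`V_c = (4π/3)R_c³`.  `G` is continuous and continuously differentiable
through the onset `V = V_c` (near onset `1−G ∼ (1−V_c/V)^{3/2}`), which
the integrators exploit.

Two consequences give the model its empirical content: a tumor shrinking
under treatment re-oxygenates, so `G` rebounds during response; and `G`
links to endpoint histology through the necrotic area fraction of a
central cross-section, `(1−G)^{2/3}`.

### Integration

`simulate_dl` offers two routes that are cross-checked against each
other in the test suite:

* `method="ode"` — differentiate the constraint once and integrate
  `(V, R_n)` jointly (LSODA), with terminal events at crossings of
  `V = V_c` in both directions and restarts at dose times.  The
  constraint Jacobian in `R_n` vanishes at `R_n = 0`, so the
  differentiated system is only engaged once `V > V_c(1 + 10⁻⁹)`.
* `method="dae"` — integrate `V` alone and re-solve the constraint
  algebraically at every right-hand-side call (bracketed Brent, absolute
  tolerance 10⁻¹⁰ cm).

Population fitting, cohort synthesis and VPC simulation use a third,
vectorized route: classical RK4 with a fixed step (default 0.05 days;
0.1 days inside SAEM) advancing all subjects simultaneously, with `G`
recovered per step from the closed-form trigonometric root of the
constraint cubic (`w = 2u−1` turns it into `w³ − 3w + (2−4s) = 0`),
which matches the bracketed scalar solver to ~10⁻¹¹.  Step grids are
aligned to dose times so the concentration
discontinuities fall on step boundaries; stage concentrations use the
exact exponential superposition, right-continuous at a step start and
left-continuous at a step end.  The three routes agree to ~10⁻⁷
relative on the study designs.

## Pharmacokinetics

CPT-11 (Irinotecan) plasma kinetics are a single exponential: each bolus
dose (mg/kg) adds its amount to the concentration instantly, which then
decays at `k_elim = ln 2 / t_half` with `t_half = 12 h`, i.e.
`k_elim ≈ 1.386 day⁻¹`.  Doses superpose linearly.  The dose amount is
used directly as the initial concentration (no volume-of-distribution
scaling); a different convention only rescales `k_drug`.

## Spatial drug penetration

For poorly penetrating agents the shell concentration solves the
quasi-steady reaction–diffusion balance `D∇²c = k_d·c` on
`R_n ≤ r ≤ R` with `c(R) = c_b(t)` and zero flux at `R_n`, giving

    c(r) = c_b · (R/r) · [sinh(q(r−R_n)) + qR_n·cosh(q(r−R_n))]
                      / [sinh(qL) + qR_n·cosh(qL)],

with `q = rho/R`, `L = R − R_n`, and `rho = R·sqrt(k_d·u/D)` the
dimensionless penetration parameter.  `rho = 0` recovers a uniform
profile; large `rho` confines the drug to the surface.  All
hyperbolic-function ratios are evaluated in shifted-exponential form
(every exponent ≤ 0) so the expressions remain finite for arbitrarily
large `rho`.  The kill term becomes the shell integral
`k_drug·(3/R³)·∫ c(r)·r² dr`, evaluated in closed form from the
antiderivative and verified against adaptive quadrature; with a uniform
concentration it reduces exactly to `k_drug·c_b·G`.

The quasi-steady assumption treats drug diffusion as fast relative to
tumor growth, so the profile tracks the instantaneous `c_b(t)` and
geometry.  By default `rho` is held fixed over a simulation (how
penetration sweeps are usually presented); a "physical" mode rescales it
in proportion to the current radius, since `rho ∝ R` by definition.

## Comparator growth laws

The standard empirical laws (linear, exponential, logistic, Gompertz,
exponential-linear, surface growth, proliferative rim) share the dosing
interface with the kill acting on total volume, `dV/dt = g(V) − k·c·V`,
since they carry no growth-fraction concept.  The exponential-linear
law uses the smooth-minimum form
`g = λ₀V/[1+(λ₀V/λ₁)^ψ]^{1/ψ}` with `ψ = 20` held fixed, evaluated in
log space to avoid overflow of the 20th power.  The surface-growth law
is `a·V^{2/3}`; the proliferative-rim law confines growth to a rim of
fixed thickness `d`: `a·(V − (4π/3)·max(R−d, 0)³)`.

## Population model and SAEM

Subject `i` carries `θ_i = θ·exp(η_i)`, `η_i ~ N(0, Ω)` diagonal —
log-normal random effects keep all parameters positive.  Residual error
is proportional by default (`y = f·(1+σε)`); additive and additive-on-log
variants are available.  Inter-individual variability (iiv) is reported
as the natural-scale SD of each parameter; the exact log-normal
conversion `sd = θ·e^{ω²/2}·sqrt(e^{ω²}−1)` is used in both directions,
with the published value treated as the median (typical value).

Estimation is stochastic approximation EM:

* **MCMC kernel.**  Per subject and chain, one independence proposal
  from the current population distribution (burn-in only) plus
  random-walk Metropolis steps whose proposal covariance is the ensemble
  covariance of the individual log-parameters (adaptive Metropolis),
  keeping moves aligned with likelihood ridges.  The global step scale
  adapts toward 35% acceptance during burn-in and is frozen afterwards.
* **Stochastic approximation.**  Step size 1 during burn-in (default
  150 iterations), `1/k` during smoothing (default 100); sufficient
  statistics are per-subject first and second moments of `φ_i = log θ_i`
  and the residual sum of squares on the error-model scale.
* **M-step.**  Exact: `μ` is the mean of the smoothed `φ_i`, `ω²` their
  variance, `σ²` the smoothed mean squared residual.  During burn-in the
  variances may not shrink faster than 5% per iteration and `ω²` is
  capped at 2.0 (random effects must not absorb fixed-effect misfit
  while the means are still moving).

**Initialization** matters more than any other control: the population
likelihood has long flat ridges (net growth vs necrotic loss vs potency)
and per-subject estimates of weakly identified parameters are
boundary-skewed noise whose mean would drag the start far down a ridge.
The default scheme therefore alternates, twice: (a) per-subject least
squares of only the well-identified parameters (growth rate and initial
volume), and (b) one pooled least squares over all subjects jointly for
the population-level parameters (drug potency and structural parameters
such as the critical radius and necrotic loss rate).  `fit_individual`
(full per-subject least squares on log-parameters with log-scale
residuals) remains available for seeding and diagnostics.

The marginal log-likelihood for AIC is estimated by importance sampling
(default 200 draws/subject) with per-subject Gaussian proposals built
from the conditional moments accumulated during smoothing (variance
inflated 1.5×); AIC counts fixed effects + iiv variances + the residual
variance.  RMSE is the root mean square residual on the error-model
scale at the conditional-mean individual parameters.  Runs are
bit-reproducible given the seed; `fit_population_runs` repeats the fit
from jittered starts and keeps the best likelihood, mirroring the
multi-run practice of production NLME analyses.

### Known estimation limits

On cohorts of ≤95 treated subjects measured every 2–3 days with 10%
noise, the necrotic loss rate `lambda_nec` has a nearly flat likelihood
profile: fits initialized at the generating values and fits initialized
agnostically can differ by 2 log-likelihood units or less while placing
`lambda_nec` anywhere within roughly ±50% of the truth, and its iiv is
systematically underestimated.  The other four parameters recover to
within ~10% under the same conditions.  This is an information limit of
the design (the necrotic compartment is never observed directly), not an
optimizer artifact, and the same flatness is why AIC differences between
the mechanistic and exponential-linear fits are small on data of this
shape.

## Synthetic cohorts

The `az_cdx` design emulates a 95-mouse CDX trial: weekly 50 mg/kg
CPT-11 under three protocols — days 1/8/15 (68 mice), 1/8/15/22
(18 mice), 4/11/18/25 (9 mice) — with measurements on days
{0, 2, 5, 7, 9, 12, 14, 16, 19, 21, 23, 26, 28, 30} (every 2–3 days to
day 30; the exact days are this package's choice since only the cadence
is documented).  Measurement noise is proportional with CV 10% by
default, applied to volume; an optional caliper layer perturbs emulated
length/width readings and recomputes `V = (π/6)·L·W²` (noise SD ≈ √5·CV
on volume).  Per-subject random streams derive from (master seed, arm
index, subject index), so resizing one arm never changes another arm's
subjects.  Generated cohorts reproduce the generating iiv SDs to <5% at
10⁴ draws and the residual CV to <2%.

What the generator does **not** emulate: dropout and humane-endpoint
censoring, measurement-day jitter, caliper digitization, tumor-type
mixtures, or model misspecification (data are generated by the same laws
that are fitted).  Passing recovery tests therefore demonstrates
estimator correctness under the stated design, not robustness to real
laboratory data.

## Visual predictive checks

`simulate_replicates` draws full replicate cohorts (fresh random effects
and noise) under the trial design; `vpc_bands` computes, per nominal
measurement day, each requested percentile (5/50/95) within each
replicate and takes the 95% interval of that statistic across
replicates.  Observed percentiles are computed per day-bin; observations
are assigned to the nearest bin and empty bins are filled by
interpolation.  An optional centered rolling mean across bins is
available for jittered observation times but is off by default — when
the growth curve is steep, averaging adjacent bins biases the percentile
level.  Self-coverage of the bands is assessed as an exit *rate*
averaged over many observed cohorts: within one cohort the subjects'
shared random effects make bin exits almost perfectly correlated, so
single-cohort bin counts are heavily overdispersed even when the
marginal coverage is exactly nominal.

## Numerical choices

* Constraint root solve: Brent on `[0, R)`, absolute tolerance 10⁻¹⁰ cm;
  the constraint is strictly monotone on the physical branch.
* Onset singularity: the differentiated-constraint ODE starts only above
  `V_c(1+10⁻⁹)`; below, the `G = 1` branch runs.
* Reference integrations: LSODA, rtol 10⁻⁸, atol 10⁻¹⁰, segmented at
  dose times; the segment end is always evaluated so restarts never use
  a stale state.
* Quadrature checks: adaptive (`scipy.integrate.quad`), relative
  tolerance 10⁻¹²  in tests; the production kill integral is closed-form.
* SAEM floors: `ω² ≥ 10⁻¹⁰`, `σ² ≥ 10⁻¹⁰`, predictions floored at
  10⁻¹⁰ cm³; proposal scales floored at `ω² = 10⁻⁴` so chains keep
  moving when iiv collapses.
* Problem sizes for the shipped experiments: parameter recovery uses the
  full 95-subject design for the diffusion-limited model and a
  40-subject protocol-1 design for the exponential-linear comparator,
  150 burn-in + 100 smoothing iterations, 2 chains; these are the
  package defaults and complete in a few minutes on one core.
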