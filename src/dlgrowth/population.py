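"""Nonlinear mixed-effects estimation by stochastic approximation EM (SAEM).

The population model is standard pharmacometrics: subject i's parameter
vector is theta_i = theta * exp(eta_i) with eta_i ~ N(0, Omega) diagonal
(log-normal random effects keep every parameter positive), and the
observed volumes carry a residual error — proportional by default,
y = f*(1 + sigma*eps), with additive and log-additive alternatives.

SAEM alternates (i) an MCMC kernel refreshing the individual log-parameters
phi_i = log theta_i from their conditional distribution given the data,
(ii) a stochastic-approximation update of the sufficient statistics of the
complete-data model (which is exponential-family in phi), and (iii) an
exact M-step for the fixed effects, the inter-individual variances and the
residual variance.  During the burn-in phase the step size is 1 and the
variances are prevented from collapsing faster than 5% per iteration
(simulated-annealing style); during the smoothing phase the step size
decays as 1/k so the estimates average out the Monte-Carlo noise.  Runs
are bit-reproducible given the seed.

The marginal log-likelihood for AIC is approximated by importance
sampling, with a Gaussian proposal per subject built from the conditional
moments accumulated during smoothing.

Inter-individual variability (iiv) is reported as the SD of each parameter
on its natural scale; the exact log-normal conversion is used both when
building a generating model from published tables and when reporting fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .dataset import CohortDataset, Subject
from .fastsim import MODEL_REGISTRY, simulate_many

__all__ = [
    "ResidualError",
    "PopulationModel",
    "SAEMConfig",
    "FitResult",
    "natural_sd_to_omega",
    "omega_to_natural_sd",
    "fit_individual",
    "fit_population",
    "fit_population_runs",
    "information_criteria",
]

_OMEGA2_FLOOR = 1e-10
_SIGMA2_FLOOR = 1e-10
_F_FLOOR = 1e-10

#: parameters estimated per subject during initialization; the rest are
#: population-level and estimated by a pooled fit over the whole cohort
#: (weakly identified per subject, their individual estimates would be
#: boundary-skewed noise)
INIT_SUBJECT = {
    "dl": ("lambda_net", "V0"),
    "exponential_linear": ("lambda0", "V0"),
    "linear": ("a", "V0"),
    "exponential": ("a", "V0"),
    "logistic": ("a", "V0"),
    "gompertz": ("a", "V0"),
    "surface": ("a", "V0"),
    "proliferative_rim": ("a", "V0"),
}

#: starting points for pooled/individual least-squares fits, per model
DEFAULT_INIT = {
    "dl": {"lambda_net": 0.1, "lambda_nec": 0.05, "k_drug": 5e-3, "R_c": 0.4, "V0": 0.3},
    "exponential_linear": {"lambda0": 0.1, "lambda1": 0.3, "k_drug": 2e-3, "V0": 0.3},
    "linear": {"a": 0.1, "k_drug": 2e-3, "V0": 0.3},
    "exponential": {"a": 0.1, "k_drug": 2e-3, "V0": 0.3},
    "logistic": {"a": 0.2, "K": 5.0, "k_drug": 2e-3, "V0": 0.3},
    "gompertz": {"a": 0.1, "K": 5.0, "k_drug": 2e-3, "V0": 0.3},
    "surface": {"a": 0.1, "k_drug": 2e-3, "V0": 0.3},
    "proliferative_rim": {"a": 0.2, "d": 0.2, "k_drug": 2e-3, "V0": 0.3},
}


def natural_sd_to_omega(theta: float, sd: float) -> float:
    """Log-scale SD omega of a log-normal with median ``theta`` and natural-scale SD ``sd``."""
    if theta <= 0.0:
        raise ValueError("theta must be positive")
    if sd < 0.0:
        raise ValueError("sd must be non-negative")
    if sd == 0.0:
        return 0.0
    ratio2 = (sd / theta) ** 2
    x = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * ratio2))  # exp(omega^2)
    return float(np.sqrt(np.log(x)))


def omega_to_natural_sd(theta: float, omega: float) -> float:
    """Natural-scale SD of a log-normal with median ``theta`` and log-SD ``omega``."""
    x = np.exp(omega**2)
    return float(theta * np.sqrt(x * (x - 1.0)))


@dataclass(frozen=True)
class ResidualError:
    """Residual error model: ``kind`` in {proportional, additive, lognormal}, SD ``sd``."""

    kind: str = "proportional"
    sd: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "additive", "lognormal"):
            raise ValueError(f"unknown residual kind {self.kind!r}")
        if self.sd <= 0.0:
            raise ValueError("residual sd must be positive")


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, inter-individual SDs (natural scale) and residual model."""

    model: str
    fixed_effects: dict[str, float]
    iiv_sd: dict[str, float] = field(default_factory=dict)
    residual: ResidualError = field(default_factory=ResidualError)

    def __post_init__(self) -> None:
        if self.model not in MODEL_REGISTRY:
            raise KeyError(f"unknown model {self.model!r}")
        names = MODEL_REGISTRY[self.model][0]
        missing = [n for n in names if n not in self.fixed_effects]
        if missing:
            raise KeyError(f"model {self.model!r} missing fixed effects {missing}")
        extra = set(self.iiv_sd) - set(self.fixed_effects)
        if extra:
            raise KeyError(f"iiv keys not among fixed effects: {sorted(extra)}")
        for k, v in self.fixed_effects.items():
            if v <= 0.0:
                raise ValueError(f"fixed effect {k} must be positive")
        for k, v in self.iiv_sd.items():
            if v < 0.0:
                raise ValueError(f"iiv sd {k} must be non-negative")

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_REGISTRY[self.model][0]

    def mu(self) -> np.ndarray:
        return np.log([self.fixed_effects[n] for n in self.param_names])

    def omega2(self) -> np.ndarray:
        return np.array(
            [natural_sd_to_omega(self.fixed_effects[n], self.iiv_sd.get(n, 0.0)) ** 2 for n in self.param_names]
        )


@dataclass(frozen=True)
class SAEMConfig:
    """SAEM controls.

    ``n_burn`` exploration iterations (step size 1, annealed variances),
    ``n_smooth`` averaging iterations (step size 1/k), ``n_chains``
    parallel Markov chains per subject, ``mcmc_steps`` Metropolis
    transitions per iteration, ``dt`` integrator step (days), ``residual``
    the error-model kind, ``ll_samples`` importance-sampling draws for the
    marginal likelihood (0 disables).
    """

    n_burn: int = 150
    n_smooth: int = 100
    n_chains: int = 2
    mcmc_steps: int = 2
    dt: float = 0.1
    residual: str = "proportional"
    ll_samples: int = 200
    init_omega2: float = 0.25
    anneal: float = 0.95
    target_accept: float = 0.35
    init_jitter: float = 0.0  # SD of a log-scale perturbation of the starting fixed effects
    sigma_inflate: float = 1.0  # burn-in temperature: >1 inflates the residual variance early
    init_dt: float | None = None  # integrator step for the initialization fits (default: same as dt —
    #                               a coarser init grid biases weakly-identified parameters through
    #                               ridge amplification of the integrator mismatch)
    init_omega2_global: float = 0.02  # starting iiv variance of pooled (population-level) parameters;
    #                                   too small freezes their random effects at zero, biasing the
    #                                   fixed effect when the true variability is large
    burn_omega2_cap: float = 2.0  # iiv-variance ceiling during burn-in (stops random effects
    #                               absorbing fixed-effect misfit before the means settle)

    def __post_init__(self) -> None:
        if self.n_burn < 1 or self.n_smooth < 1 or self.n_chains < 1 or self.mcmc_steps < 1:
            raise ValueError("iteration/chain counts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Population estimate, per-subject estimates and fit diagnostics."""

    population: PopulationModel
    individual: pd.DataFrame
    rmse: float
    aic: float
    loglik: float
    converged: bool
    trace: pd.DataFrame
    n_parameters: int
    cond_mean: np.ndarray  # per-subject conditional means of phi (n, p)
    cond_var: np.ndarray   # per-subject conditional variances of phi (n, p)


# --------------------------------------------------------------------------
# design matrices and likelihood
# --------------------------------------------------------------------------


class _Design:
    """Flattened cohort view for vectorized prediction and likelihood."""

    def __init__(self, cohort: CohortDataset, model: str, dt: float):
        self.model = model
        self.dt = dt
        self.n = len(cohort)
        names = MODEL_REGISTRY[model][0]
        self.param_names = names
        self.p = len(names)
        snapped = [np.round(np.asarray(s.times) / dt) * dt for s in cohort]
        self.t_union = np.unique(np.concatenate(snapped))
        col_of = {t: j for j, t in enumerate(self.t_union)}
        self.obs_row = np.concatenate([np.full(len(ts), i, dtype=int) for i, ts in enumerate(snapped)])
        self.obs_col = np.concatenate([[col_of[t] for t in ts] for ts in snapped]).astype(int)
        self.y = np.concatenate([s.volumes for s in cohort])
        self.n_obs = len(self.y)
        self.schedules = [s.doses for s in cohort]
        self.ids = [s.id for s in cohort]

    def predict(self, theta_rows: np.ndarray) -> np.ndarray:
        """Noise-free predictions for stacked parameter rows.

        ``theta_rows`` has shape (m*n, p) with the cohort tiled m times;
        returns an (m, n_obs) matrix of predictions at the observations.
        """
        rows = theta_rows.shape[0]
        m = rows // self.n
        params = {name: theta_rows[:, j] for j, name in enumerate(self.param_names)}
        sims = simulate_many(self.model, params, list(self.schedules) * m, self.t_union, dt=self.dt)
        out = np.empty((m, self.n_obs))
        for c in range(m):
            out[c] = sims[c * self.n + self.obs_row, self.obs_col]
        return out


def _loglik_obs(f: np.ndarray, y: np.ndarray, sigma2: float, kind: str) -> np.ndarray:
    """Per-observation log density of y given prediction f."""
    f = np.maximum(f, _F_FLOOR)
    if kind == "proportional":
        var = sigma2 * f * f
        return -0.5 * (np.log(2.0 * np.pi * var) + (y - f) ** 2 / var)
    if kind == "additive":
        return -0.5 * (np.log(2.0 * np.pi * sigma2) + (y - f) ** 2 / sigma2)
    r = np.log(y) - np.log(f)
    return -0.5 * (np.log(2.0 * np.pi * sigma2) + r * r / sigma2) - np.log(y)


def _resid2(f: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Squared residuals on the error model's scale (sufficient stat for sigma^2)."""
    f = np.maximum(f, _F_FLOOR)
    if kind == "proportional":
        return ((y - f) / f) ** 2
    if kind == "additive":
        return (y - f) ** 2
    return (np.log(y) - np.log(f)) ** 2


def _ll_from_f(design: _Design, fpred: np.ndarray, sigma2: float, kind: str) -> np.ndarray:
    """Per-subject log-likelihood from cached predictions: (m, n_obs) -> (m, n)."""
    terms = _loglik_obs(fpred, design.y[None, :], sigma2, kind)
    out = np.zeros((fpred.shape[0], design.n))
    for c in range(fpred.shape[0]):
        out[c] = np.bincount(design.obs_row, weights=terms[c], minlength=design.n)
    return out


def _subject_loglik(design: _Design, phi: np.ndarray, sigma2: float, kind: str, return_f: bool = False):
    """Log p(y_i | phi_i) for stacked chains: phi (m, n, p) -> (m, n)."""
    m = phi.shape[0]
    fpred = design.predict(np.exp(phi.reshape(m * design.n, design.p)))
    out = _ll_from_f(design, fpred, sigma2, kind)
    return (out, fpred) if return_f else out


# --------------------------------------------------------------------------
# individual and pooled least-squares fits
# --------------------------------------------------------------------------


def _ls_fit(
    design: _Design,
    init: dict[str, float],
    bound: float = 6.0,
    xtol: float = 1e-10,
    max_nfev: int | None = None,
    free: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Least squares on log-parameters, log-scale residuals; returns phi-hat.

    With ``free`` given, only that parameter subset is estimated and the
    rest stay at their ``init`` values.
    """
    names = design.param_names
    phi_full = np.log([init[n] for n in names])
    free_idx = np.array([names.index(n) for n in (free or names)])

    def unpack(phi_free):
        phi = phi_full.copy()
        phi[free_idx] = phi_free
        return phi

    def resid(phi_free):
        phi = unpack(phi_free)
        f = design.predict(np.exp(phi)[None, :].repeat(design.n, axis=0))[0]
        return np.log(design.y) - np.log(np.maximum(f, _F_FLOOR))

    phi0 = phi_full[free_idx]
    sol = least_squares(
        resid, phi0, bounds=(phi0 - bound, phi0 + bound), xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=max_nfev
    )
    return unpack(sol.x)


def _global_ls(
    design: _Design,
    phi_subject: np.ndarray,
    global_idx: np.ndarray,
    g0: np.ndarray,
    bound: float = 3.0,
) -> np.ndarray:
    """Pooled least squares over population-level log-parameters.

    Per-subject log-parameters are held fixed at ``phi_subject``; only the
    columns in ``global_idx`` (shared across subjects) are estimated.
    """

    def resid(g_free):
        phi = phi_subject.copy()
        phi[:, global_idx] = g_free[None, :]
        f = design.predict(np.exp(phi))[0]
        return np.log(design.y) - np.log(np.maximum(f, _F_FLOOR))

    sol = least_squares(resid, g0, bounds=(g0 - bound, g0 + bound), xtol=1e-8, ftol=1e-8, max_nfev=60)
    return sol.x


def _alternating_init(
    cohort: CohortDataset,
    design: _Design,
    model: str,
    start: dict[str, float],
    dt: float,
    rounds: int = 2,
) -> np.ndarray:
    """Two-stage initialization: subject-level then pooled population fits.

    Alternates (a) per-subject least squares of the well-identified
    parameters (growth rate, V0) with the population-level parameters
    held fixed, and (b) one pooled least squares of the population-level
    parameters (drug potency and any structural parameters) over all
    subjects jointly.  Returns the per-subject log-parameter matrix with
    the pooled values in the shared columns.
    """
    names = design.param_names
    n, p = design.n, design.p
    subject_free = tuple(nme for nme in INIT_SUBJECT[model] if nme in names)
    global_names = tuple(nme for nme in names if nme not in subject_free)
    global_idx = np.array([names.index(nme) for nme in global_names])
    current = dict(start)
    phi = np.tile(np.log([current[nme] for nme in names]), (n, 1))
    any_doses = any(len(s.doses.events) for s in cohort)
    for _ in range(rounds):
        for i, subj in enumerate(cohort):
            design_i = _Design(CohortDataset(subjects=(subj,)), model, dt)
            start_i = dict(current, V0=float(subj.volumes[0]))
            phi[i] = _ls_fit(design_i, start_i, bound=4.0, xtol=1e-6, max_nfev=30, free=subject_free)
            phi[i, global_idx] = [np.log(current[nme]) for nme in global_names]
        est_idx = global_idx
        if not any_doses and "k_drug" in global_names:
            est_idx = np.array([names.index(nme) for nme in global_names if nme != "k_drug"])
        if len(est_idx):
            g0 = phi[0, est_idx].copy()
            g_hat = _global_ls(design, phi, est_idx, g0)
            phi[:, est_idx] = g_hat[None, :]
            for j in est_idx:
                current[names[j]] = float(np.exp(phi[0, j]))
    return phi


def fit_individual(
    subject: Subject,
    model: str,
    init: dict[str, float] | None = None,
    dt: float = 0.1,
    xtol: float = 1e-10,
    max_nfev: int | None = None,
) -> dict[str, float]:
    """Least-squares fit of one subject's series; seeds population fitting.

    Minimizes log-scale residuals log(y) - log(f) over the log-parameters
    (the weighted objective matching a proportional error model).  Needs
    at least as many observations as parameters and >= 4 observations.
    """
    names = MODEL_REGISTRY[model][0]
    if subject.n_obs < max(4, len(names)):
        raise ValueError(
            f"subject {subject.id}: {subject.n_obs} observations cannot identify {len(names)} parameters"
        )
    init = dict(DEFAULT_INIT[model], **(init or {}))
    if subject.n_obs:
        init["V0"] = float(subject.volumes[0])
    design = _Design(CohortDataset(subjects=(subject,)), model, dt)
    phi = _ls_fit(design, init, xtol=xtol, max_nfev=max_nfev)
    return {n: float(v) for n, v in zip(names, np.exp(phi))}


# --------------------------------------------------------------------------
# SAEM
# --------------------------------------------------------------------------


def fit_population(
    cohort: CohortDataset,
    model: str,
    config: SAEMConfig | None = None,
    seed: int = 0,
    init: PopulationModel | dict[str, float] | None = None,
) -> FitResult:
    """SAEM estimation of fixed effects, iiv SDs and residual SD.

    Parameters
    ----------
    cohort : CohortDataset (>= 2 subjects)
    model : growth-law name from the registry
    config : SAEMConfig, defaults used when omitted
    seed : master seed; identical seed + config + data reproduce the run
        bit for bit
    init : optional starting fixed effects (a dict or a PopulationModel);
        otherwise a pooled least-squares fit of typical values seeds the run

    Returns
    -------
    FitResult
        Population model (iiv reported as natural-scale SDs), per-subject
        conditional-mean estimates, rmse, importance-sampling AIC and the
        convergence trace.  Non-convergence sets ``converged=False``
        rather than raising.
    """
    if len(cohort) < 2:
        raise ValueError("population fitting needs at least 2 subjects")
    cfg = config or SAEMConfig()
    rng = np.random.default_rng(seed)
    design = _Design(cohort, model, cfg.dt)
    n, p = design.n, design.p
    m = cfg.n_chains
    kind = cfg.residual

    # ---- initialization -----------------------------------------------------
    # Per-subject least-squares fits of the well-identified parameter
    # subset (growth rate, drug potency, V0), with the remaining
    # parameters held at typical values, seed both the individual
    # log-parameters and the population summaries.  A PopulationModel or
    # a dict of typical values can override.
    phi_init = None
    if isinstance(init, PopulationModel):
        mu = init.mu()
        sigma2 = init.residual.sd**2
        omega2 = np.maximum(init.omega2(), 1e-4)
    else:
        start = dict(DEFAULT_INIT[model], **(init or {}))
        init_dt = cfg.init_dt if cfg.init_dt is not None else cfg.dt
        phi_init = _alternating_init(cohort, design, model, start, dt=init_dt)
        mu = np.median(phi_init, axis=0)
        f0 = design.predict(np.exp(phi_init))[0]
        sigma2 = float(np.mean(_resid2(f0, design.y, kind)))
        subject_free = set(INIT_SUBJECT[model]) & set(design.param_names)
        omega2 = np.array(
            [
                np.clip(np.var(phi_init[:, j]), 1e-3, cfg.init_omega2)
                if design.param_names[j] in subject_free
                else cfg.init_omega2_global
                for j in range(p)
            ]
        )
    # simulated annealing: start hot (inflated residual variance) so the
    # chain can travel along ridges of the population likelihood early on
    sigma2 = max(sigma2 * max(cfg.sigma_inflate, 1.0), _SIGMA2_FLOOR)
    if cfg.init_jitter > 0.0:
        mu = mu + cfg.init_jitter * rng.standard_normal(p)

    if phi_init is not None and cfg.init_jitter == 0.0:
        # start each chain at the subject's own seeded parameters (tiny
        # jitter decorrelates chains without displacing sharp posteriors)
        phi = np.broadcast_to(phi_init, (m, n, p)).copy()
        phi += 0.01 * rng.standard_normal((m, n, p))
    else:
        phi = mu[None, None, :] + np.sqrt(omega2)[None, None, :] * rng.standard_normal((m, n, p))
        v0_col = design.param_names.index("V0")
        phi[:, :, v0_col] = np.log([max(s.volumes[0], _F_FLOOR) for s in cohort])[None, :]
    ll, fcur = _subject_loglik(design, phi, sigma2, kind, return_f=True)

    s1 = np.zeros((n, p))
    s2 = np.zeros((n, p))
    s3 = 0.0
    # conditional moments accumulated during smoothing (for IS proposals)
    c1 = np.zeros((n, p))
    c2 = np.zeros((n, p))
    step_scale = 0.4
    n_iter = cfg.n_burn + cfg.n_smooth
    trace_rows = []

    for it in range(1, n_iter + 1):
        burn = it <= cfg.n_burn
        gamma = 1.0 if burn else 1.0 / (it - cfg.n_burn)

        # ---- MCMC kernel: random-walk Metropolis on phi_i ------------------
        # random-walk proposals use the ensemble covariance of phi so moves
        # stay aligned with likelihood ridges (adaptive Metropolis)
        flat = phi.reshape(m * n, p)
        if m * n > p + 2:
            S = np.cov(flat.T) + np.diag(np.maximum(omega2, 1e-4)) * 0.1
        else:
            S = np.diag(np.maximum(omega2, 1e-4))
        L_chol = np.linalg.cholesky(S)
        acc_frac = 0.0
        for step in range(cfg.mcmc_steps):
            if burn and step == 0:
                # independence kernel: propose from the current population
                # distribution (prior and proposal cancel in the ratio);
                # lets subjects jump between likelihood ridges while hot
                cand = mu[None, None, :] + np.sqrt(omega2)[None, None, :] * rng.standard_normal((m, n, p))
                ll_cand, f_cand = _subject_loglik(design, cand, sigma2, kind, return_f=True)
                log_alpha = ll_cand - ll
            else:
                z = rng.standard_normal((m, n, p))
                cand = phi + step_scale * np.einsum("mnp,qp->mnq", z, L_chol)
                ll_cand, f_cand = _subject_loglik(design, cand, sigma2, kind, return_f=True)
                lp = -0.5 * np.sum((phi - mu[None, None, :]) ** 2 / omega2[None, None, :], axis=2)
                lp_cand = -0.5 * np.sum((cand - mu[None, None, :]) ** 2 / omega2[None, None, :], axis=2)
                log_alpha = (ll_cand + lp_cand) - (ll + lp)
            accept = np.log(rng.uniform(size=(m, n))) < log_alpha
            phi = np.where(accept[:, :, None], cand, phi)
            ll = np.where(accept, ll_cand, ll)
            # swap cached predictions for accepted subjects (observation-wise)
            acc_obs = accept[:, design.obs_row]
            fcur = np.where(acc_obs, f_cand, fcur)
            if not (burn and step == 0):
                acc_frac += accept.mean() / max(cfg.mcmc_steps - (1 if burn else 0), 1)
        if burn:
            step_scale = float(np.clip(step_scale * np.exp(0.05 * (acc_frac - cfg.target_accept)), 0.001, 2.0))

        # ---- stochastic approximation of sufficient statistics -------------
        phi_mean = phi.mean(axis=0)          # (n, p) over chains
        phi2_mean = (phi**2).mean(axis=0)
        r2 = float(np.mean(np.sum(_resid2(fcur, design.y[None, :], kind), axis=1)))
        s1 = s1 + gamma * (phi_mean - s1)
        s2 = s2 + gamma * (phi2_mean - s2)
        s3 = s3 + gamma * (r2 - s3)
        if not burn:
            g2 = 1.0 / (it - cfg.n_burn)
            c1 = c1 + g2 * (phi_mean - c1)
            c2 = c2 + g2 * (phi2_mean - c2)

        # ---- M-step ---------------------------------------------------------
        mu = s1.mean(axis=0)
        omega2_new = np.maximum(s2.mean(axis=0) - mu**2, _OMEGA2_FLOOR)
        sigma2_new = max(s3 / design.n_obs, _SIGMA2_FLOOR)
        if burn:
            omega2 = np.minimum(np.maximum(omega2_new, cfg.anneal * omega2), cfg.burn_omega2_cap)
            sigma2 = max(sigma2_new, cfg.anneal * sigma2)
        else:
            omega2, sigma2 = omega2_new, sigma2_new
        ll = _ll_from_f(design, fcur, sigma2, kind)  # refresh under new sigma, no re-simulation

        trace_rows.append(
            dict(
                iteration=it,
                phase="burn" if burn else "smooth",
                accept=acc_frac,
                sigma=np.sqrt(sigma2),
                **{f"mu_{nme}": mu[j] for j, nme in enumerate(design.param_names)},
                **{f"omega_{nme}": np.sqrt(omega2[j]) for j, nme in enumerate(design.param_names)},
            )
        )

    trace = pd.DataFrame(trace_rows)

    # ---- convergence check on the smoothing-phase trace ----------------------
    tail = trace[trace["phase"] == "smooth"]
    half = max(len(tail) // 2, 1)
    mu_cols = [f"mu_{nme}" for nme in design.param_names]
    drift = (tail[mu_cols].iloc[-1] - tail[mu_cols].iloc[half - 1]).abs()
    converged = bool((drift < 0.10).all())

    theta_hat = np.exp(mu)
    fixed = {nme: float(theta_hat[j]) for j, nme in enumerate(design.param_names)}
    iiv = {nme: omega_to_natural_sd(theta_hat[j], float(np.sqrt(omega2[j]))) for j, nme in enumerate(design.param_names)}
    pop = PopulationModel(
        model=model, fixed_effects=fixed, iiv_sd=iiv, residual=ResidualError(kind=kind, sd=float(np.sqrt(sigma2)))
    )

    cond_var = np.maximum(c2 - c1**2, 1e-8)
    individual = pd.DataFrame(np.exp(c1), columns=list(design.param_names))
    individual.insert(0, "subject_id", design.ids)

    n_parameters = p + p + 1  # fixed effects + iiv variances + residual variance
    if cfg.ll_samples > 0:
        loglik = _importance_loglik(design, mu, omega2, sigma2, kind, c1, cond_var, cfg.ll_samples, rng)
    else:
        loglik = float("nan")
    aic = -2.0 * loglik + 2.0 * n_parameters

    # conditional-mean predictions: c1 is (n, p), i.e. the cohort tiled once
    f_ind = design.predict(np.exp(c1))[0]
    rmse = float(np.sqrt(np.mean(_resid2(f_ind, design.y, kind))))

    return FitResult(
        population=pop,
        individual=individual,
        rmse=rmse,
        aic=float(aic),
        loglik=float(loglik),
        converged=converged,
        trace=trace,
        n_parameters=n_parameters,
        cond_mean=c1,
        cond_var=cond_var,
    )


def fit_population_runs(
    cohort: CohortDataset,
    model: str,
    config: SAEMConfig | None = None,
    seed: int = 0,
    n_runs: int = 10,
    init: PopulationModel | dict[str, float] | None = None,
) -> tuple[FitResult, list[FitResult]]:
    """Repeat the SAEM fit ``n_runs`` times and keep the best.

    The population likelihood of nonlinear mixed models can be
    multi-modal, so production analyses repeat the fit from perturbed
    starts with different seeds and report the run with the highest
    importance-sampling log-likelihood.  Returns (best run, all runs).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = config or SAEMConfig()
    if cfg.ll_samples <= 0:
        raise ValueError("multi-run selection needs ll_samples > 0")
    runs = []
    for r in range(n_runs):
        cfg_r = cfg if r == 0 else replace(cfg, init_jitter=max(cfg.init_jitter, 0.3))
        runs.append(fit_population(cohort, model, cfg_r, seed=seed + 1000 * r, init=init))
    best = max(runs, key=lambda f: f.loglik)
    return best, runs


def _importance_loglik(
    design: _Design,
    mu: np.ndarray,
    omega2: np.ndarray,
    sigma2: float,
    kind: str,
    prop_mean: np.ndarray,
    prop_var: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> float:
    """Importance-sampling marginal log-likelihood.

    Per subject the proposal is Gaussian with the conditional moments from
    the SAEM smoothing phase (variance inflated 1.5x); subjects with
    effectively no random effect collapse onto the prior automatically.
    """
    n, p = prop_mean.shape
    omega2_safe = np.maximum(omega2, _OMEGA2_FLOOR)
    # where the prior is tighter than the proposal, sample the prior instead
    q_var = np.minimum(1.5 * prop_var, np.broadcast_to(omega2_safe, (n, p)) * 4.0)
    q_var = np.maximum(q_var, 1e-10)
    q_mean = prop_mean
    tiny = omega2_safe < 1e-8
    q_mean = np.where(tiny[None, :], mu[None, :], q_mean)
    q_var = np.where(tiny[None, :], omega2_safe[None, :], q_var)

    logw = np.empty((n_samples, n))
    q_sd = np.sqrt(q_var)
    for s in range(n_samples):
        phi = q_mean + q_sd * rng.standard_normal((n, p))
        ll = _subject_loglik(design, phi[None, :, :], sigma2, kind)[0]
        lprior = -0.5 * np.sum(
            (phi - mu[None, :]) ** 2 / omega2_safe[None, :] + np.log(2.0 * np.pi * omega2_safe)[None, :], axis=1
        )
        lq = -0.5 * np.sum((phi - q_mean) ** 2 / q_var + np.log(2.0 * np.pi * q_var), axis=1)
        logw[s] = ll + lprior - lq
    ll_subj = logsumexp(logw, axis=0) - np.log(n_samples)
    return float(ll_subj.sum())


def information_criteria(fit: FitResult, cohort: CohortDataset) -> tuple[float, float]:
    """(rmse, AIC) of a converged fit on its cohort.

    rmse is the root mean square residual on the residual model's scale at
    the per-subject conditional-mean parameters; AIC is
    -2*loglik + 2*(fixed effects + iiv variances + residual variance),
    with the marginal log-likelihood from importance sampling.
    """
    if not np.isfinite(fit.loglik):
        raise ValueError("fit carries no likelihood (ll_samples was 0); refit with ll_samples > 0")
    return fit.rmse, fit.aic
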