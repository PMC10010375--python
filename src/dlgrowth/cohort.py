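"""Synthetic cohorts emulating CDX-style preclinical trial designs.

The reference design ("az_cdx") mirrors a 95-mouse SW620 xenograft trial:
weekly 50 mg/kg CPT-11 boluses under three protocols — days 1/8/15
(68 mice), days 1/8/15/22 (18 mice), days 4/11/18/25 (9 mice) — with
caliper volume measurements every 2-3 days over ~30 days.  Individual
parameters are drawn log-normally around the population values and the
observed volumes carry proportional measurement noise (default CV 10%).

Per-subject random streams are derived from (master seed, arm index,
subject index), so changing one arm's size never perturbs another arm's
subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CohortDataset, Subject
from .fastsim import simulate_many
from .pk import DoseSchedule, weekly_protocol
from .population import PopulationModel, ResidualError, natural_sd_to_omega

__all__ = [
    "Arm",
    "CohortDesign",
    "az_cdx_design",
    "table_population",
    "DL_POPULATION",
    "EL_POPULATION",
    "DEFAULT_MEASUREMENT_DAYS",
    "sample_individual_params",
    "generate_cohort",
    "caliper_observe",
]

#: nominal measurement days, every 2-3 days over ~30 days
DEFAULT_MEASUREMENT_DAYS = (0.0, 2.0, 5.0, 7.0, 9.0, 12.0, 14.0, 16.0, 19.0, 21.0, 23.0, 26.0, 28.0, 30.0)

#: published population estimates (value, natural-scale iiv SD) for the
#: diffusion-limited model on the 95-mouse CDX dataset
DL_POPULATION = {
    "lambda_net": (0.12, 0.02),
    "lambda_nec": (0.05, 0.03),
    "k_drug": (5.7e-3, 2.4e-4),
    "R_c": (0.41, 0.07),
    "V0": (0.25, 0.11),
}

#: exponential-linear counterpart (transition exponent psi fixed, not fitted)
EL_POPULATION = {
    "lambda0": (0.08, 0.25),
    "lambda1": (0.31, 0.06),
    "k_drug": (1.2e-3, 4e-4),
    "V0": (0.29, 0.13),
}


def table_population(model: str, residual_sd: float = 0.1, residual_kind: str = "proportional") -> PopulationModel:
    """The published population model for ``model`` in {"dl", "exponential_linear"}."""
    table = {"dl": DL_POPULATION, "exponential_linear": EL_POPULATION}[model]
    return PopulationModel(
        model=model,
        fixed_effects={k: v[0] for k, v in table.items()},
        iiv_sd={k: v[1] for k, v in table.items()},
        residual=ResidualError(kind=residual_kind, sd=residual_sd),
    )


@dataclass(frozen=True)
class Arm:
    """One protocol arm: subject count, dose schedule, measurement days."""

    n_subjects: int
    schedule: DoseSchedule | None = None
    measurement_days: tuple[float, ...] = DEFAULT_MEASUREMENT_DAYS
    label: str = "arm"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        days = tuple(float(d) for d in self.measurement_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement days must be strictly increasing")
        object.__setattr__(self, "measurement_days", days)


@dataclass(frozen=True)
class CohortDesign:
    """A list of arms plus the observation-noise model.

    ``error_cv`` is the proportional measurement CV (caliper noise applied
    to volume); ``observation`` chooses the noise layer — "volume"
    multiplies the volume directly, "caliper" perturbs emulated
    length/width measurements and recomputes V = (pi/6)*L*W^2.
    """

    arms: tuple[Arm, ...]
    error_cv: float = 0.10
    observation: str = "volume"

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        if not self.arms:
            raise ValueError("design needs at least one arm")
        if self.error_cv < 0.0:
            raise ValueError("error_cv must be non-negative")
        if self.observation not in ("volume", "caliper"):
            raise ValueError(f"unknown observation layer {self.observation!r}")

    @property
    def n_subjects(self) -> int:
        return sum(a.n_subjects for a in self.arms)


def az_cdx_design(
    n_subjects: int | None = None,
    dose: float = 50.0,
    error_cv: float = 0.10,
    measurement_days: tuple[float, ...] = DEFAULT_MEASUREMENT_DAYS,
) -> CohortDesign:
    """The three-protocol CDX treatment design (68/18/9 mice, 95 total).

    With ``n_subjects`` given, arm sizes are scaled proportionally (each
    arm keeps at least one subject).
    """
    sizes = np.array([68, 18, 9], dtype=float)
    if n_subjects is not None:
        scaled = np.maximum(np.rint(sizes * n_subjects / sizes.sum()).astype(int), 1)
        # adjust the largest arm so the total matches exactly
        scaled[0] += n_subjects - scaled.sum()
        sizes = scaled
    sizes = sizes.astype(int)
    arms = tuple(
        Arm(
            n_subjects=int(nk),
            schedule=weekly_protocol(proto, dose=dose),
            measurement_days=measurement_days,
            label=f"protocol{proto}",
        )
        for nk, proto in zip(sizes, (1, 2, 3))
    )
    return CohortDesign(arms=arms, error_cv=error_cv)


def sample_individual_params(pop: PopulationModel, seed, n: int = 1) -> dict[str, np.ndarray]:
    """Draw ``n`` individual parameter sets from the log-normal iiv model.

    ``seed`` may be an int or a ``numpy`` SeedSequence/Generator.  All
    draws are strictly positive; zero iiv returns the fixed effects
    exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in pop.param_names:
        theta = pop.fixed_effects[name]
        omega = natural_sd_to_omega(theta, pop.iiv_sd.get(name, 0.0))
        out[name] = theta * np.exp(omega * rng.standard_normal(n))
    return out


def caliper_observe(V: np.ndarray, cv: float, rng: np.random.Generator, aspect: float = 1.3) -> np.ndarray:
    """Caliper emulation: noise on length/width, volume via V = (pi/6)*L*W^2.

    The true volume is mapped to a length/width pair with fixed aspect
    ratio ``L/W``, each measurement is perturbed with proportional CV
    ``cv``, and the conventional ellipsoid formula recomputes the volume.
    """
    W = np.cbrt(6.0 * V / (np.pi * aspect))
    L = aspect * W
    L_obs = L * (1.0 + cv * rng.standard_normal(V.shape))
    W_obs = W * (1.0 + cv * rng.standard_normal(V.shape))
    return np.pi / 6.0 * np.abs(L_obs) * W_obs**2


def generate_cohort(
    design: CohortDesign,
    pop: PopulationModel,
    model: str | None = None,
    seed: int = 0,
    dt: float = 0.05,
    max_redraws: int = 20,
) -> CohortDataset:
    """Simulate a synthetic cohort under ``design`` from ``pop``.

    Per subject: draw individual parameters, integrate the growth law
    under the arm's dose schedule, and apply measurement noise at the
    observation days.  Pathological draws whose observed volumes are not
    all positive are redrawn (count capped by ``max_redraws``).
    """
    model = model or pop.model
    if model != pop.model:
        raise ValueError(f"population model is {pop.model!r}, requested {model!r}")
    subjects: list[Subject] = []
    counter = 0
    for arm_idx, arm in enumerate(design.arms):
        days = np.asarray(arm.measurement_days)
        # one simulation per arm: draw all subjects, integrate vectorized
        draws: dict[str, np.ndarray] = {name: np.empty(arm.n_subjects) for name in pop.param_names}
        rngs = [
            np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), arm_idx, j)))
            for j in range(arm.n_subjects)
        ]
        for j, rng in enumerate(rngs):
            single = sample_individual_params(pop, rng, n=1)
            for name in pop.param_names:
                draws[name][j] = single[name][0]
        clean = simulate_many(model, draws, arm.schedule, days, dt=dt)
        for j, rng in enumerate(rngs):
            volumes = None
            for attempt in range(max_redraws + 1):
                if design.observation == "caliper":
                    obs = caliper_observe(clean[j], design.error_cv, rng)
                else:
                    obs = clean[j] * (1.0 + design.error_cv * rng.standard_normal(len(days)))
                if np.all(obs > 0.0):
                    volumes = obs
                    break
                # redraw the noise only; the trajectory itself is deterministic
            if volumes is None:
                raise RuntimeError(f"subject draw produced non-positive volumes after {max_redraws} redraws")
            counter += 1
            subjects.append(
                Subject(
                    id=f"{arm.label}_{j + 1:03d}",
                    times=days.copy(),
                    volumes=volumes,
                    doses=arm.schedule if arm.schedule is not None else DoseSchedule(),
                )
            )
    return CohortDataset(subjects=tuple(subjects))
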