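"""Empirical comparator growth laws under the shared dosing/kill interface.

Each law is a rate equation dV/dt = g(V) - k_drug*c(t)*V, with the kill
acting on the total volume (these laws carry no growth-fraction concept).
Available laws:

========================  ==========================================  ======
name                      g(V)                                        params
========================  ==========================================  ======
linear                    a                                           a
exponential               a*V                                         a
logistic                  a*V*(1 - V/K)                               a, K
gompertz                  a*V*ln(K/V)                                 a, K
exponential_linear        lam0*V / (1 + (lam0*V/lam1)^psi)^(1/psi)    lam0, lam1 (psi fixed)
surface                   a*V^(2/3)                                   a
proliferative_rim         a*(V - (4pi/3)*max(R - d, 0)^3)             a, d
========================  ==========================================  ======

The exponential-linear law interpolates smoothly between an exponential
phase (rate lam0, day^-1) and a linear phase (rate lam1, cm^3/day); the
sharpness exponent psi is held at 20, fast enough that the law is
effectively the exponential-then-linear envelope.  The surface-growth and
proliferative-rim laws restrict proliferation to a fixed outer region of
the tumor (the full surface, or a rim of constant thickness d cm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import Trajectory
from .fastsim import EL_PSI_DEFAULT, MODEL_REGISTRY
from .pk import DoseSchedule

__all__ = ["ELParams", "GrowthLawSpec", "get_law", "growth_rate", "simulate_law", "LAW_NAMES"]

#: comparator law names (every registry model except the mechanistic one)
LAW_NAMES = tuple(name for name in MODEL_REGISTRY if name != "dl")


@dataclass(frozen=True)
class ELParams:
    """Exponential-linear parameters (Simeoni-type smooth transition).

    ``lambda0`` exponential-phase rate (day^-1), ``lambda1`` linear-phase
    rate (cm^3/day), ``psi`` transition sharpness (fixed, not fitted),
    ``k_drug`` potency (kg mg^-1 day^-1), ``V0`` initial volume (cm^3).
    """

    lambda0: float
    lambda1: float
    k_drug: float
    V0: float
    psi: float = EL_PSI_DEFAULT

    def __post_init__(self) -> None:
        for name in ("lambda0", "lambda1", "k_drug", "V0", "psi"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")

    def as_dict(self) -> dict[str, float]:
        return {"lambda0": self.lambda0, "lambda1": self.lambda1, "k_drug": self.k_drug, "V0": self.V0}


@dataclass(frozen=True)
class GrowthLawSpec:
    """A named growth law bound to parameter values."""

    name: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in MODEL_REGISTRY:
            raise KeyError(f"unknown growth law {self.name!r}; known: {sorted(MODEL_REGISTRY)}")
        names, fixed, _ = MODEL_REGISTRY[self.name]
        missing = [n for n in names if n != "k_drug" and n != "V0" and n not in self.params]
        if missing:
            raise KeyError(f"law {self.name!r} missing parameters {missing}")
        for key, value in self.params.items():
            if key not in ("psi",) and value <= 0.0 and key != "k_drug":
                raise ValueError(f"{key} must be positive, got {value!r}")


def get_law(name: str, **params: float) -> GrowthLawSpec:
    """Convenience constructor with validation."""
    return GrowthLawSpec(name=name, params=params)


def growth_rate(law: GrowthLawSpec | str, V, params: dict[str, float] | None = None):
    """Drug-free net growth rate g(V) (cm^3/day) of a law; vectorized in V."""
    if isinstance(law, str):
        law = GrowthLawSpec(name=law, params=dict(params or {}))
    _, fixed, drift = MODEL_REGISTRY[law.name]
    P = dict(fixed)
    P.update(law.params)
    P["k_drug"] = 0.0
    V_arr = np.asarray(V, dtype=float)
    if np.any(V_arr <= 0.0):
        raise ValueError("volume must be positive")
    out = drift(V_arr, 0.0, P)
    return float(out) if np.ndim(V) == 0 else out


def simulate_law(
    law: GrowthLawSpec | str,
    schedule: DoseSchedule | None,
    t_grid: np.ndarray,
    params: dict[str, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate dV/dt = g(V) - k_drug*c(t)*V on ``t_grid`` (days).

    Dose events are handled as concentration discontinuities by
    segmenting the integration at dose times.  Comparator laws have no
    necrotic compartment, so the returned trajectory has ``G = 1`` and
    ``R_n = 0`` throughout.
    """
    if isinstance(law, str):
        law = GrowthLawSpec(name=law, params=dict(params or {}))
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0.0) or t_grid[0] != 0.0:
        raise ValueError("t_grid must be strictly increasing and start at 0")

    _, fixed, drift = MODEL_REGISTRY[law.name]
    P = dict(fixed)
    P.update(law.params)
    k_drug = float(P.get("k_drug", 0.0))
    P["k_drug"] = k_drug
    V0 = float(P.get("V0", law.params.get("V0", np.nan)))
    if not np.isfinite(V0) or V0 <= 0.0:
        raise ValueError("law parameters must include a positive V0")

    def conc(t: float) -> float:
        return 0.0 if schedule is None else schedule.concentration(t)

    def rhs(t, y):
        return [float(drift(np.array([max(y[0], 1e-12)]), conc(t), P)[0])]

    t_end = float(t_grid[-1])
    dose_times = np.array([]) if schedule is None else schedule.times
    cuts = np.unique(dose_times[(dose_times > 0.0) & (dose_times < t_end)])
    edges = np.concatenate(([0.0], cuts, [t_end]))

    out = np.empty_like(t_grid)
    written = np.zeros(len(t_grid), dtype=bool)
    out[0] = V0
    written[0] = True
    V_now = V0
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (t_grid > a + 1e-13) & (t_grid <= b + 1e-13) & ~written
        t_req = t_grid[mask]
        # the segment end is always evaluated: it is the restart state
        t_eval = np.unique(np.append(t_req, b))
        sol = solve_ivp(rhs, (a, b), [V_now], method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1] if len(sol.t) else a}: {sol.message}")
        if len(t_req):
            out[mask] = sol.y[0][np.isin(sol.t, t_req)]
            written[mask] = True
        V_now = float(sol.y[0, -1])
    out[~written] = V_now
    return Trajectory(t=t_grid.copy(), V=out, G=np.ones_like(out), R_n=np.zeros_like(out))
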