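"""Diffusion-limited tumor growth law.

A spherical tumor is modeled as a proliferating shell around a necrotic
core.  Nutrient reaches the tissue by diffusion from the surface; below a
critical radius ``R_c`` the whole tumor is nourished and proliferates
(growth fraction ``G = 1``, exponential growth).  Once the outer radius
``R`` exceeds ``R_c``, the steady-state spherical diffusion balance with
uniform consumption in the live shell and no flux into the core fixes the
necrotic radius ``R_n`` through the algebraic constraint

    R^2 - 3*R_n^2 + 2*R_n^3 / R = R_c^2,

and the growth fraction is the live-shell volume fraction
``G = 1 - (R_n/R)^3``.  The volume then evolves as

    dV/dt = lambda_net*G*V - lambda_nec*(1-G)*V - k_drug*c(t)*G*V,

i.e. net proliferation in the growing fraction, breakdown and removal of
necrotic material, and drug kill acting on living cells only.

The system is a differential-algebraic equation (DAE).  Two equivalent
integration routes are provided: re-solving the constraint for ``R_n`` at
every right-hand-side evaluation (``method="dae"``), or differentiating
the constraint once and integrating ``(V, R_n)`` jointly
(``method="ode"``), with event detection for the necrosis-onset crossing
in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

if TYPE_CHECKING:  # pragma: no cover
    from .pk import DoseSchedule

__all__ = [
    "DLParams",
    "TumorState",
    "Trajectory",
    "critical_volume",
    "radius_from_volume",
    "volume_from_radius",
    "solve_necrotic_radius",
    "growth_fraction",
    "necrotic_area_fraction",
    "dl_rhs",
    "simulate_dl",
]

_FOUR_THIRDS_PI = 4.0 * np.pi / 3.0

#: absolute tolerance for the necrotic-radius root solve (cm)
ROOT_ATOL = 1e-10

#: relative offset above the critical volume before the differentiated
#: constraint ODE is engaged (the constraint Jacobian in R_n vanishes at
#: R_n = 0, so the switch must happen strictly above onset)
ONSET_DELTA = 1e-9


@dataclass(frozen=True)
class DLParams:
    """Parameters of the diffusion-limited growth law.

    Attributes
    ----------
    lambda_net : float
        Net proliferation rate in the growing fraction (day^-1).
    lambda_nec : float
        Necrotic breakdown/removal rate (day^-1).
    k_drug : float
        Drug potency (kg mg^-1 day^-1); the kill rate is ``k_drug * c``
        with ``c`` in mg/kg.
    R_c : float
        Critical radius (cm) at which necrosis first appears.
    V0 : float
        Initial tumor volume (cm^3).
    """

    lambda_net: float
    lambda_nec: float
    k_drug: float
    R_c: float
    V0: float

    def __post_init__(self) -> None:
        for name in ("lambda_net", "lambda_nec", "k_drug", "R_c", "V0"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")

    @property
    def V_c(self) -> float:
        """Critical volume (cm^3) corresponding to ``R_c``."""
        return critical_volume(self.R_c)


@dataclass(frozen=True)
class TumorState:
    """Instantaneous tumor description.

    ``V`` volume (cm^3), ``R`` outer radius (cm), ``R_n`` necrotic radius
    (cm), ``G`` growth fraction (dimensionless, in (0, 1]).
    """

    V: float
    R: float
    R_n: float
    G: float

    @classmethod
    def from_volume(cls, V: float, R_c: float) -> "TumorState":
        """Construct a consistent state from a volume and critical radius."""
        if V <= 0.0:
            raise ValueError(f"volume must be positive, got {V!r}")
        R = radius_from_volume(V)
        if V <= critical_volume(R_c):
            return cls(V=V, R=R, R_n=0.0, G=1.0)
        R_n = solve_necrotic_radius(R, R_c)
        return cls(V=V, R=R, R_n=R_n, G=1.0 - (R_n / R) ** 3)


@dataclass(frozen=True)
class Trajectory:
    """Simulated trajectory on a time grid: arrays ``t``, ``V``, ``G``, ``R_n``."""

    t: np.ndarray
    V: np.ndarray
    G: np.ndarray
    R_n: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.V) == len(self.G) == len(self.R_n) == n):
            raise ValueError("trajectory arrays must share one length")


def critical_volume(R_c: float) -> float:
    """Volume (cm^3) of a sphere of the critical radius ``R_c`` (cm).

    Tumors below this volume are fully proliferating; necrosis first
    appears when the volume reaches it.
    """
    if R_c <= 0.0:
        raise ValueError(f"R_c must be positive, got {R_c!r}")
    return _FOUR_THIRDS_PI * R_c**3


def radius_from_volume(V):
    """Radius (cm) of a sphere of volume ``V`` (cm^3). Accepts arrays."""
    return np.cbrt(np.asarray(V) / _FOUR_THIRDS_PI) if np.ndim(V) else float(np.cbrt(V / _FOUR_THIRDS_PI))


def volume_from_radius(R):
    """Volume (cm^3) of a sphere of radius ``R`` (cm). Accepts arrays."""
    return _FOUR_THIRDS_PI * np.asarray(R) ** 3 if np.ndim(R) else _FOUR_THIRDS_PI * float(R) ** 3


def _constraint(R_n: float, R: float, R_c: float) -> float:
    """Residual of the nutrient-diffusion constraint at necrotic radius R_n."""
    return R * R - 3.0 * R_n * R_n + 2.0 * R_n**3 / R - R_c * R_c


def solve_necrotic_radius(R: float, R_c: float, atol: float = ROOT_ATOL) -> float:
    """Necrotic radius ``R_n`` for a tumor of outer radius ``R``.

    Solves the steady-state spherical diffusion constraint
    ``R^2 - 3 R_n^2 + 2 R_n^3 / R = R_c^2`` for the unique root in
    ``[0, R)``.  The constraint is strictly decreasing in ``R_n`` on that
    interval, so the root is bracketed and found by Brent's method.

    Raises
    ------
    ValueError
        If ``R < R_c`` (the tumor is fully proliferating; the caller must
        use the ``G = 1`` branch).
    """
    if R < R_c:
        raise ValueError(f"R={R!r} < R_c={R_c!r}: tumor is fully proliferating (G = 1 branch)")
    if R == R_c:
        return 0.0
    lo, hi = 0.0, R * (1.0 - 1e-15)
    f_lo = _constraint(lo, R, R_c)
    f_hi = _constraint(hi, R, R_c)
    if f_lo < 0.0 or f_hi > 0.0:
        raise ArithmeticError(f"no sign change bracketing R_n for R={R}, R_c={R_c}")
    return float(brentq(_constraint, lo, hi, args=(R, R_c), xtol=atol))


def growth_fraction(V: float, R_c: float) -> float:
    """Growth fraction ``G`` of a tumor of volume ``V`` (cm^3).

    Returns 1 while ``V`` is at or below the critical volume; above it,
    ``G = 1 - (R_n/R)^3`` with ``R_n`` from the diffusion constraint.
    Continuous at the onset and strictly decreasing in ``V`` beyond it.
    """
    if V <= 0.0:
        raise ValueError(f"volume must be positive, got {V!r}")
    if V <= critical_volume(R_c):
        return 1.0
    R = radius_from_volume(V)
    R_n = solve_necrotic_radius(R, R_c)
    return 1.0 - (R_n / R) ** 3


def necrotic_area_fraction(G: float) -> float:
    """Necrotic area fraction of a central cross-section, ``(1 - G)^(2/3)``.

    The volumetric growth fraction gives ``(R_n/R)^3 = 1 - G``; a central
    section through the sphere shows the necrotic disc as an area fraction
    ``(R_n/R)^2``.  This is the scalar link between the model's growth
    fraction and endpoint histology (e.g. Ki-67-delineated necrotic area).
    """
    if not 0.0 < G <= 1.0:
        raise ValueError(f"growth fraction must lie in (0, 1], got {G!r}")
    return (1.0 - G) ** (2.0 / 3.0)


# --------------------------------------------------------------------------
# fast vectorized growth fraction: u = R_n/R solves (1-u)^2 (1+2u) = (R_c/R)^2
# --------------------------------------------------------------------------

_TWO_PI_3 = 2.0 * np.pi / 3.0


def core_ratio(s):
    """Vectorized inverse of ``(1-u)^2 (1+2u) = s`` for ``u = R_n/R``.

    ``s = (R_c/R)^2`` in ``(0, 1]``; returns ``u`` in ``[0, 1)``.  The
    substitution ``w = 2u - 1`` turns the constraint cubic into the
    depressed form ``w^3 - 3w + (2 - 4s) = 0``, whose physical root has
    the closed trigonometric expression used here.
    """
    s = np.asarray(s, dtype=float)
    u = 0.5 + np.cos(np.arccos(np.clip(2.0 * s - 1.0, -1.0, 1.0)) / 3.0 - _TWO_PI_3)
    return np.clip(u, 0.0, 1.0 - 1e-15)


def growth_fraction_vec(V, R_c):
    """Vectorized growth fraction for volumes ``V`` (cm^3); arrays allowed."""
    V = np.asarray(V, dtype=float)
    R_c = np.asarray(R_c, dtype=float)
    s = (critical_volume(1.0) * R_c**3 / np.maximum(V, 1e-300)) ** (2.0 / 3.0)
    u = core_ratio(np.minimum(s, 1.0))
    return np.where(s >= 1.0, 1.0, 1.0 - u**3)


# --------------------------------------------------------------------------
# right-hand sides
# --------------------------------------------------------------------------


def dl_rhs(state: TumorState, params: DLParams, c: float) -> tuple[float, float]:
    """Time derivatives ``(dV/dt, dR_n/dt)`` at a consistent state.

    ``dV/dt = lambda_net*G*V - lambda_nec*(1-G)*V - k_drug*c*G*V``.  In
    the diffusion-limited phase ``dR_n/dt`` follows from differentiating
    the constraint and chain-ruling through ``dR/dt``; in the fully
    proliferating phase ``R_n`` is identically zero.
    """
    V, R, R_n, G = state.V, state.R, state.R_n, state.G
    dV = (params.lambda_net * G - params.lambda_nec * (1.0 - G) - params.k_drug * c * G) * V
    if R_n <= 0.0:
        return dV, 0.0
    dR = dV / (4.0 * np.pi * R * R)
    # F(R, R_n) = R^2 - 3 R_n^2 + 2 R_n^3/R - R_c^2 = 0 along the trajectory
    F_R = 2.0 * R - 2.0 * R_n**3 / (R * R)
    F_Rn = -6.0 * R_n + 6.0 * R_n * R_n / R
    if F_Rn == 0.0:
        raise ZeroDivisionError("constraint Jacobian singular at R_n = 0; use the G = 1 branch")
    dRn = -F_R * dR / F_Rn
    return dV, dRn


def _drift(V: float, G: float, params: DLParams, c: float) -> float:
    return (params.lambda_net * G - params.lambda_nec * (1.0 - G) - params.k_drug * c * G) * V


# --------------------------------------------------------------------------
# trajectory simulation with phase switching
# --------------------------------------------------------------------------


def simulate_dl(
    params: DLParams,
    schedule: "DoseSchedule | None",
    t_grid: np.ndarray,
    method: str = "ode",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the diffusion-limited law on ``t_grid`` (days).

    Parameters
    ----------
    params : DLParams
    schedule : DoseSchedule or None
        Dose events with exponential plasma decay; ``None`` means no
        treatment.
    t_grid : array of days
        Strictly increasing output times starting at 0.
    method : {"ode", "dae"}
        ``"ode"`` integrates ``(V, R_n)`` with the differentiated
        constraint; ``"dae"`` integrates ``V`` alone, re-solving the
        algebraic constraint for the growth fraction at every
        right-hand-side call.  The two agree to integrator tolerance.

    Returns
    -------
    Trajectory
        Volume, growth fraction and necrotic radius at the grid times.

    Notes
    -----
    Integration is segmented at dose times (the plasma concentration is
    discontinuous there) and at crossings of the critical volume in either
    direction — growth into the diffusion-limited phase, or drug-induced
    shrinkage back to full proliferation, which responsively raises the
    growth fraction.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise ValueError("t_grid must be a 1-D array of times")
    if np.any(np.diff(t_grid) <= 0.0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if method not in ("ode", "dae"):
        raise ValueError(f"unknown method {method!r}")

    V_c = params.V_c
    dose_times = np.array([], dtype=float)
    if schedule is not None and len(schedule.events) > 0:
        dose_times = np.array([e.time for e in schedule.events], dtype=float)

    def conc(t: float) -> float:
        return 0.0 if schedule is None else schedule.concentration(t)

    t_end = float(t_grid[-1])
    # segment boundaries: dose times inside (0, t_end)
    cuts = np.unique(dose_times[(dose_times > 0.0) & (dose_times < t_end)])
    seg_edges = np.concatenate(([0.0], cuts, [t_end]))

    out_V = np.empty_like(t_grid)
    out_Rn = np.empty_like(t_grid)

    V_now = params.V0
    Rn_now = 0.0 if V_now <= V_c else solve_necrotic_radius(radius_from_volume(V_now), params.R_c)
    switch_up = V_c * (1.0 + ONSET_DELTA)  # engage the limited phase strictly above onset

    written = np.zeros(len(t_grid), dtype=bool)
    if t_grid[0] == 0.0:
        out_V[0], out_Rn[0] = V_now, Rn_now
        written[0] = True

    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        if b <= a:
            continue
        t0 = a
        while t0 < b - 1e-13:
            limited = V_now > switch_up or Rn_now > 0.0

            if method == "dae":

                def rhs(t, y):
                    V = y[0]
                    G = growth_fraction_vec(V, params.R_c) if V > V_c else 1.0
                    return [_drift(V, float(G), params, conc(t))]

                y0 = [V_now]
            elif limited:

                def rhs(t, y):
                    V, Rn = y
                    R = radius_from_volume(V)
                    Rn = min(max(Rn, 0.0), R * (1.0 - 1e-12))
                    G = 1.0 - (Rn / R) ** 3
                    dV = _drift(V, G, params, conc(t))
                    dR = dV / (4.0 * np.pi * R * R)
                    F_R = 2.0 * R - 2.0 * Rn**3 / (R * R)
                    F_Rn = -6.0 * Rn + 6.0 * Rn * Rn / R
                    dRn = -F_R * dR / F_Rn if F_Rn != 0.0 else 0.0
                    return [dV, dRn]

                y0 = [V_now, Rn_now]
            else:

                def rhs(t, y):
                    return [_drift(y[0], 1.0, params, conc(t))]

                y0 = [V_now]

            events = []
            if method == "ode":
                if limited:
                    # leaving the limited phase: V falls back to V_c
                    def ev_down(t, y):
                        return y[0] - V_c

                    ev_down.terminal = True
                    ev_down.direction = -1
                    events.append(ev_down)
                else:
                    # entering the limited phase
                    def ev_up(t, y):
                        return y[0] - switch_up

                    ev_up.terminal = True
                    ev_up.direction = 1
                    events.append(ev_up)

            mask = (t_grid > t0 + 1e-13) & (t_grid <= b + 1e-13) & ~written
            # always evaluate the segment end: it is the restart state
            t_eval = np.unique(np.append(t_grid[mask], b))
            sol = solve_ivp(
                rhs,
                (t0, b),
                y0,
                method="LSODA",
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
                events=events or None,
                dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(f"integration failed at t={sol.t[-1] if len(sol.t) else t0}: {sol.message}")

            # record any requested outputs the solver reached (sol.y is an
            # empty list when an event fires before the first output time)
            ys = np.asarray(sol.y)
            if ys.size:
                for tt, yv in zip(sol.t, ys.T):
                    j = int(np.searchsorted(t_grid, tt))
                    if j < len(t_grid) and abs(t_grid[j] - tt) < 1e-9 and not written[j]:
                        V_j = float(yv[0])
                        if method == "dae":
                            Rn_j = (
                                0.0
                                if V_j <= V_c
                                else radius_from_volume(V_j) * float(core_ratio((V_c / V_j) ** (2.0 / 3.0)))
                            )
                        else:
                            Rn_j = float(yv[1]) if limited else 0.0
                        out_V[j], out_Rn[j] = V_j, max(Rn_j, 0.0)
                        written[j] = True

            if sol.status == 1:  # phase-switch event fired
                t0 = float(sol.t_events[0][0])
                V_now = float(sol.y_events[0][0][0])
                if limited and method == "ode":
                    V_now = min(V_now, V_c)
                    Rn_now = 0.0
                else:
                    Rn_now = solve_necrotic_radius(radius_from_volume(V_now), params.R_c) if V_now > V_c else 0.0
            else:
                t0 = b
                V_now = float(sol.y[0, -1])
                if method == "dae":
                    Rn_now = (
                        0.0
                        if V_now <= V_c
                        else radius_from_volume(V_now) * float(core_ratio((V_c / V_now) ** (2.0 / 3.0)))
                    )
                elif limited:
                    Rn_now = max(float(sol.y[1, -1]), 0.0)
                else:
                    Rn_now = 0.0

    if not written.all():
        # end points exactly at segment edges can be missed by t_eval masks
        for j in np.nonzero(~written)[0]:
            out_V[j], out_Rn[j] = V_now, Rn_now
            written[j] = True

    R_out = radius_from_volume(out_V)
    G_out = 1.0 - (out_Rn / R_out) ** 3
    return Trajectory(t=t_grid.copy(), V=out_V, G=np.clip(G_out, 0.0, 1.0), R_n=out_Rn)
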