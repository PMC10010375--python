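"""Dose schedules and the single-exponential plasma concentration model.

Doses are idealized as instantaneous boluses: each dose event raises the
plasma concentration by the administered amount (mg/kg), which then decays
exponentially with rate ``k_elim`` (day^-1).  For CPT-11 (Irinotecan), a
12-hour half-life gives ``k_elim = ln 2 / 0.5 ≈ 1.386 day^-1``.
Concentrations superpose linearly over doses and are right-continuous at
dose times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseEvent",
    "DoseSchedule",
    "decay_rate_from_half_life",
    "half_life_from_decay_rate",
    "weekly_protocol",
    "PROTOCOL_DOSE_DAYS",
]

#: dosing days of the three CDX treatment protocols (50 mg/kg CPT-11 weekly)
PROTOCOL_DOSE_DAYS = {1: (1.0, 8.0, 15.0), 2: (1.0, 8.0, 15.0, 22.0), 3: (4.0, 11.0, 18.0, 25.0)}

#: Irinotecan plasma half-life in days (12 hours)
CPT11_HALF_LIFE_DAYS = 0.5


def decay_rate_from_half_life(t_half: float) -> float:
    """Exponential decay rate (day^-1) from a half-life (days): ``ln 2 / t_half``."""
    if t_half <= 0.0:
        raise ValueError(f"half-life must be positive, got {t_half!r}")
    return float(np.log(2.0) / t_half)


def half_life_from_decay_rate(k_elim: float) -> float:
    """Half-life (days) from a decay rate (day^-1); inverse of :func:`decay_rate_from_half_life`."""
    if k_elim <= 0.0:
        raise ValueError(f"decay rate must be positive, got {k_elim!r}")
    return float(np.log(2.0) / k_elim)


@dataclass(frozen=True)
class DoseEvent:
    """A bolus dose: ``time`` in days (>= 0), ``amount`` in mg/kg (>= 0)."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0.0:
            raise ValueError(f"dose time must be non-negative, got {self.time!r}")
        if self.amount < 0.0:
            raise ValueError(f"dose amount must be non-negative, got {self.amount!r}")


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered dose events plus the exponential elimination rate.

    ``concentration(t)`` superposes the decayed contributions of all doses
    administered at or before ``t``.
    """

    events: tuple[DoseEvent, ...] = field(default_factory=tuple)
    k_elim: float = decay_rate_from_half_life(CPT11_HALF_LIFE_DAYS)

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)
        if self.k_elim <= 0.0:
            raise ValueError(f"k_elim must be positive, got {self.k_elim!r}")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def amounts(self) -> np.ndarray:
        return np.array([e.amount for e in self.events], dtype=float)

    def concentration(self, t, *, before_dose: bool = False):
        """Plasma concentration (mg/kg) at time(s) ``t`` (days).

        Right-continuous at dose times; with ``before_dose=True`` the
        left limit is returned instead (the carry-over just before a
        dose is administered).
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.events) == 0:
            out = np.zeros_like(t_arr)
        else:
            dt = t_arr[:, None] - self.times[None, :]
            if before_dose:
                active = dt > 0.0
            else:
                active = dt >= 0.0
            out = np.sum(np.where(active, self.amounts[None, :] * np.exp(-self.k_elim * np.where(active, dt, 0.0)), 0.0), axis=1)
        return float(out[0]) if np.ndim(t) == 0 else out

    def merged(self, other: "DoseSchedule") -> "DoseSchedule":
        """Union of two schedules sharing an elimination rate (concentrations add)."""
        if not np.isclose(self.k_elim, other.k_elim):
            raise ValueError("cannot merge schedules with different elimination rates")
        return DoseSchedule(events=self.events + other.events, k_elim=self.k_elim)


def weekly_protocol(protocol: int, dose: float = 50.0, k_elim: float | None = None) -> DoseSchedule:
    """One of the three CDX dosing protocols as a :class:`DoseSchedule`.

    Protocol 1 doses on days 1, 8, 15; protocol 2 on days 1, 8, 15, 22;
    protocol 3 on days 4, 11, 18, 25 — all at ``dose`` mg/kg (default 50).
    """
    if protocol not in PROTOCOL_DOSE_DAYS:
        raise ValueError(f"unknown protocol {protocol!r}; expected one of {sorted(PROTOCOL_DOSE_DAYS)}")
    k = decay_rate_from_half_life(CPT11_HALF_LIFE_DAYS) if k_elim is None else k_elim
    return DoseSchedule(events=tuple(DoseEvent(d, dose) for d in PROTOCOL_DOSE_DAYS[protocol]), k_elim=k)
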