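"""Visual predictive checks.

A VPC simulates many replicate cohorts from a fitted population model
under the trial design and, per time bin, compares confidence bands of
the simulated 5th/50th/95th percentiles against the observed percentiles.
Observed percentiles are computed per nominal measurement day and
optionally smoothed with a centered rolling average across adjacent bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDesign, generate_cohort
from .dataset import CohortDataset
from .population import PopulationModel

__all__ = ["VPCResult", "simulate_replicates", "vpc_bands", "observed_percentiles"]

DEFAULT_PERCENTILES = (5.0, 50.0, 95.0)


@dataclass(frozen=True)
class VPCResult:
    """Percentile bands as a tidy table.

    ``table`` columns: bin_time, percentile, lower, mid, upper (the CI of
    that simulated percentile across replicates) and observed (the data
    percentile in the bin; NaN when no data were supplied).
    """

    table: pd.DataFrame
    ci_level: float
    n_replicates: int

    def band(self, percentile: float) -> pd.DataFrame:
        return self.table[self.table["percentile"] == percentile].reset_index(drop=True)


def simulate_replicates(
    pop: PopulationModel,
    design: CohortDesign,
    n_sim: int,
    seed: int = 0,
) -> np.ndarray:
    """Simulate ``n_sim`` replicate cohorts under ``design``.

    Returns an array of shape (n_sim, n_subjects, n_days) of observed
    (noise-bearing) volumes; requires all arms to share measurement days.
    Each replicate uses fresh random-effect draws and residual noise;
    the whole array is reproducible from ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    days = design.arms[0].measurement_days
    if any(a.measurement_days != days for a in design.arms):
        raise ValueError("replicate simulation requires common measurement days across arms")
    out = np.empty((n_sim, design.n_subjects, len(days)))
    for r in range(n_sim):
        cohort = generate_cohort(design, pop, seed=_replicate_seed(seed, r))
        out[r] = np.stack([s.volumes for s in cohort])
    return out


def _replicate_seed(seed: int, r: int) -> int:
    return int(np.random.SeedSequence(entropy=(int(seed), int(r))).generate_state(1)[0] % (2**31 - 1))


def observed_percentiles(
    cohort: CohortDataset,
    bin_times: np.ndarray,
    percentiles=DEFAULT_PERCENTILES,
    rolling_window: int = 1,
) -> pd.DataFrame:
    """Data percentiles per time bin.

    Observations are assigned to the nearest bin time; empty bins are
    filled by interpolation.  ``rolling_window > 1`` applies a centered
    rolling mean across bins — useful when observation times are jittered
    so single bins are sparse, but biased where the growth curve is steep
    (adjacent bins differ in level), hence off by default: binning at the
    nominal measurement days already pools each day's observations.
    """
    bin_times = np.asarray(bin_times, dtype=float)
    t_all = np.concatenate([s.times for s in cohort])
    v_all = np.concatenate([s.volumes for s in cohort])
    idx = np.argmin(np.abs(t_all[:, None] - bin_times[None, :]), axis=1)
    rows = []
    for j, bt in enumerate(bin_times):
        vals = v_all[idx == j]
        rows.append({"bin_time": bt, "n": len(vals), **{f"p{q:g}": (np.percentile(vals, q) if len(vals) else np.nan) for q in percentiles}})
    frame = pd.DataFrame(rows)
    for q in percentiles:
        col = f"p{q:g}"
        frame[col] = frame[col].interpolate(limit_direction="both")  # empty-bin fallback
        if rolling_window > 1:
            frame[col] = frame[col].rolling(rolling_window, center=True, min_periods=1).mean()
    return frame


def vpc_bands(
    replicates: np.ndarray,
    bin_times: np.ndarray,
    percentiles=DEFAULT_PERCENTILES,
    ci_level: float = 0.95,
    observed: CohortDataset | None = None,
    rolling_window: int = 1,
) -> VPCResult:
    """Confidence bands of simulated percentiles, optionally with data overlay.

    Per time bin each percentile is computed within each replicate (across
    its subjects); the band is the ``ci_level`` interval of that statistic
    across replicates, and ``mid`` its median.  Ordering invariants
    (5th <= 50th <= 95th, lower <= mid <= upper) hold by construction.
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.ndim != 3:
        raise ValueError("replicates must have shape (n_sim, n_subjects, n_bins)")
    bin_times = np.asarray(bin_times, dtype=float)
    if replicates.shape[2] != len(bin_times):
        raise ValueError("bin_times length must match the replicate time axis")
    percentiles = tuple(float(q) for q in percentiles)
    alpha = 100.0 * (1.0 - ci_level) / 2.0

    obs_frame = (
        observed_percentiles(observed, bin_times, percentiles, rolling_window) if observed is not None else None
    )

    rows = []
    for q in percentiles:
        stat = np.percentile(replicates, q, axis=1)  # (n_sim, n_bins)
        lower = np.percentile(stat, alpha, axis=0)
        mid = np.percentile(stat, 50.0, axis=0)
        upper = np.percentile(stat, 100.0 - alpha, axis=0)
        for j, bt in enumerate(bin_times):
            rows.append(
                {
                    "bin_time": bt,
                    "percentile": q,
                    "lower": lower[j],
                    "mid": mid[j],
                    "upper": upper[j],
                    "observed": (obs_frame.loc[j, f"p{q:g}"] if obs_frame is not None else np.nan),
                }
            )
    return VPCResult(table=pd.DataFrame(rows), ci_level=ci_level, n_replicates=replicates.shape[0])
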