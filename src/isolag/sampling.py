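"""Georeference dated hair segments against a trajectory and an isoscape.

For each segment window (optionally shifted back in time by a candidate lag),
the environmental δ³⁴S is the arithmetic mean of the isoscape value at every
GPS fix falling in the half-open window.  Fixes outside the raster extent or
on nodata cells are excluded from both the numerator and the count; a segment
with no contributing fixes is dropped upstream.  Coverage is always judged
*after* the lag shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import SegmentWindow, date_segments, segment_bounds_ns
from .io import HairRecord, IsoScape, Trajectory

__all__ = [
    "SegmentObservation",
    "TrajectoryCache",
    "shift_window",
    "segment_env_mean",
    "build_observations",
]

_DAY_NS = 86_400_000_000_000  # pandas timestamps count nanoseconds


@dataclass(frozen=True)
class SegmentObservation:
    """One regression point: a hair segment's measured δ³⁴S paired with the
    mean environmental δ³⁴S over its (lag-shifted) growth window."""

    animal_id: str
    segment_index: int
    hair_d34S: float
    env_d34S: float
    n_fixes: int


def shift_window(window: SegmentWindow, lag_days: float) -> SegmentWindow:
    """Move a segment window earlier by ``lag_days``, preserving its duration.

    This asks "where was the animal ``lag_days`` before this hair grew" —
    the ingestion window whose isotopic signal the segment records.
    """
    if lag_days < 0:
        raise ValueError("lag must be non-negative")
    delta = pd.Timedelta(days=float(lag_days))
    return SegmentWindow(
        segment_index=window.segment_index,
        t_start=window.t_start - delta,
        t_end=window.t_end - delta,
    )


class TrajectoryCache:
    """Per-trajectory precomputation for fast windowed isoscape means.

    The isoscape value at each fix does not depend on the candidate lag or on
    the assumed growth rate, so it is sampled once; windowed means over the
    sorted fix times then cost two binary searches via prefix sums (nodata
    fixes contribute zero weight).
    """

    def __init__(self, traj: Trajectory, scape: IsoScape):
        self.animal_id = traj.animal_id
        self.times_ns = traj.times.asi8  # sorted by Trajectory invariant
        vals = scape.sample(traj.x, traj.y)
        valid = np.isfinite(vals)
        self._cum_val = np.concatenate([[0.0], np.cumsum(np.where(valid, vals, 0.0))])
        self._cum_n = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
        self.fix_values = vals
        self.t_first_ns = int(self.times_ns[0])

    def window_means(self, starts_ns: np.ndarray,
                     ends_ns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mean isoscape value and contributing fix count per ``[start, end)``."""
        i = np.searchsorted(self.times_ns, starts_ns, side="left")
        j = np.searchsorted(self.times_ns, ends_ns, side="left")
        n = self._cum_n[j] - self._cum_n[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (self._cum_val[j] - self._cum_val[i]) / n
        return means, n


def segment_env_mean(traj: Trajectory, window: SegmentWindow,
                     scape: IsoScape) -> tuple[float, int]:
    """Mean isoscape δ³⁴S over all fixes in ``[t_start, t_end)``.

    Returns ``(mean, n_fixes)``; ``n_fixes = 0`` (with NaN mean) signals an
    uncovered segment for the caller to drop.
    """
    mask = (traj.times >= window.t_start) & (traj.times < window.t_end)
    vals = scape.sample(traj.x[mask], traj.y[mask])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def build_observations(hair: HairRecord, traj: Trajectory, scape: IsoScape,
                       rate: float, lag_days: float,
                       cache: TrajectoryCache | None = None,
                       warn_on_drop: bool = True) -> list[SegmentObservation]:
    """Pair every hair segment with its lag-shifted environmental mean.

    Segments whose shifted window contains no usable fix (before the first
    fix, after the last, or entirely on nodata cells) are dropped; the drop
    count is reported as a warning.  The hair record must carry measured
    segment values.
    """
    if hair.segments is None:
        raise ValueError(f"{hair.animal_id}: hair record has no segment δ³⁴S values")
    if len(traj) == 0:  # unreachable via Trajectory invariant; belt-and-braces
        raise ValueError(f"{traj.animal_id}: empty trajectory")
    if lag_days < 0:
        raise ValueError("lag must be non-negative")
    if cache is None:
        cache = TrajectoryCache(traj, scape)

    windows = date_segments(hair, rate)
    starts, ends = segment_bounds_ns(
        pd.Timestamp(hair.end_date).value, hair.n_segments, rate, lag_days
    )
    means, n = cache.window_means(starts, ends)

    obs = [
        SegmentObservation(
            animal_id=hair.animal_id,
            segment_index=w.segment_index,
            hair_d34S=float(hair.segments[w.segment_index]),
            env_d34S=float(means[k]),
            n_fixes=int(n[k]),
        )
        for k, w in enumerate(windows)
        if n[k] >= 1
    ]
    dropped = len(windows) - len(obs)
    if dropped and warn_on_drop:
        warnings.warn(
            f"{hair.animal_id}: dropped {dropped}/{len(windows)} segments with no "
            f"GPS coverage at lag {lag_days} d",
            stacklevel=2,
        )
    return obs
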