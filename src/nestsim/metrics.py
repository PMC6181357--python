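"""Summary metrics over annual trajectories.

All metrics are pure functions of the trajectory frame: period means use the
annual year-start samples of the window, inclusive at both ends (a 2010-2050
window averages 41 samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, UndefinedGapError
from .simulate import Trajectory

__all__ = [
    "RunSummary",
    "capacity_gap_percent",
    "max_reduction_vs_reference",
    "time_to_capacity",
    "is_extinct",
    "summarize",
    "summary_table",
]

#: Continuous occupancy below this rounds to zero pairs; the deterministic
#: model never reaches exactly 0 from a positive state.
EXTINCTION_THRESHOLD = 0.5


def _window_frame(traj: Trajectory, window: Optional[Tuple[int, int]]) -> pd.DataFrame:
    frame = traj.frame
    if window is None:
        return frame
    lo, hi = window
    out = frame[(frame["year"] >= lo) & (frame["year"] <= hi)]
    if out.empty:
        raise InvalidInputError(f"window {window} does not overlap the trajectory")
    return out


def capacity_gap_percent(
    traj: Trajectory, window: Optional[Tuple[int, int]] = None
) -> float:
    """Percent shortfall of mean occupancy below mean carrying capacity.

    ``100 * (mean(moc) - mean(on)) / mean(moc)`` over the window's annual
    samples.  Negative when occupancy (e.g. a start above capacity) exceeds
    capacity on average.
    """
    frame = _window_frame(traj, window)
    mean_moc = frame["moc"].mean()
    if not mean_moc > 0:
        raise UndefinedGapError("mean carrying capacity over the window is zero")
    return 100.0 * (mean_moc - frame["on"].mean()) / mean_moc


def max_reduction_vs_reference(traj: Trajectory, ref: Trajectory) -> float:
    """Largest annual percent reduction of occupancy versus a reference run.

    ``max over years of 100 * (on_ref - on) / on_ref`` on identical annual
    grids; the reference occupancy must be positive everywhere.
    """
    years = traj.years
    ref_years = ref.years
    if len(years) != len(ref_years) or not np.array_equal(years, ref_years):
        raise InvalidInputError("trajectories are not on the same annual grid")
    on_ref = ref.on
    if np.any(on_ref <= 0):
        raise InvalidInputError("reference occupancy must be positive everywhere")
    return float(np.max(100.0 * (on_ref - traj.on) / on_ref))


def time_to_capacity(traj: Trajectory, fraction: float = 0.99) -> Optional[int]:
    """First year with positive capacity at which occupancy reaches
    ``fraction`` of it; ``None`` if never.

    Zero-capacity years are skipped: reaching 99 % of nothing says nothing
    about recovery.
    """
    frame = traj.frame
    mask = (frame["moc"] > 0) & (frame["on"] >= fraction * frame["moc"])
    hit = frame.loc[mask, "year"]
    return int(hit.iloc[0]) if not hit.empty else None


def is_extinct(traj: Trajectory, threshold: float = EXTINCTION_THRESHOLD) -> bool:
    """Whether final occupancy rounds to zero pairs."""
    return bool(traj.on[-1] < threshold)


@dataclass(frozen=True)
class RunSummary:
    """Window summary of one run (the machine-readable scenario table row)."""

    scenario_id: str
    mean_moc: float
    sd_moc: float
    mean_on: float
    sd_on: float
    gap_percent: Optional[float]
    max_reduction_percent_vs_ref: Optional[float]
    time_to_capacity: Optional[int]
    extinct: bool


def summarize(
    traj: Trajectory,
    ref: Optional[Trajectory] = None,
    window: Optional[Tuple[int, int]] = None,
) -> RunSummary:
    """Compute the summary row for one trajectory (optionally versus an
    unmanaged reference run)."""
    frame = _window_frame(traj, window)
    mean_moc = float(frame["moc"].mean())
    try:
        gap: Optional[float] = capacity_gap_percent(traj, window)
    except UndefinedGapError:
        gap = None
    return RunSummary(
        scenario_id=traj.config.id if traj.config is not None else "",
        mean_moc=mean_moc,
        sd_moc=float(frame["moc"].std(ddof=0)),
        mean_on=float(frame["on"].mean()),
        sd_on=float(frame["on"].std(ddof=0)),
        gap_percent=gap,
        max_reduction_percent_vs_ref=(
            max_reduction_vs_reference(traj, ref) if ref is not None else None
        ),
        time_to_capacity=time_to_capacity(traj),
        extinct=is_extinct(traj),
    )


def summary_table(summaries) -> pd.DataFrame:
    """Stack summary rows into a tidy frame, one row per scenario."""
    return pd.DataFrame([vars(s) for s in summaries])
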