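"""Trajectory/event export, config snapshots, and observed-series utilities.

CSV is the single trajectory format (series are at most a few hundred rows).
A run's JSON config snapshot suffices to re-run it bit-identically: the model
contains no randomness, so byte-equal CSVs are the reproducibility contract.

The synthetic observed-series generator stands in for field monitoring data
(annual counts of occupied nests): a logistic rise with integer rounding and
seeded Gaussian jitter, for exercising trajectory-comparison utilities.  It
is synthetic data, not a reconstruction of any survey.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, InvalidParameterError
from .scenarios import ScenarioConfig
from .simulate import Trajectory

__all__ = [
    "write_trajectory_csv",
    "write_events_csv",
    "write_forest_states_csv",
    "write_config_snapshot",
    "load_config_snapshot",
    "generate_synthetic_observed",
    "compare_to_observed",
]

PathLike = Union[str, Path]


def write_trajectory_csv(traj: Trajectory, path: PathLike) -> Path:
    """Write the annual trajectory as tidy CSV (one row per calendar year,
    state sampled at year start)."""
    path = Path(path)
    traj.frame.to_csv(path, index=False)
    return path


def write_events_csv(traj: Trajectory, path: PathLike) -> Path:
    """Write the clearcut event log (year, areas, mfcr, nests lost)."""
    path = Path(path)
    cols = ["year", "area_cut", "mature_area_before", "mfcr",
            "nests_lost", "tn_before", "tn_after"]
    pd.DataFrame([asdict(e) for e in traj.events], columns=cols).to_csv(
        path, index=False
    )
    return path


def write_forest_states_csv(states, path: PathLike) -> Path:
    """Write yearly forest age distributions as tidy CSV.

    ``states`` is the output of :func:`nestsim.forest.age_distribution_series`:
    pairs of (year, forest).  One row per (year, age_class) with its area.
    """
    path = Path(path)
    rows = [
        (year, age, area)
        for year, forest in states
        for age, area in sorted(forest.areas.items())
    ]
    pd.DataFrame(rows, columns=["year", "age_class", "area_ha"]).to_csv(
        path, index=False
    )
    return path


def write_config_snapshot(config: ScenarioConfig, path: PathLike) -> Path:
    """Write the JSON sidecar from which the run can be reproduced exactly."""
    path = Path(path)
    payload = {
        "config": config.to_dict(),
        "determinism": "the model is deterministic; no seeds are involved",
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_config_snapshot(path: PathLike) -> ScenarioConfig:
    """Rebuild a scenario configuration from its JSON sidecar."""
    payload = json.loads(Path(path).read_text())
    return ScenarioConfig.from_dict(payload["config"])


def generate_synthetic_observed(
    start_year: int = 1991,
    n_years: int = 27,
    capacity: float = 33.0,
    growth_rate: float = 0.15,
    midpoint_year: Optional[int] = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    mean: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Synthetic annual occupied-nest counts: logistic rise plus seeded jitter.

    The expected series is ``capacity / (1 + exp(-growth_rate * (year -
    midpoint_year)))`` (or ``mean`` verbatim when given, e.g. a simulated
    trajectory to perturb).  Counts are the expectation plus Gaussian noise of
    standard deviation ``noise_sd``, rounded to integers and clipped at zero;
    ``noise_sd = 0`` returns the rounded expectation exactly.  Deterministic
    per seed.
    """
    if noise_sd < 0:
        raise InvalidParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    years = np.arange(start_year, start_year + n_years)
    if mean is not None:
        mu = np.asarray(mean, dtype=float)
        if mu.shape != years.shape:
            raise InvalidInputError(
                f"mean series length {mu.size} != n_years {n_years}"
            )
    else:
        mid = midpoint_year if midpoint_year is not None else start_year + n_years // 2
        mu = capacity / (1.0 + np.exp(-growth_rate * (years - mid)))
    rng = np.random.default_rng(seed)
    counts = np.rint(mu + rng.normal(0.0, noise_sd, size=mu.shape)) if noise_sd > 0 else np.rint(mu)
    counts = np.clip(counts, 0, None).astype(int)
    return pd.DataFrame({"year": years, "observed_on": counts})


def compare_to_observed(
    traj: Trajectory, observed: Union[pd.DataFrame, PathLike]
) -> dict:
    """Fit statistics of simulated occupancy against observed annual counts.

    Returns RMSE and mean bias (observed minus simulated) over the
    overlapping years; at least three overlapping years are required.
    """
    if not isinstance(observed, pd.DataFrame):
        observed = pd.read_csv(observed)
    merged = pd.merge(
        traj.frame[["year", "on"]], observed[["year", "observed_on"]], on="year"
    )
    if len(merged) < 3:
        raise InvalidInputError(
            f"only {len(merged)} overlapping years; need at least 3"
        )
    resid = merged["observed_on"].to_numpy(dtype=float) - merged["on"].to_numpy()
    return {
        "n_years": int(len(merged)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "bias": float(np.mean(resid)),
    }
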