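"""Scenario engine: run a configuration to an annual trajectory.

Within each calendar year the two stocks are integrated by explicit Euler at
a fixed substep (``1/dt`` substeps per year) under that year's carrying
capacity.  At each year boundary the forest ages and, in cut years, a
clearcut pulse removes mature cohorts and the corresponding fraction of the
nest stock instantaneously.  State is sampled at year starts, after any
boundary event, together with the instantaneous flows at that state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import ModelParams, _advance, carrying_capacity, clearcut_nest_loss, compute_flows
from .exceptions import InvalidConfigError
from .forest import AgeCohortForest, ForestDriver, equilibrium_distribution
from .scenarios import SEED_AT_FIRST_MATURITY, ScenarioConfig

__all__ = ["Trajectory", "ClearcutRecord", "simulate"]

logger = logging.getLogger(__name__)

#: Column order of the annual trajectory frame.
TRAJECTORY_COLUMNS = [
    "year",
    "tn",
    "on",
    "moc",
    "mature_area",
    "anr",
    "occ_ratio",
    "onir",
    "onar",
    "nb",
    "ndr",
    "nlfc_pulse",
]


@dataclass(frozen=True)
class ClearcutRecord:
    """A logged clearcut pulse: forest removed and nests lost."""

    year: int
    area_cut: float
    mature_area_before: float
    mfcr: float
    nests_lost: float
    tn_before: float
    tn_after: float


@dataclass
class Trajectory:
    """Annual output of one run: a tidy frame plus the event log."""

    frame: pd.DataFrame
    events: List[ClearcutRecord] = field(default_factory=list)
    config: Optional[ScenarioConfig] = None

    @property
    def years(self) -> np.ndarray:
        return self.frame["year"].to_numpy()

    @property
    def on(self) -> np.ndarray:
        return self.frame["on"].to_numpy()

    @property
    def tn(self) -> np.ndarray:
        return self.frame["tn"].to_numpy()

    @property
    def moc(self) -> np.ndarray:
        return self.frame["moc"].to_numpy()

    def at(self, year: int) -> pd.Series:
        rows = self.frame[self.frame["year"] == year]
        if rows.empty:
            raise KeyError(f"year {year} not in trajectory")
        return rows.iloc[0]


def _substeps(dt: float) -> int:
    n = round(1.0 / dt)
    if n < 1 or abs(n * dt - 1.0) > 1e-9:
        raise InvalidConfigError(
            f"dt must divide one year evenly (1/dt integer), got dt={dt}"
        )
    return n


def _initial_forest(config: ScenarioConfig) -> Optional[AgeCohortForest]:
    setup = config.forest
    if setup.plan is not None:
        return equilibrium_distribution(setup.total_area, setup.plan)
    if setup.initial_age is not None:
        if setup.total_area == 0:
            return AgeCohortForest({})
        return AgeCohortForest({setup.initial_age: setup.total_area})
    return None


def simulate(config: ScenarioConfig) -> Trajectory:
    """Run a scenario and return its annual trajectory.

    Deterministic: the same configuration always yields the identical
    trajectory (there is no randomness anywhere in the model).
    """
    params: ModelParams = config.params
    n_sub = _substeps(config.dt)
    dt = config.dt

    initial = _initial_forest(config)
    if initial is None:
        driver = None
        mature = config.forest.total_area
    else:
        driver = ForestDriver(initial, config.forest.plan, params.maturity_age)
        mature = driver.mature()

    on = float(config.initial_on)
    tn = float(config.initial_tn)
    seeded = False
    if config.seeding == SEED_AT_FIRST_MATURITY and mature > 0:
        on = max(on, config.seed_amount)
        tn = max(tn, config.seed_amount)
        seeded = True

    rows = []
    events: List[ClearcutRecord] = []

    def record(year: int, mature_now: float, pulse: float) -> None:
        moc = carrying_capacity(mature_now, params.mfap)
        fl = compute_flows(on, tn, moc, params, nlfc=pulse)
        rows.append(
            (year, tn, on, moc, mature_now, fl.anr, fl.occ_ratio, fl.onir,
             fl.onar, fl.nb, fl.ndr, pulse)
        )

    record(config.t0, mature, 0.0)

    for year in range(config.t0, config.t1):
        moc = carrying_capacity(mature, params.mfap)
        for _ in range(n_sub):
            on, tn = _advance(on, tn, moc, params, dt)
        pulse = 0.0
        if driver is not None:
            event = driver.step_to(year + 1)
            mature = driver.mature()
            if event is not None and event.mfcr > 0.0:
                pulse = clearcut_nest_loss(
                    tn, event.mfcr, config.protection, params.protection_factor
                )
                tn_before = tn
                tn = tn - pulse
                events.append(
                    ClearcutRecord(
                        year=year + 1,
                        area_cut=event.area_cut,
                        mature_area_before=event.mature_area_before,
                        mfcr=event.mfcr,
                        nests_lost=pulse,
                        tn_before=tn_before,
                        tn_after=tn,
                    )
                )
                logger.info(
                    "clearcut %d: %.1f ha cut, mfcr=%.4f, %.3f nests lost",
                    year + 1, event.area_cut, event.mfcr, pulse,
                )
        if (
            config.seeding == SEED_AT_FIRST_MATURITY
            and not seeded
            and mature > 0
        ):
            on = max(on, config.seed_amount)
            tn = max(tn, config.seed_amount)
            seeded = True
            logger.info("seeded %.2f pair(s) at %d (first mature forest)",
                        config.seed_amount, year + 1)
        record(year + 1, mature, pulse)

    frame = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    return Trajectory(frame=frame, events=events, config=config)
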