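"""Age-structured forest submodel.

Forest area is tracked per one-year tree-age class.  The submodel supplies two
quantities to the occupancy dynamics: the mature area (all classes at or above
the nesting maturity age, 34 years by default), which sets carrying capacity,
and the fraction of mature forest removed at each clearcut event, which scales
nest loss.

Two cutting modes are supported:

``cohort-pulse`` (default)
    Every ``cut_interval`` years all area aged >= ``rotation_age`` is clearcut
    in a single pulse and replanted at age 0.  The long-term state under this
    regime is a set of even-aged blocks ``cut_interval`` years apart; capacity
    follows a sawtooth as blocks mature and are cut.

``smoothed-annual``
    An idealisation of a perfectly staggered rotation: each year the single
    oldest cohort (age ``rotation_age``, area ``total/rotation_age``) is cut
    and replanted.  The age distribution is uniform over 1..rotation_age and
    mature area is constant at ``total * (rotation_age - maturity + 1) /
    rotation_age``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

from .exceptions import InvalidParameterError, InvalidPlanError

__all__ = [
    "AgeCohortForest",
    "RotationPlan",
    "ClearcutEvent",
    "equilibrium_distribution",
    "advance_year",
    "apply_clearcut",
    "mature_area",
    "mature_series",
    "age_distribution_series",
]

PULSE = "cohort-pulse"
SMOOTHED = "smoothed-annual"


@dataclass(frozen=True)
class RotationPlan:
    """A clearcut rotation: which tree ages are cut, and how often.

    ``first_cut_year`` only applies in cohort-pulse mode; smoothed-annual
    cutting runs every year by construction.
    """

    rotation_age: int
    cut_interval: int = 10
    first_cut_year: Optional[int] = None
    mode: str = PULSE

    def __post_init__(self) -> None:
        if self.mode not in (PULSE, SMOOTHED):
            raise InvalidPlanError(f"unknown cutting mode {self.mode!r}")
        if self.rotation_age < 1:
            raise InvalidPlanError(f"rotation_age must be >= 1, got {self.rotation_age}")
        if self.cut_interval < 1:
            raise InvalidPlanError(f"cut_interval must be >= 1, got {self.cut_interval}")
        if self.mode == PULSE and self.rotation_age % self.cut_interval != 0:
            raise InvalidPlanError(
                f"cohort-pulse mode needs rotation_age divisible by cut_interval, "
                f"got {self.rotation_age} / {self.cut_interval}"
            )

    def is_cut_year(self, year: int) -> bool:
        if self.mode == SMOOTHED:
            return True
        if self.first_cut_year is None or year < self.first_cut_year:
            return False
        return (year - self.first_cut_year) % self.cut_interval == 0


@dataclass(frozen=True)
class AgeCohortForest:
    """Hectares of forest per integer tree-age class."""

    areas: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for age, area in self.areas.items():
            if age < 0:
                raise InvalidParameterError(f"negative age class {age}")
            if area < 0:
                raise InvalidParameterError(f"negative area {area} in age class {age}")

    @property
    def total_area(self) -> float:
        return sum(self.areas.values())


@dataclass(frozen=True)
class ClearcutEvent:
    """One clearcut pulse: what was removed and how it bears on nests.

    ``mfcr`` is (mature area removed) / (mature area before the cut) — the
    fraction applied to the nest stock — and is 0 when no mature area existed.
    """

    year: int
    area_cut: float
    mature_area_before: float
    mfcr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mfcr <= 1.0:
            raise InvalidParameterError(f"mfcr must lie in [0, 1], got {self.mfcr}")


def equilibrium_distribution(total_area: float, plan: RotationPlan) -> AgeCohortForest:
    """Long-term age distribution under a rotation plan (the post-cut state).

    Cohort-pulse: ``rotation_age / cut_interval`` even-aged blocks of area
    ``total * cut_interval / rotation_age`` at ages 0, I, 2I, ...,
    rotation_age - I.  Smoothed-annual: uniform ``total / rotation_age`` per
    one-year class over ages 1..rotation_age.
    """
    if total_area < 0:
        raise InvalidParameterError(f"total_area must be >= 0, got {total_area}")
    if total_area == 0:
        return AgeCohortForest({})
    if plan.mode == SMOOTHED:
        per = total_area / plan.rotation_age
        return AgeCohortForest({age: per for age in range(1, plan.rotation_age + 1)})
    n_blocks = plan.rotation_age // plan.cut_interval
    per = total_area / n_blocks
    return AgeCohortForest({plan.cut_interval * i: per for i in range(n_blocks)})


def advance_year(forest: AgeCohortForest) -> AgeCohortForest:
    """Age every cohort by one year; area is conserved exactly."""
    return AgeCohortForest({age + 1: area for age, area in forest.areas.items()})


def mature_area(forest: AgeCohortForest, maturity_age: int) -> float:
    """Total area in classes at or above the nesting maturity age."""
    if maturity_age < 0:
        raise InvalidParameterError(f"maturity_age must be >= 0, got {maturity_age}")
    return sum(area for age, area in forest.areas.items() if age >= maturity_age)


def apply_clearcut(
    forest: AgeCohortForest,
    plan: RotationPlan,
    maturity_age: int = 34,
    year: int = 0,
) -> Tuple[AgeCohortForest, ClearcutEvent]:
    """Clearcut all cohorts aged >= ``rotation_age`` and replant them at age 0.

    Returns the post-cut forest and the event record; total area is conserved
    across the event.
    """
    mature_before = mature_area(forest, maturity_age)
    kept = {age: a for age, a in forest.areas.items() if age < plan.rotation_age}
    cut_area = forest.total_area - sum(kept.values())
    cut_mature = sum(
        a
        for age, a in forest.areas.items()
        if age >= plan.rotation_age and age >= maturity_age
    )
    mfcr = cut_mature / mature_before if mature_before > 0 else 0.0
    if cut_area > 0:
        kept[0] = kept.get(0, 0.0) + cut_area
    event = ClearcutEvent(
        year=year,
        area_cut=cut_area,
        mature_area_before=mature_before,
        mfcr=min(mfcr, 1.0),
    )
    return AgeCohortForest(kept), event


class ForestDriver:
    """Yearly evolution of a forest under a plan (or plain aging without one).

    ``step_to(year)`` advances the state across one year boundary and returns
    the clearcut event applied at that boundary, if any.  In cohort-pulse mode
    the boundary order is age-then-cut (a block reaching the rotation age in a
    cut year is cut that year); in smoothed-annual mode it is cut-then-age,
    which keeps the uniform 1..rotation_age distribution exactly periodic with
    period one year.
    """

    def __init__(
        self,
        forest: AgeCohortForest,
        plan: Optional[RotationPlan],
        maturity_age: int,
    ) -> None:
        if plan is not None and plan.rotation_age < maturity_age:
            warnings.warn(
                f"rotation age {plan.rotation_age} below maturity age "
                f"{maturity_age}: the managed forest never supports nesting",
                stacklevel=2,
            )
        self.forest = forest
        self.plan = plan
        self.maturity_age = maturity_age

    def mature(self) -> float:
        return mature_area(self.forest, self.maturity_age)

    def step_to(self, year: int) -> Optional[ClearcutEvent]:
        plan = self.plan
        if plan is not None and plan.mode == SMOOTHED:
            self.forest, event = apply_clearcut(
                self.forest, plan, self.maturity_age, year
            )
            self.forest = advance_year(self.forest)
            return event if event.area_cut > 0 else None
        self.forest = advance_year(self.forest)
        if plan is not None and plan.is_cut_year(year):
            self.forest, event = apply_clearcut(
                self.forest, plan, self.maturity_age, year
            )
            return event
        return None


def age_distribution_series(
    plan: Optional[RotationPlan],
    total_area: float,
    t0: int,
    t1: int,
    maturity_age: int = 34,
    initial: Optional[AgeCohortForest] = None,
) -> List[Tuple[int, AgeCohortForest]]:
    """Yearly forest states (year, age distribution) under a plan.

    Companion to :func:`mature_series` for exporting the full age structure.
    """
    if t0 >= t1:
        raise InvalidParameterError(f"need t0 < t1, got {t0} >= {t1}")
    if plan is None and initial is None:
        raise InvalidParameterError(
            "age_distribution_series needs a rotation plan or an initial forest"
        )
    forest = initial if initial is not None else equilibrium_distribution(total_area, plan)
    driver = ForestDriver(forest, plan, maturity_age)
    out: List[Tuple[int, AgeCohortForest]] = [(t0, driver.forest)]
    for year in range(t0 + 1, t1 + 1):
        driver.step_to(year)
        out.append((year, driver.forest))
    return out


def mature_series(
    plan: Optional[RotationPlan],
    total_area: float,
    t0: int,
    t1: int,
    maturity_age: int = 34,
    initial: Optional[AgeCohortForest] = None,
) -> List[Tuple[int, float, Optional[ClearcutEvent]]]:
    """Annual schedule of (year, mature area, clearcut event at that year).

    With a plan, the forest starts from ``equilibrium_distribution`` (or
    ``initial`` if given) and evolves by aging plus scheduled cuts.  Without a
    plan and without an initial distribution the whole area is treated as
    mature throughout (unmanaged mature landscape).
    """
    if t0 >= t1:
        raise InvalidParameterError(f"need t0 < t1, got {t0} >= {t1}")
    if plan is None and initial is None:
        return [(y, total_area, None) for y in range(t0, t1 + 1)]
    forest = initial if initial is not None else equilibrium_distribution(total_area, plan)
    driver = ForestDriver(forest, plan, maturity_age)
    out: List[Tuple[int, float, Optional[ClearcutEvent]]] = [(t0, driver.mature(), None)]
    for year in range(t0 + 1, t1 + 1):
        event = driver.step_to(year)
        out.append((year, driver.mature(), event))
    return out
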