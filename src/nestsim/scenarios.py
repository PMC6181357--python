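"""Built-in scenario configurations.

Eleven reproducible runs cover the study design:

* ``burete_base`` — historical colonisation of a fully mature 10,000-ha
  landscape from a single breeding pair, 1890-2018.
* ``espuna`` — growth run on a 20,000-ha reforested landscape whose trees are
  all one year old in 1910; one pair is seeded the first year any forest
  reaches nesting maturity (1943 with the default 34-yr maturity).
* ``unmanaged_2010`` — 2010-2050 reference run started at carrying capacity.
* ``cut{40,50,60,70}_{prot,noprot}`` — 2010-2050 managed runs: decadal
  clearcutting of all trees at or above the rotation age, with or without
  nest protection, the forest starting at its long-term rotation equilibrium
  and occupancy at the base run's maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Any, Dict, Optional

import yaml

from .core import DEFAULT_DT, ModelParams, carrying_capacity, equilibrium_total_nests
from .exceptions import InvalidConfigError
from .forest import PULSE, RotationPlan

__all__ = [
    "ForestSetup",
    "ScenarioConfig",
    "build_burete_base",
    "build_espuna_validation",
    "build_unmanaged_2010",
    "build_managed",
    "get_scenario",
    "list_scenarios",
    "SEED_AT_FIRST_MATURITY",
]

SEED_AT_FIRST_MATURITY = "seed-at-first-maturity"

#: Rotation ages exercised in the study design.
STANDARD_ROTATIONS = (40, 50, 60, 70)

_BURETE_AREA_HA = 10_000.0
_ESPUNA_AREA_HA = 20_000.0
_MANAGED_WINDOW = (2010, 2050)
_DEFAULT_FIRST_CUT = 2020


@dataclass(frozen=True)
class ForestSetup:
    """How the landscape's forest is represented in a run.

    * ``plan`` set — managed forest starting at the plan's long-term
      equilibrium age distribution.
    * ``plan`` unset, ``initial_age`` set — unmanaged even-aged forest that
      simply ages (capacity appears once it crosses the maturity age).
    * neither — unmanaged mature landscape: the whole area counts as mature
      habitat throughout.
    """

    total_area: float
    plan: Optional[RotationPlan] = None
    initial_age: Optional[int] = None


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully specified, deterministic run."""

    id: str
    t0: int
    t1: int
    params: ModelParams = field(default_factory=ModelParams)
    forest: ForestSetup = field(default_factory=lambda: ForestSetup(_BURETE_AREA_HA))
    initial_on: float = 0.0
    initial_tn: float = 0.0
    protection: bool = False
    dt: float = DEFAULT_DT
    seeding: str = "none"
    seed_amount: float = 1.0

    def __post_init__(self) -> None:
        if self.t0 >= self.t1:
            raise InvalidConfigError(f"empty time window: t0={self.t0}, t1={self.t1}")
        if not self.dt > 0:
            raise InvalidConfigError(f"dt must be positive, got {self.dt}")
        if self.seeding not in ("none", SEED_AT_FIRST_MATURITY):
            raise InvalidConfigError(f"unknown seeding rule {self.seeding!r}")
        if self.initial_on < 0 or self.initial_tn < 0:
            raise InvalidConfigError("initial stocks must be non-negative")
        if self.initial_on > self.initial_tn:
            warnings.warn(
                f"scenario {self.id!r} starts with more occupied nests "
                f"({self.initial_on}) than total nests ({self.initial_tn})",
                stacklevel=2,
            )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["params"] = asdict(self.params)
        forest: Dict[str, Any] = {"total_area": self.forest.total_area}
        if self.forest.plan is not None:
            forest["plan"] = asdict(self.forest.plan)
        if self.forest.initial_age is not None:
            forest["initial_age"] = self.forest.initial_age
        d["forest"] = forest
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        params = ModelParams(**d.pop("params", {}))
        fdict = dict(d.pop("forest"))
        plan = fdict.pop("plan", None)
        forest = ForestSetup(
            total_area=fdict["total_area"],
            plan=RotationPlan(**plan) if plan is not None else None,
            initial_age=fdict.get("initial_age"),
        )
        return cls(params=params, forest=forest, **d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))

    def with_overrides(self, **kwargs: Any) -> "ScenarioConfig":
        return replace(self, **kwargs)


# -- builders --------------------------------------------------------------


def build_burete_base(params: Optional[ModelParams] = None) -> ScenarioConfig:
    """Historical base run: whole area mature, one pair and one nest in 1890."""
    params = params or ModelParams()
    return ScenarioConfig(
        id="burete_base",
        t0=1890,
        t1=2018,
        params=params,
        forest=ForestSetup(total_area=params.mfa),
        initial_on=1.0,
        initial_tn=1.0,
    )


def build_espuna_validation(
    params: Optional[ModelParams] = None, total_area: float = _ESPUNA_AREA_HA
) -> ScenarioConfig:
    """Reforestation growth run: all trees one year old in 1910; a single pair
    settles the first year the forest reaches nesting maturity."""
    params = params or ModelParams()
    return ScenarioConfig(
        id="espuna",
        t0=1910,
        t1=2018,
        params=params,
        forest=ForestSetup(total_area=total_area, initial_age=1),
        initial_on=0.0,
        initial_tn=0.0,
        seeding=SEED_AT_FIRST_MATURITY,
        seed_amount=1.0,
    )


def build_unmanaged_2010(params: Optional[ModelParams] = None) -> ScenarioConfig:
    """2010-2050 reference: unmanaged mature landscape started at capacity."""
    params = params or ModelParams()
    moc = carrying_capacity(params.mfa, params.mfap)
    return ScenarioConfig(
        id="unmanaged_2010",
        t0=_MANAGED_WINDOW[0],
        t1=_MANAGED_WINDOW[1],
        params=params,
        forest=ForestSetup(total_area=params.mfa),
        initial_on=moc,
        initial_tn=equilibrium_total_nests(moc, params.nbr, params.nlf),
    )


def build_managed(
    rotation_age: int,
    protection: bool,
    params: Optional[ModelParams] = None,
    mode: str = PULSE,
    first_cut_year: int = _DEFAULT_FIRST_CUT,
) -> ScenarioConfig:
    """2010-2050 managed run: decadal clearcutting at ``rotation_age``.

    Initial occupancy is the base run's maximum (the unmanaged carrying
    capacity) and initial total nests its analytic equilibrium; the forest
    starts at the rotation's long-term equilibrium age distribution.
    """
    params = params or ModelParams()
    if rotation_age not in STANDARD_ROTATIONS:
        warnings.warn(
            f"rotation age {rotation_age} is outside the standard set "
            f"{STANDARD_ROTATIONS}",
            stacklevel=2,
        )
    moc = carrying_capacity(params.mfa, params.mfap)
    plan = RotationPlan(
        rotation_age=rotation_age,
        cut_interval=10,
        first_cut_year=first_cut_year,
        mode=mode,
    )
    suffix = "prot" if protection else "noprot"
    return ScenarioConfig(
        id=f"cut{rotation_age}_{suffix}",
        t0=_MANAGED_WINDOW[0],
        t1=_MANAGED_WINDOW[1],
        params=params,
        forest=ForestSetup(total_area=params.mfa, plan=plan),
        initial_on=moc,
        initial_tn=equilibrium_total_nests(moc, params.nbr, params.nlf),
        protection=protection,
    )


_BUILDERS = {
    "burete_base": build_burete_base,
    "espuna": build_espuna_validation,
    "unmanaged_2010": build_unmanaged_2010,
}
for _r in STANDARD_ROTATIONS:
    _BUILDERS[f"cut{_r}_noprot"] = (lambda r: lambda: build_managed(r, False))(_r)
    _BUILDERS[f"cut{_r}_prot"] = (lambda r: lambda: build_managed(r, True))(_r)


def list_scenarios() -> list:
    """Identifiers of the eleven built-in scenarios."""
    return sorted(_BUILDERS)


def get_scenario(scenario_id: str) -> ScenarioConfig:
    """Build a scenario configuration by id."""
    try:
        builder = _BUILDERS[scenario_id]
    except KeyError:
        raise InvalidConfigError(
            f"unknown scenario {scenario_id!r}; known: {', '.join(list_scenarios())}"
        ) from None
    return builder()
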