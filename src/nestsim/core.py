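"""Core stocks and flows of the nest-occupancy model.

The model tracks a community of tree-nesting forest raptors through two
continuous stocks: the total number of nesting platforms in the landscape
(``tn``, occupied or not) and the number of nests occupied by a breeding pair
(``on``; one pair per occupied nest).  Carrying capacity is set by mature
forest: ``moc = mfa / mfap`` pairs, where ``mfa`` is the mature forest area and
``mfap`` the mature area one pair requires.

Occupancy changes through two opposed flows.  Settlement

    ``onir = anr * or * (tn - on) * cr``

is proportional to the unoccupied nest stock ``tn - on`` (nests are reused and
act as settlement cues), to the occupied ratio ``or = on / moc`` (conspecific
attraction: an empty landscape attracts no settlers, which also makes
extinction absorbing), and to the available-capacity ratio
``anr = (moc - on) / moc`` (settlement saturates as the community approaches
capacity).  Both ratio factors are saturating fractions and are evaluated
clamped to [0, 1]; the ``tn - on`` factor keeps its sign, so occupancy is
pulled back down when destruction leaves fewer nests than pairs.  Abandonment

    ``onar = max(0, (on - moc) * cr)``

removes the excess pairs whenever management reduces capacity below current
occupancy.  Nests themselves are built at ``nb = on * nbr`` and decay at
``ndr = tn / nlf``; clearcutting removes ``nlfc = tn * mfcr`` nests as an
instantaneous pulse at each cut event (reduced by the protection factor when
nests are protected by buffer zones).

Integration is explicit Euler with a fixed step ``dt`` (an integer number of
substeps per year); cut pulses are applied between continuous steps at year
boundaries, never inside them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import (
    InvalidEventError,
    InvalidParameterError,
    InvalidStateError,
    NumericalInstabilityError,
)

__all__ = [
    "ModelParams",
    "NestState",
    "FlowRates",
    "carrying_capacity",
    "occupation_increase_rate",
    "abandonment_rate",
    "nest_building_rate",
    "nest_destruction_rate",
    "clearcut_nest_loss",
    "equilibrium_total_nests",
    "compute_flows",
    "step",
]

#: Default explicit-Euler step, in years.  1/256 yr keeps the dt-halving
#: difference of every annual value below 0.1 % of the trajectory scale even
#: through the exponential abandonment phases of zero-capacity years.
DEFAULT_DT = 1.0 / 256.0


@dataclass(frozen=True)
class ModelParams:
    """Community-level parameters.

    Parameters
    ----------
    nbr : float
        Nest building ratio: new nests built per breeding pair per year.
    nlf : float
        Average nest life expectancy in years; nests decay at ``tn / nlf``.
    mfa : float
        Mature forest area in hectares.  Used directly only in runs without a
        forest submodel; managed runs take mature area from the age cohorts.
    mfap : float
        Mature forest required per breeding pair, hectares/pair.
    cr : float
        Change ratio (1/yr): relaxation rate of the occupancy flows.
    protection_factor : float
        Fraction of clearcut nest loss avoided when nests are protected by
        buffer zones (0.9 = 90 % of the loss avoided).
    maturity_age : int
        Minimum tree age (years) at which a stand counts as mature nesting
        habitat.
    """

    nbr: float = 0.14
    nlf: float = 20.68
    mfa: float = 10_000.0
    mfap: float = 300.0
    cr: float = 1.0
    protection_factor: float = 0.9
    maturity_age: int = 34

    def __post_init__(self) -> None:
        for name in ("nbr", "nlf", "mfa", "mfap", "cr", "maturity_age"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}"
                )
        if not 0.0 <= self.protection_factor <= 1.0:
            raise InvalidParameterError(
                f"protection_factor must lie in [0, 1], got {self.protection_factor!r}"
            )


@dataclass(frozen=True)
class NestState:
    """The two stocks at one point in simulated time.

    ``t`` is calendar time in years; ``tn`` and ``on`` are continuous counts
    (the model is an aggregate deterministic one — integers only appear at the
    reporting layer).
    """

    t: float
    tn: float
    on: float

    def __post_init__(self) -> None:
        if self.tn < 0 or self.on < 0:
            raise InvalidStateError(
                f"stocks must be non-negative, got tn={self.tn}, on={self.on}"
            )


@dataclass(frozen=True)
class FlowRates:
    """Instantaneous flows and diagnostics at one state.

    ``nlfc`` is a pulse amount (nests per event), non-zero only at cut years;
    all other flows are rates per year.
    """

    moc: float
    anr: float
    occ_ratio: float
    onir: float
    onar: float
    nb: float
    ndr: float
    nlfc: float = 0.0


def carrying_capacity(mfa: float, mfap: float) -> float:
    """Maximum number of occupied nests supported by ``mfa`` hectares of
    mature forest, ``moc = mfa / mfap`` breeding pairs."""
    if not mfap > 0:
        raise InvalidParameterError(f"mfap must be positive, got {mfap!r}")
    if mfa < 0:
        raise InvalidParameterError(f"mfa must be non-negative, got {mfa!r}")
    return mfa / mfap


def occupation_increase_rate(on: float, tn: float, moc: float, cr: float = 1.0) -> float:
    """Settlement flow ``anr * or * (tn - on) * cr`` in pairs/yr.

    The two ratio factors are clamped to [0, 1]: they are saturating
    fractions, and letting them run negative (or above one) when occupancy
    exceeds capacity would turn settlement into an explosive sink — capacity
    excess is the abandonment flow's job.  With no mature forest
    (``moc = 0``) settlement is zero.
    """
    if on < 0 or tn < 0 or moc < 0:
        raise InvalidStateError(
            f"negative input to occupation rate: on={on}, tn={tn}, moc={moc}"
        )
    if moc == 0:
        return 0.0
    anr = min(max((moc - on) / moc, 0.0), 1.0)
    occ = min(max(on / moc, 0.0), 1.0)
    return anr * occ * (tn - on) * cr


def abandonment_rate(on: float, moc: float, cr: float = 1.0) -> float:
    """Abandonment flow ``max(0, (on - moc) * cr)`` in pairs/yr.

    Active only while occupancy exceeds capacity; the clamp stops the formula
    acting as a spurious growth term below capacity.  With ``moc = 0`` every
    pair is under abandonment pressure (``on * cr``).
    """
    if on < 0 or moc < 0:
        raise InvalidStateError(f"negative input to abandonment rate: on={on}, moc={moc}")
    return max(0.0, (on - moc) * cr)


def nest_building_rate(on: float, nbr: float) -> float:
    """Nest construction ``on * nbr`` in nests/yr."""
    if on < 0:
        raise InvalidStateError(f"on must be non-negative, got {on!r}")
    return on * nbr


def nest_destruction_rate(tn: float, nlf: float) -> float:
    """Natural nest decay ``tn / nlf`` in nests/yr."""
    if not nlf > 0:
        raise InvalidParameterError(f"nlf must be positive, got {nlf!r}")
    if tn < 0:
        raise InvalidStateError(f"tn must be non-negative, got {tn!r}")
    return tn / nlf


def clearcut_nest_loss(
    tn: float,
    mfcr: float,
    protected: bool = False,
    protection_factor: float = 0.9,
) -> float:
    """Nests destroyed by one clearcut event (a pulse, not a rate).

    ``mfcr`` is the fraction of mature forest removed by the event; the same
    fraction of the nest stock is lost, reduced by ``protection_factor`` when
    buffer-zone protection is active.
    """
    if not 0.0 <= mfcr <= 1.0:
        raise InvalidEventError(f"mfcr must lie in [0, 1], got {mfcr!r}")
    if tn < 0:
        raise InvalidStateError(f"tn must be non-negative, got {tn!r}")
    loss = tn * mfcr
    if protected:
        loss *= 1.0 - protection_factor
    return loss


def equilibrium_total_nests(moc: float, nbr: float, nlf: float) -> float:
    """Closed-form total-nest equilibrium ``moc * nbr * nlf``.

    Fixed point of building/destruction with occupancy at capacity: setting
    ``on = moc`` and ``nb = ndr`` gives ``tn = moc * nbr * nlf``.  Used to
    initialise managed scenarios and as the analytic asymptote of unmanaged
    runs.
    """
    if moc < 0:
        raise InvalidStateError(f"moc must be non-negative, got {moc!r}")
    return moc * nbr * nlf


def compute_flows(
    on: float, tn: float, moc: float, params: ModelParams, nlfc: float = 0.0
) -> FlowRates:
    """All instantaneous flows at a state, as reported in trajectories."""
    if moc > 0:
        anr = min(max((moc - on) / moc, 0.0), 1.0)
        occ = min(max(on / moc, 0.0), 1.0)
    else:
        anr = 0.0
        occ = 0.0
    return FlowRates(
        moc=moc,
        anr=anr,
        occ_ratio=occ,
        onir=occupation_increase_rate(on, tn, moc, params.cr),
        onar=abandonment_rate(on, moc, params.cr),
        nb=nest_building_rate(on, params.nbr),
        ndr=nest_destruction_rate(tn, params.nlf),
        nlfc=nlfc,
    )


# Negative overshoot beyond this fraction of the stock (or of 1 nest for tiny
# stocks) indicates the Euler step is too coarse rather than a rounding wiggle.
_CLAMP_TOL_FRACTION = 1e-6


def _advance(on: float, tn: float, moc: float, params: ModelParams, dt: float):
    """One Euler substep on plain floats (no allocation; used by simulate)."""
    if moc > 0:
        anr = (moc - on) / moc
        if anr < 0.0:
            anr = 0.0
        elif anr > 1.0:
            anr = 1.0
        occ = on / moc
        if occ > 1.0:
            occ = 1.0
        onir = anr * occ * (tn - on) * params.cr
        onar = on - moc
        onar = onar * params.cr if onar > 0.0 else 0.0
    else:
        onir = 0.0
        onar = on * params.cr
    new_on = on + (onir - onar) * dt
    new_tn = tn + (on * params.nbr - tn / params.nlf) * dt
    if not (math.isfinite(new_on) and math.isfinite(new_tn)):
        raise NumericalInstabilityError(
            "non-finite stock during Euler step; reduce dt"
        )
    if new_on < -_CLAMP_TOL_FRACTION * max(on, 1.0) or new_tn < -_CLAMP_TOL_FRACTION * max(tn, 1.0):
        raise NumericalInstabilityError(
            f"negative stock overshoot at on={new_on}, tn={new_tn}; reduce dt"
        )
    return (new_on if new_on > 0.0 else 0.0, new_tn if new_tn > 0.0 else 0.0)


def step(state: NestState, params: ModelParams, moc_t: float, dt: float) -> NestState:
    """Advance the stocks by one explicit-Euler step of length ``dt`` years.

    ``moc_t`` is the carrying capacity in force during the step (managed runs
    recompute it yearly from the forest submodel).  Pulse losses are applied
    separately at event times, not inside this continuous update.
    """
    if not dt > 0:
        raise InvalidParameterError(f"dt must be positive, got {dt!r}")
    if moc_t < 0:
        raise InvalidStateError(f"moc must be non-negative, got {moc_t!r}")
    on, tn = _advance(state.on, state.tn, moc_t, params, dt)
    return NestState(t=state.t + dt, tn=tn, on=on)
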