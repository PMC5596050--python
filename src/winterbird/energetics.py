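"""Per-period energy gains, expenditures, and the stochastic fat transition.

Costs are built from the per-period resting metabolism C_rm:

* an active (foraging) bird pays C_rm * (1 + mu + mu * x / x_max) -- three
  times resting for a lean bird, five times for a maximally fat one at the
  baseline mu = 2;
* a resting bird pays C_rm;
* a hypothermic bird at depth y pays C_rm * (1 - epsilon * y / y_max),
  i.e. it saves up to the fraction epsilon of resting expenditure at the
  deepest depth; a rewarming bird additionally pays its per-period share of
  the extra warm-up cost.

Every cost is multiplied by the bad-weather factor gamma whenever the
*coming* period's weather is bad, which ties the expenditure draw to the
weather transition.  Foraging gain is weather-independent: the full gross
gain with probability lambda, a fraction delta of it otherwise (a parid
always finds something in five minutes; how much varies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behaviours as bh
from .config import ModelParams
from .grid import BAD, GOOD
from .thermo import step_hypothermia

__all__ = [
    "Outcome",
    "FatTransition",
    "activity_cost",
    "hypothermic_cost",
    "fat_transition",
]


@dataclass(frozen=True)
class Outcome:
    next_fat: float      #: kJ; may be <= 0 (starvation) and is capped at x_max
    probability: float
    next_weather: int    #: GOOD or BAD
    next_y: float        #: degC


@dataclass(frozen=True)
class FatTransition:
    """The stochastic one-period state transition for one behaviour.

    Four outcomes for foraging behaviours (success x next weather), two for
    the others (weather only).  Probabilities sum to one.
    """

    outcomes: tuple[Outcome, ...]


def activity_cost(
    params: ModelParams, behaviour: int, x, weather: int = GOOD
) -> np.ndarray:
    """Per-period cost (kJ) of a non-hypothermic behaviour at fat load x.

    In good weather this is C_rm * (1 + mu + mu * x / x_max).  Under bad
    weather the resting-metabolism component is multiplied by gamma; under
    the default scope the activity increment is not (movement heat
    substitutes for thermoregulation in the cold), under the
    ``total_cost`` scope the whole cost is.
    """
    if behaviour not in bh.ALL:
        raise ValueError(f"unknown behaviour: {behaviour}")
    if behaviour in (bh.COOL, bh.WARM, bh.HOLD):
        raise ValueError(
            "activity_cost applies to behaviours 1-3; use hypothermic_cost"
        )
    x = np.asarray(x, dtype=float)
    c_rm = params.derived.c_rm_period
    mu = params.mu_forage if behaviour in (bh.FORAGE_HIGH, bh.FORAGE_LOW) else 0.0
    gamma_w = params.bad_weather_multiplier if weather == BAD else 1.0
    activity = mu * c_rm * (1.0 + x / params.x_max)
    if params.bad_weather_scope == "total_cost":
        return (c_rm + activity) * gamma_w
    return c_rm * gamma_w + activity


def hypothermic_cost(
    params: ModelParams, y: float, weather: int, warming: bool = False
) -> float:
    """Per-period cost (kJ) at hypothermic depth y under the given weather.

    ``y`` is the depth at which the period is spent (for depth-changing
    behaviours, the post-change depth).  ``warming`` adds the per-period
    share of the extra rewarming cost.
    """
    if y < 0 or y > params.y_max:
        raise ValueError(f"depth {y} outside [0, y_max]")
    d = params.derived
    gamma_w = params.bad_weather_multiplier if weather == BAD else 1.0
    cost = (d.c_rm_period - params.epsilon * d.c_rm_period * y / params.y_max) * gamma_w
    if warming:
        cost += d.warmup_surcharge
    return cost


def _weather_branches(params: ModelParams, weather: int) -> tuple:
    """((next_weather, probability), ...) given the current weather."""
    if weather == GOOD:
        return ((GOOD, params.p_gg), (BAD, 1.0 - params.p_gg))
    return ((BAD, params.p_bb), (GOOD, 1.0 - params.p_bb))


def fat_transition(
    params: ModelParams,
    behaviour: int,
    x: float,
    y: float,
    weather: int,
    daylight: bool,
) -> FatTransition:
    """Enumerate the one-period outcomes of a behaviour in state (x, y, w).

    Raises for behaviours that are infeasible in the given state (foraging
    at night, foraging while too deep in hypothermia, depth changes outside
    their domain).
    """
    lam = params.success_prob
    outcomes: list[Outcome] = []

    if behaviour in (bh.FORAGE_HIGH, bh.FORAGE_LOW):
        if not daylight:
            raise ValueError("foraging is infeasible at night")
        if y > 0 and y >= params.shallow_forage_limit:
            raise ValueError("foraging is infeasible at this hypothermic depth")
        d = params.derived
        g = d.g_period_high if behaviour == bh.FORAGE_HIGH else d.g_period_low
        for next_w, p_w in _weather_branches(params, weather):
            c = float(activity_cost(params, behaviour, x, weather=next_w))
            for gain, p_s in ((g, lam), (g * params.unsuccessful_gain, 1.0 - lam)):
                outcomes.append(
                    Outcome(min(x + gain - c, params.x_max), p_s * p_w, next_w, y)
                )
    elif behaviour == bh.REST:
        if y != 0:
            raise ValueError("resting requires normothermia")
        for next_w, p_w in _weather_branches(params, weather):
            c = float(activity_cost(params, behaviour, x, weather=next_w))
            outcomes.append(Outcome(min(x - c, params.x_max), p_w, next_w, y))
    elif behaviour in (bh.COOL, bh.WARM, bh.HOLD):
        y_next = step_hypothermia(params, y, behaviour)
        warming = behaviour == bh.WARM
        for next_w, p_w in _weather_branches(params, weather):
            c = hypothermic_cost(params, y_next, next_w, warming=warming)
            outcomes.append(Outcome(min(x - c, params.x_max), p_w, next_w, y_next))
    else:
        raise ValueError(f"unknown behaviour: {behaviour}")

    return FatTransition(outcomes=tuple(outcomes))
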