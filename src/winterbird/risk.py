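"""Per-period predation hazards.

Three ingredients, combined per behaviour and time of day:

* an activity-dependent baseline (intensive foraging > cautious foraging >
  resting in safety), converted from the tabulated daily values to
  per-period hazards by compounding;
* a mass-dependent acceleration for active (non-hypothermic) birds in
  daylight: above a critical fat load x_cr the hazard is multiplied by
  1 + ((x - x_cr) / x_cr)**alpha, reflecting lost agility;
* hypothermia: a lethargic bird in daylight is conspicuous and slow, so the
  baseline day-time hazard for behaviours 4-6 is high and constant
  (variants: growing linearly with depth on top of the resting hazard, or
  equal to the resting hazard).  At night, hypothermic sleep carries a
  higher hazard than normothermic sleep -- a sleeping normothermic bird can
  still flee a nest-box predator, a torpid one often cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import behaviours as bh
from .config import ModelParams

__all__ = ["RiskModel", "build_risk_model", "mass_multiplier", "predation_hazard"]


@dataclass(frozen=True)
class RiskModel:
    beta_forage_high: float   #: per daylight period, lean bird
    beta_forage_low: float
    beta_rest_day: float
    beta_rest_night: float
    beta_hypo_day: float      #: per daylight period, hypothermic bird
    beta_hypo_night: float    #: per night period, hypothermic bird
    x_cr: float
    alpha_exp: float
    y_max: float
    mode: str                 #: day-time hypothermia risk variant


def build_risk_model(params: ModelParams) -> RiskModel:
    d = params.derived
    return RiskModel(
        beta_forage_high=d.beta_forage_high_p,
        beta_forage_low=d.beta_forage_low_p,
        beta_rest_day=d.beta_rest_day_p,
        beta_rest_night=d.beta_rest_night_p,
        beta_hypo_day=d.beta_hypo_day_p,
        beta_hypo_night=d.beta_hypo_night_p,
        x_cr=params.x_cr,
        alpha_exp=params.alpha_exp,
        y_max=params.y_max,
        mode=params.daytime_hypo_risk_mode,
    )


def mass_multiplier(risk: RiskModel, x) -> np.ndarray:
    """Accelerating mass factor: 1 below x_cr, 1 + ((x-x_cr)/x_cr)**alpha above."""
    x = np.asarray(x, dtype=float)
    excess = np.clip((x - risk.x_cr) / risk.x_cr, 0.0, None)
    return 1.0 + excess**risk.alpha_exp


def predation_hazard(
    risk: RiskModel,
    behaviour: int,
    x,
    y,
    daylight: bool,
):
    """Per-period predation hazard for a behaviour in state (x, y).

    ``x`` (kJ) and ``y`` (degC) broadcast; for the depth-changing behaviours
    ``y`` is the post-change depth, consistent with how the solver prices
    the period.  Foraging hazards are only defined in daylight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if behaviour in (bh.FORAGE_HIGH, bh.FORAGE_LOW):
        if not daylight:
            raise ValueError("foraging hazard is undefined at night")
        base = (
            risk.beta_forage_high
            if behaviour == bh.FORAGE_HIGH
            else risk.beta_forage_low
        )
        return base * mass_multiplier(risk, x)
    if behaviour == bh.REST:
        if daylight:
            return risk.beta_rest_day * mass_multiplier(risk, x)
        return np.broadcast_to(
            np.asarray(risk.beta_rest_night), np.broadcast(x, y).shape
        ).copy()
    if behaviour in (bh.COOL, bh.WARM, bh.HOLD):
        if not daylight:
            return np.broadcast_to(
                np.asarray(risk.beta_hypo_night), np.broadcast(x, y).shape
            ).copy()
        if risk.mode == "constant_high":
            return np.broadcast_to(
                np.asarray(risk.beta_hypo_day), np.broadcast(x, y).shape
            ).copy()
        rest = risk.beta_rest_day * mass_multiplier(risk, x)
        if risk.mode == "safe_as_rest":
            return np.broadcast_to(rest, np.broadcast(x, y).shape).copy()
        # linear_in_depth: resting hazard plus a depth-proportional share of
        # the high day-time hypothermia hazard
        return rest + (y / risk.y_max) * risk.beta_hypo_day
    raise ValueError(f"unknown behaviour: {behaviour}")
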