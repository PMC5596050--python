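"""Hypothermia state dynamics and the rewarming fat requirement.

Depth changes at a fixed per-period rate: a full transit of the y range
(normothermic to deepest hypothermia, or back) takes ``n_warmup_periods``
periods (6 at baseline, i.e. 30 min), which is the rate at which small
parids cool at dusk and rewarm before dawn.  Cooling and rewarming are
symmetric.

Because the presentation grid for y (n_hypo_steps intervals) need not be
divisible by n_warmup_periods, transitions follow a "ladder" of grid nodes
at the rounded positions k * n_hypo_steps / n_warmup_periods: transitions
land exactly on grid nodes, a down-step followed by an up-step returns to
the same ladder node, and a full transit takes exactly n_warmup_periods
periods.  Energetically only the saving fraction epsilon * y / y_max
matters, so the ladder's sub-degree rounding is irrelevant to the model's
predictions; the degC axis is presentation.
"""

from __future__ import annotations

import math

import numpy as np

from . import behaviours as bh
from .config import ModelParams

__all__ = [
    "depth_ladder",
    "down_map",
    "up_map",
    "step_hypothermia",
    "n_rewarm_periods",
    "warmup_fat_requirement",
]


def depth_ladder(params: ModelParams) -> np.ndarray:
    """Grid indices of the reachable hypothermia depths (the "ladder")."""
    steps = np.rint(
        np.linspace(0, params.n_hypo_steps, params.n_warmup_periods + 1)
    ).astype(np.int64)
    return np.unique(steps)


def down_map(params: ModelParams) -> np.ndarray:
    """Next grid index when deepening, for every current index.

    On-ladder indices move one rung down the ladder; off-ladder indices
    (unreachable from a normothermic start) move to the nearest ladder node
    in the deepening direction.  The deepest index maps to itself (deepening
    there is infeasible and masked out by the solver).
    """
    ladder = depth_ladder(params)
    n = params.n_hypo_steps
    out = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        deeper = ladder[ladder > j]
        out[j] = deeper[0] if len(deeper) else n
    return out


def up_map(params: ModelParams) -> np.ndarray:
    """Next grid index when rewarming; index 0 maps to itself.

    The bird can never overshoot normothermia: the rewarming step is
    min(step, current depth).
    """
    ladder = depth_ladder(params)
    n = params.n_hypo_steps
    out = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        shallower = ladder[ladder < j]
        out[j] = shallower[-1] if len(shallower) else 0
    return out


def _index_of(params: ModelParams, y: float) -> int:
    step = params.y_max / params.n_hypo_steps
    idx = y / step
    j = int(round(idx))
    if not math.isclose(idx, j, abs_tol=1e-9):
        raise ValueError(f"hypothermia depth {y} degC is not a grid node")
    if not 0 <= j <= params.n_hypo_steps:
        raise ValueError(f"hypothermia depth {y} degC outside [0, y_max]")
    return j


def step_hypothermia(params: ModelParams, y: float, behaviour: int) -> float:
    """Depth (degC) after one period of behaviour 4 (cool), 5 (warm) or
    6 (hold), starting from grid-node depth ``y``.

    Feasibility: cooling requires y < y_max; warming and holding require
    y > 0 (the model's convention; at y = 0 "rest" plays that role).
    """
    j = _index_of(params, y)
    step = params.y_max / params.n_hypo_steps
    if behaviour == bh.COOL:
        if j >= params.n_hypo_steps:
            raise ValueError("cannot deepen hypothermia at maximal depth")
        return float(down_map(params)[j]) * step
    if behaviour == bh.WARM:
        if j == 0:
            raise ValueError("cannot rewarm a normothermic bird")
        return float(up_map(params)[j]) * step
    if behaviour == bh.HOLD:
        if j == 0:
            raise ValueError("cannot hold hypothermia at normothermia")
        return y
    raise ValueError(f"behaviour {behaviour} does not change depth")


def n_rewarm_periods(params: ModelParams, y: float) -> int:
    """Number of periods needed to rewarm from depth ``y`` to normothermia."""
    j = _index_of(params, y)
    up = up_map(params)
    count = 0
    while j > 0:
        j = int(up[j])
        count += 1
    return count


def warmup_fat_requirement(params: ModelParams, y: float) -> float:
    """Fat (kJ) a bird at depth ``y`` needs in order to rewarm.

    The requirement is the pro-rated share of the extra rewarming cost,
    (y / y_max) * warmup_cost, plus the resting cost of the rewarming
    periods themselves.  A normothermic bird needs nothing.
    """
    if y == 0:
        return 0.0
    c_rm = params.derived.c_rm_period
    return (y / params.y_max) * params.warmup_cost + n_rewarm_periods(
        params, y
    ) * c_rm
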