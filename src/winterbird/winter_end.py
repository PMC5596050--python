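"""Terminal reward and the uncertain end-of-winter window.

Winter lasts n_days days but its exact end is unknown to the bird: it can
end on the morning after any of the last (n_days - t_f_day + 1) nights,
i.e. at one of the candidate daybreaks of days t_f_day+1 .. n_days+1 (the
final daybreak, after the appended post-midnight periods, is the last
candidate and the final period T of the model).  The per-candidate end
hazard 1 / (candidates remaining) makes the end day exactly uniform over
the window.

When winter ends the bird is rewarded 1 (survived) if it is alive and
carries at least the fat needed to rewarm from its current hypothermic
depth, else 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelParams
from .grid import StateGrid
from .thermo import warmup_fat_requirement

__all__ = [
    "TerminalModel",
    "build_terminal_model",
    "end_probability",
    "daybreak_end_probability",
    "terminal_reward",
    "terminal_reward_array",
]


@dataclass(frozen=True)
class TerminalModel:
    t_f: int                       #: first period of the end window
    t_last: int                    #: final period T (a daybreak)
    candidate_daybreaks: np.ndarray  #: ascending absolute periods


def build_terminal_model(params: ModelParams, grid: StateGrid) -> TerminalModel:
    ppd = params.periods_per_day
    t_f = (params.t_f_day - 1) * ppd
    t_last = grid.n_periods_total
    first_end_day = params.t_f_day + 1
    candidates = np.array(
        [
            (d - 1) * ppd + params.daylight_start
            for d in range(first_end_day, params.n_days + 2)
        ],
        dtype=np.int64,
    )
    assert candidates[-1] == t_last
    return TerminalModel(
        t_f=t_f, t_last=t_last, candidate_daybreaks=candidates
    )


def end_probability(tm: TerminalModel, t: int) -> float:
    """Literal per-period end hazard 1 / ((T + 1) - t) inside the window.

    This is the raw uniform-end hazard; the solver applies its daybreak
    counterpart :func:`daybreak_end_probability`, because the terminal
    reward can only be collected at a daybreak.
    """
    if t < tm.t_f or t > tm.t_last:
        return 0.0
    return 1.0 / ((tm.t_last + 1) - t)


def daybreak_end_probability(tm: TerminalModel, t: int) -> float:
    """End hazard at a candidate daybreak: 1 / (candidates remaining).

    Zero off the candidate daybreaks.  Sequential application yields a
    uniform end distribution over all candidates.
    """
    pos = np.searchsorted(tm.candidate_daybreaks, t)
    if pos >= len(tm.candidate_daybreaks) or tm.candidate_daybreaks[pos] != t:
        return 0.0
    remaining = len(tm.candidate_daybreaks) - pos
    return 1.0 / remaining


def terminal_reward(
    tm: TerminalModel,
    params: ModelParams,
    x: float,
    y: float,
    t: int,
) -> float:
    """1 if a bird in state (x, y) survives a winter ending at period t.

    Requires t to be a candidate daybreak, the bird not to have starved
    (x > 0) and to carry the fat needed to rewarm from depth y.
    """
    if daybreak_end_probability(tm, t) == 0.0:
        return 0.0
    if x <= 0.0:
        return 0.0
    return 1.0 if x >= warmup_fat_requirement(params, y) else 0.0


def terminal_reward_array(
    tm: TerminalModel, params: ModelParams, grid: StateGrid
) -> np.ndarray:
    """Terminal reward on the (fat, hypo) lattice, shape (n_fat+1, n_hypo+1)."""
    xc = np.array(
        [warmup_fat_requirement(params, y) for y in grid.hypo_values]
    )
    phi = (grid.fat_values[:, None] >= xc[None, :]).astype(float)
    phi[0, :] = 0.0  # x = 0 is starvation
    return phi
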