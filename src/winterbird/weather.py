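"""Two-state Markov weather chain (good / bad).

The only effect of bad weather is a multiplicative increase of energy
expenditure; the chain exists to make the environment unpredictable.  Good
weather is the more persistent (hence more common) state: at the baseline
per-period persistences 0.9983 / 0.9965 a good spell survives 24 h with
probability 0.613 and a bad spell with probability 0.364.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import BAD, GOOD

__all__ = ["WeatherChain", "persistence_probability", "sample_path"]


@dataclass(frozen=True)
class WeatherChain:
    p_gg: float   #: per-period probability that good weather persists
    p_bb: float   #: per-period probability that bad weather persists

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic matrix over (good, bad)."""
        return np.array(
            [[self.p_gg, 1.0 - self.p_gg], [1.0 - self.p_bb, self.p_bb]]
        )

    def stationary(self) -> np.ndarray:
        """Long-run (good, bad) occupancy of the ergodic chain."""
        leave_g = 1.0 - self.p_gg
        leave_b = 1.0 - self.p_bb
        total = leave_g + leave_b
        return np.array([leave_b / total, leave_g / total])


def persistence_probability(
    chain: WeatherChain, state: int, n_periods: int
) -> float:
    """Probability that the current weather lasts ``n_periods`` more periods."""
    if n_periods < 0:
        raise ValueError("n_periods must be non-negative")
    p = chain.p_gg if state == GOOD else chain.p_bb
    return p**n_periods

def sample_path(
    chain: WeatherChain,
    start: int,
    n_periods: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """A realised weather sequence of length ``n_periods`` from ``start``.

    ``rng`` may be a Generator or an integer seed; a given seed always
    yields the same path.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    u = rng.random(n_periods)
    path = np.empty(n_periods, dtype=np.int8)
    state = start
    for i in range(n_periods):
        stay = chain.p_gg if state == GOOD else chain.p_bb
        if u[i] >= stay:
            state = BAD if state == GOOD else GOOD
        path[i] = state
    return path
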