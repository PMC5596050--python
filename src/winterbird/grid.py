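"""Discrete state lattice and linear value interpolation in fat.

The state of a bird is (x, y, w, t): fat reserves x on a uniform grid of
n_fat_steps intervals over [0, x_max], hypothermia depth y on a uniform grid
over [0, y_max], weather w in {good, bad}, and period t.  Per-period net fat
changes (~0.3 kJ) are much smaller than the fat grid step (1.48 kJ at
baseline), so the value function is interpolated linearly between fat nodes;
hypothermia transitions are constructed to land exactly on grid nodes, so no
interpolation is needed in y.

Fat x <= 0 is death by starvation and carries value 0 at every period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelParams

GOOD, BAD = 0, 1
WEATHER_LABELS = ("G", "B")

__all__ = [
    "GOOD",
    "BAD",
    "WEATHER_LABELS",
    "StateGrid",
    "build_grid",
    "interpolate_value",
    "interp_index_frac",
    "pchip_slopes",
    "hermite_basis",
]


@dataclass(frozen=True)
class StateGrid:
    """Discretisation of the (fat, hypothermia, weather, time) lattice."""

    fat_values: np.ndarray     #: kJ, shape (n_fat_steps + 1,), 0 .. x_max
    hypo_values: np.ndarray    #: degC, shape (n_hypo_steps + 1,), 0 .. y_max
    fat_step: float
    hypo_step: float
    n_periods_total: int
    periods_per_day: int
    daylight_start: int
    daylight_end: int
    n_days: int

    @property
    def n_fat(self) -> int:
        return len(self.fat_values) - 1

    @property
    def n_hypo(self) -> int:
        return len(self.hypo_values) - 1

    # -- time maps ---------------------------------------------------------

    def period_of_day(self, t: int | np.ndarray) -> int | np.ndarray:
        return t % self.periods_per_day

    def day_of(self, t: int | np.ndarray) -> int | np.ndarray:
        """1-based day index of period ``t`` (period 0 is midnight, day 1)."""
        return t // self.periods_per_day + 1

    def is_daylight(self, t: int | np.ndarray):
        pod = self.period_of_day(t)
        return (pod >= self.daylight_start) & (pod < self.daylight_end)

    def daybreak_period(self, day: int) -> int:
        """Absolute period of daybreak on the given (1-based) day."""
        return (day - 1) * self.periods_per_day + self.daylight_start

    def clock(self, t: int) -> str:
        """Wall-clock label of a period, e.g. period 96 -> '08:00'."""
        minutes = (t % self.periods_per_day) * (24 * 60 // self.periods_per_day)
        return f"{minutes // 60:02d}:{minutes % 60:02d}"


def build_grid(params: ModelParams) -> StateGrid:
    """Uniform state grids plus period/day index maps."""
    fat = np.linspace(0.0, params.x_max, params.n_fat_steps + 1)
    hypo = np.linspace(0.0, params.y_max, params.n_hypo_steps + 1)
    return StateGrid(
        fat_values=fat,
        hypo_values=hypo,
        fat_step=params.x_max / params.n_fat_steps,
        hypo_step=params.y_max / params.n_hypo_steps,
        n_periods_total=params.derived.n_periods_total,
        periods_per_day=params.periods_per_day,
        daylight_start=params.daylight_start,
        daylight_end=params.daylight_end,
        n_days=params.n_days,
    )


def interp_index_frac(
    x: np.ndarray, fat_step: float, n_fat: int
) -> tuple[np.ndarray, np.ndarray]:
    """Lower node index and interpolation fraction for fat values ``x``.

    Conventions: x <= 0 maps to node 0 with fraction 0 (node 0 always holds
    the starvation value 0); x >= x_max maps to the top interval with
    fraction 1.  The returned index is always in [0, n_fat - 1] so that
    ``index + 1`` is a valid node.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("fat values must be finite")
    pos = np.clip(x, 0.0, None) / fat_step
    idx = np.minimum(pos.astype(np.int64), n_fat - 1)
    frac = pos - idx
    frac = np.minimum(frac, 1.0)
    return idx, frac


def pchip_slopes(F: np.ndarray, step: float, axis: int = -1) -> np.ndarray:
    """Monotonicity-preserving derivative estimates on a uniform grid
    (Fritsch-Carlson): harmonic mean of adjacent secant slopes where they
    agree in sign, zero at local extrema, limited one-sided values at the
    ends.  The resulting cubic Hermite interpolant never overshoots the
    bracketing nodes."""
    F = np.moveaxis(np.asarray(F, dtype=float), axis, -1)
    m = np.diff(F) / step
    d = np.zeros_like(F)
    if F.shape[-1] >= 3:
        m0, m1 = m[..., :-1], m[..., 1:]
        prod = m0 * m1
        with np.errstate(divide="ignore", invalid="ignore"):
            harm = 2.0 * prod / (m0 + m1)
        d[..., 1:-1] = np.where(prod > 0, harm, 0.0)
        for end, ms, mn in ((0, m[..., 0], m[..., 1]), (-1, m[..., -1], m[..., -2])):
            cand = 1.5 * ms - 0.5 * mn
            cand = np.where(cand * ms <= 0, 0.0, cand)
            cand = np.where(np.abs(cand) > 3 * np.abs(ms), 3 * ms, cand)
            d[..., end] = cand
    else:
        d[..., 0] = m[..., 0]
        d[..., -1] = m[..., -1]
    return np.moveaxis(d, -1, axis)


def hermite_basis(frac: np.ndarray) -> tuple[np.ndarray, ...]:
    """Cubic Hermite basis polynomials evaluated at ``frac`` in [0, 1].

    Returns (h00, h10, h01, h11) such that the interpolant on one interval
    is h00*F_lo + h10*(step*d_lo) + h01*F_hi + h11*(step*d_hi).
    """
    t = np.asarray(frac, dtype=float)
    t2 = t * t
    t3 = t2 * t
    return (
        2 * t3 - 3 * t2 + 1,
        t3 - 2 * t2 + t,
        -2 * t3 + 3 * t2,
        t3 - t2,
    )


def interpolate_value(F_slice: np.ndarray, x: float, fat_step: float) -> float:
    """Interpolate a value-over-fat-grid array at fat ``x`` (monotone cubic).

    x <= 0 returns 0 (starvation); x at or above the last node returns the
    value at the last node.  Interpolated values never overshoot the
    bracketing nodes, and linear data are reproduced exactly.
    """
    if not np.isfinite(x):
        raise ValueError("fat value must be finite")
    F_slice = np.asarray(F_slice, dtype=float)
    n_fat = len(F_slice) - 1
    if x <= 0.0:
        return 0.0
    idx, frac = interp_index_frac(np.asarray([x]), fat_step, n_fat)
    i, f = int(idx[0]), float(frac[0])
    d = pchip_slopes(F_slice, fat_step) * fat_step
    h00, h10, h01, h11 = hermite_basis(np.asarray(f))
    return float(
        F_slice[i] * h00 + d[i] * h10 + F_slice[i + 1] * h01 + d[i + 1] * h11
    )
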