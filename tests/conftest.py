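"""Shared fixtures: tiny toy parameterisations and a plain reference solver.

The reference solver recomputes the value function by direct recursion over
every lattice state with scalar arithmetic (no vectorisation, no
precomputation), which makes it an independent check of the production
solver's gather/interpolate machinery on small instances.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from winterbird import behaviours as bh
from winterbird.config import ModelParams
from winterbird.grid import build_grid
from winterbird.risk import build_risk_model
from winterbird.solver import expected_value, feasible_behaviours
from winterbird.winter_end import (
    build_terminal_model,
    daybreak_end_probability,
    terminal_reward_array,
)


def toy_params(**overrides) -> ModelParams:
    """A 1-day, 8-period, 6x3-state model small enough to enumerate."""
    base = dict(
        x_max=6.0,
        n_fat_steps=5,
        y_max=2.0,
        n_hypo_steps=2,
        n_warmup_periods=2,
        n_days=1,
        periods_per_day=6,
        extra_periods=2,
        daylight_start=2,
        daylight_end=4,
        t_f_day=1,
        gain_forage_high=4.0,
        gain_forage_low=2.0,
        resting_metabolism=6.0,   # 1 kJ per period
        mu_forage=2.0,
        bad_weather_multiplier=1.5,
        unsuccessful_gain=0.5,
        success_prob=0.7,
        epsilon=0.5,
        beta_forage_high=0.10,
        beta_forage_low=0.05,
        beta_rest=0.01,
        beta_hypo_day=0.30,
        beta_hypo_night=0.02,
        x_cr=2.0,
        alpha_exp=2.0,
        p_gg=0.9,
        p_bb=0.8,
        x_start=3.0,
        warmup_cost=0.0,
    )
    base.update(overrides)
    return ModelParams(**base).validate()


def node_exact_params(**overrides) -> ModelParams:
    """A model whose per-period fat changes are exact grid-node multiples,
    so the value function involves no interpolation at all."""
    base = dict(
        x_max=8.0,
        n_fat_steps=16,
        y_max=2.0,
        n_hypo_steps=2,
        n_warmup_periods=2,
        n_days=3,
        periods_per_day=6,
        extra_periods=2,
        daylight_start=2,
        daylight_end=4,
        t_f_day=3,
        gain_forage_high=4.0,   # per-period gain 2.0, half-gain 1.0
        gain_forage_low=2.0,
        resting_metabolism=3.0,  # 0.5 kJ per period
        mu_forage=0.0,
        bad_weather_multiplier=2.0,
        unsuccessful_gain=0.5,
        epsilon=0.0,
        x_start=2.0,
    )
    base.update(overrides)
    return ModelParams(**base).validate()


def naive_solve(params: ModelParams):
    """Plain backward recursion over all states; returns (F, policy) with
    F of shape (T+1, nx+1, ny+1, 2) and policy of shape (T, nx+1, ny+1, 2)."""
    grid = build_grid(params)
    risk = build_risk_model(params)
    tm = build_terminal_model(params, grid)
    T = grid.n_periods_total
    nx1, ny1 = grid.n_fat + 1, grid.n_hypo + 1
    phi = terminal_reward_array(tm, params, grid)
    F = np.zeros((T + 1, nx1, ny1, 2))
    policy = np.zeros((T, nx1, ny1, 2), dtype=int)
    F[T] = phi[:, :, None]
    for t in range(T - 1, -1, -1):
        for iy, y in enumerate(grid.hypo_values):
            feas = feasible_behaviours(params, y, t)
            order = [b for b in bh.TIE_BREAK_ORDER if b in feas]
            for ix, x in enumerate(grid.fat_values):
                if ix == 0:
                    continue  # starvation row stays 0
                for w in (0, 1):
                    best, chosen = -1.0, 0
                    for b in order:
                        v = expected_value(
                            F[t + 1], params, grid, risk, b, x, y, w, t
                        )
                        if v > best:
                            best, chosen = v, b
                    F[t, ix, iy, w] = best
                    policy[t, ix, iy, w] = chosen
        p_end = daybreak_end_probability(tm, t)
        if t < T and p_end > 0.0:
            F[t] = p_end * phi[:, :, None] + (1.0 - p_end) * F[t]
            F[t, 0] = 0.0
    return F, policy


@pytest.fixture(scope="session")
def toy():
    return toy_params()


@pytest.fixture(scope="session")
def toy_solution(toy):
    return naive_solve(toy)
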