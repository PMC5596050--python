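"""Backward induction of the survival value function and optimal policy.

The value F_w(x, y, t) is the maximum probability of surviving from period
t to the end of winter, computed separately for good and bad current
weather.  The recursion walks backward from the final daybreak: each period
the bird picks the behaviour maximising

    (1 - beta_i) * E[ F_{w'}(x', y', t + 1) ]

where the expectation runs over foraging success and the weather
transition (the bad-weather cost factor applies exactly when the coming
period's weather is bad), beta_i is the per-period predation hazard of the
behaviour, and F is interpolated between fat grid nodes with a monotone
cubic scheme (see winterbird.grid).  At the
candidate end-of-winter daybreaks the value blends the terminal reward
with the continuation at the uniform end hazard.

Behaviour feasibility: foraging needs daylight and (near-)normothermia,
resting needs normothermia, deepening needs y < y_max, rewarming and
holding need y > 0.  Ties are broken toward the lower-risk behaviour, then
the lower behaviour index, so policies are deterministic.

The solver is fully vectorised over (fat, depth, weather) and over an
optional batch of parameter variants that share the same lattice (used for
epsilon / food-availability sweeps); per-period work is a fixed set of
gather-interpolate-reduce operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import behaviours as bh
from .config import ModelParams
from .energetics import fat_transition
from .grid import (
    BAD,
    GOOD,
    StateGrid,
    build_grid,
    hermite_basis,
    interp_index_frac,
    interpolate_value,
    pchip_slopes,
)
from .risk import RiskModel, build_risk_model, mass_multiplier, predation_hazard
from .thermo import down_map, up_map
from .winter_end import (
    TerminalModel,
    build_terminal_model,
    daybreak_end_probability,
    terminal_reward_array,
)

__all__ = [
    "Policy",
    "SolveResult",
    "feasible_behaviours",
    "expected_value",
    "backward_induction",
    "solve_batch",
]

# structural fields every variant in a batch must share (the lattice and
# time layout; rate-like parameters are free to differ per variant)
_STRUCTURAL = (
    "x_max",
    "n_fat_steps",
    "y_max",
    "n_hypo_steps",
    "n_days",
    "periods_per_day",
    "extra_periods",
    "daylight_start",
    "daylight_end",
    "t_f_day",
    "shallow_forage_limit",
)


def feasible_behaviours(params: ModelParams, y: float, t: int) -> set[int]:
    """The behaviours available at depth ``y`` in period ``t``."""
    grid = build_grid(params)
    daylight = bool(grid.is_daylight(t))
    out: set[int] = set()
    if daylight and (y == 0 or y < params.shallow_forage_limit):
        out |= {bh.FORAGE_HIGH, bh.FORAGE_LOW}
    if y == 0:
        out.add(bh.REST)
    if y < params.y_max:
        out.add(bh.COOL)
    if y > 0:
        out |= {bh.WARM, bh.HOLD}
    return out


def expected_value(
    F_next: np.ndarray,
    params: ModelParams,
    grid: StateGrid,
    risk: RiskModel,
    behaviour: int,
    x: float,
    y: float,
    weather: int,
    t: int,
) -> float:
    """Survival value of one behaviour in state (x, y, weather) at period t.

    ``F_next`` is the value array of period t+1 with shape
    (n_fat+1, n_hypo+1, 2).  This is the scalar reference path; the solver
    proper uses a vectorised equivalent.
    """
    daylight = bool(grid.is_daylight(t))
    trans = fat_transition(params, behaviour, x, y, weather, daylight)
    total = 0.0
    y_post = y
    for out in trans.outcomes:
        iy = int(round(out.next_y / grid.hypo_step))
        total += out.probability * interpolate_value(
            F_next[:, iy, out.next_weather], out.next_fat, grid.fat_step
        )
        y_post = out.next_y
    beta = float(predation_hazard(risk, behaviour, x, y_post, daylight))
    return (1.0 - beta) * total


@dataclass
class Policy:
    """Optimal behaviour (1-6) on the lattice for one parameter variant."""

    params: ModelParams
    grid: StateGrid
    behaviour: np.ndarray  #: int8, shape (horizon, n_fat+1, n_hypo+1, 2)

    @property
    def horizon(self) -> int:
        return self.behaviour.shape[0]


@dataclass
class SolveResult:
    variants: list[ModelParams]
    grid: StateGrid
    terminal: TerminalModel
    F_start: np.ndarray          #: shape (V,): value at the forward start state
    F_at: dict[int, np.ndarray]  #: period -> value array (V, nx+1, ny+1, 2)
    policy: np.ndarray | None    #: int8 (horizon, V, nx+1, ny+1, 2) or None
    F_full: np.ndarray | None = None  #: (T+1, V, ...) when store_F (toys only)

    def policy_for(self, v: int = 0) -> Policy:
        if self.policy is None:
            raise ValueError("solve was run without policy storage")
        return Policy(
            params=self.variants[v],
            grid=self.grid,
            behaviour=self.policy[:, v],
        )


class _Entry:
    """Per-behaviour precomputation: feasible depth rows, branch gather
    tables (node index plus frozen Hermite basis weights), and the
    survival factor (1 - beta)."""

    __slots__ = ("behaviour", "rows", "idx", "basis", "probs", "one_minus_beta")

    def __init__(self, behaviour, rows, idx, basis, probs, one_minus_beta):
        self.behaviour = behaviour
        self.rows = rows            # slice over depth rows
        self.idx = idx              # list of int64 (V, nx1, nrows)
        self.basis = basis          # list of (h00, h10, h01, h11) arrays
        self.probs = probs          # probs[w] -> float (V, n_branches)
        self.one_minus_beta = one_minus_beta  # (V, nx1|1, nrows|1)


def _flat_index(ix, iy, w, V, nx1, ny1):
    """Flat index into F.ravel() for F of shape (V, nx1, ny1, 2)."""
    v = np.arange(V, dtype=np.int64).reshape(V, 1, 1)
    return ((v * nx1 + ix) * ny1 + iy) * 2 + w


def _branch_tables(x_next, iy_next, next_w, grid, V, nx1, ny1):
    """Gather tables (flat node index, Hermite basis) for ``x_next``.

    ``x_next`` broadcasts to (V, nx1, nrows); ``iy_next`` is the per-row
    destination depth index, shape (nrows,).  Next-fat values at or below
    zero land on node 0 with fraction 0, whose value is pinned at 0
    (starvation), so they contribute nothing.
    """
    idx_x, frac = interp_index_frac(x_next, grid.fat_step, grid.n_fat)
    dead = np.asarray(x_next) <= 0.0
    idx_x = np.where(dead, 0, idx_x)
    frac = np.where(dead, 0.0, frac)
    flat = _flat_index(idx_x, iy_next.reshape(1, 1, -1), next_w, V, nx1, ny1)
    return flat, hermite_basis(frac)


def _build_entries(
    variants: Sequence[ModelParams],
    grid: StateGrid,
    risks: Sequence[RiskModel],
    daylight: bool,
):
    """The behaviour entries evaluated each period of the given phase, in
    tie-break order."""
    V = len(variants)
    nx1, ny1 = grid.n_fat + 1, grid.n_hypo + 1
    xs = grid.fat_values
    ys = grid.hypo_values
    gamma = np.array([p.bad_weather_multiplier for p in variants])
    lam = np.array([p.success_prob for p in variants])
    p_gg = np.array([p.p_gg for p in variants])
    p_bb = np.array([p.p_bb for p in variants])
    c_rm = np.array([p.derived.c_rm_period for p in variants])

    # foraging is allowed at depth 0 and, in the shallow-forage variant,
    # at any depth below the limit (a contiguous block of rows from 0)
    limit = variants[0].shallow_forage_limit
    n_forage_rows = max(1, int(np.sum(ys < limit))) if limit > 0 else 1

    def weather_probs(branch_next_w):
        """probs[w] array (V, n_branches) for branches with given next-w."""
        out = []
        for w in (GOOD, BAD):
            stay = p_gg if w == GOOD else p_bb
            cols = []
            for next_w, p_succ in branch_next_w:
                p_w = stay if next_w == w else 1.0 - stay
                cols.append(p_w * p_succ)
            out.append(np.stack(cols, axis=1))
        return out

    def hazard(behaviour, y_post_vals, rows_len):
        """(1 - beta) with shape (V, nx1 or 1, rows_len or 1)."""
        omb = np.empty((V, nx1, rows_len))
        for v, r in enumerate(risks):
            b = predation_hazard(
                r,
                behaviour,
                xs[:, None],
                np.asarray(y_post_vals)[None, :],
                daylight,
            )
            omb[v] = 1.0 - np.broadcast_to(b, (nx1, rows_len))
        return omb

    entries: list[_Entry] = []
    down = {v: down_map(p) for v, p in enumerate(variants)}
    up = {v: up_map(p) for v, p in enumerate(variants)}

    for behaviour in bh.TIE_BREAK_ORDER:
        if behaviour in (bh.FORAGE_HIGH, bh.FORAGE_LOW):
            if not daylight:
                continue
            rows = slice(0, n_forage_rows)
            iy_next = np.arange(n_forage_rows)
            mu = np.array([p.mu_forage for p in variants])
            activity = (
                mu[:, None] * c_rm[:, None] * (1.0 + xs[None, :] / grid.fat_values[-1])
            )  # (V, nx1)
            total_scope = np.array(
                [p.bad_weather_scope == "total_cost" for p in variants]
            )
            g = np.array(
                [
                    p.derived.g_period_high
                    if behaviour == bh.FORAGE_HIGH
                    else p.derived.g_period_low
                    for p in variants
                ]
            )
            delta = np.array([p.unsuccessful_gain for p in variants])
            branches = []
            branch_meta = []
            for next_w in (GOOD, BAD):
                if next_w == BAD:
                    c = np.where(
                        total_scope[:, None],
                        (c_rm[:, None] + activity) * gamma[:, None],
                        c_rm[:, None] * gamma[:, None] + activity,
                    )
                else:
                    c = c_rm[:, None] + activity
                for gain, p_succ in (
                    (g, lam),
                    (g * delta, 1.0 - lam),
                ):
                    x_next = np.minimum(
                        xs[None, :] + gain[:, None] - c, grid.fat_values[-1]
                    )[:, :, None]
                    x_next = np.broadcast_to(x_next, (V, nx1, n_forage_rows))
                    branches.append(
                        _branch_tables(x_next, iy_next, next_w, grid, V, nx1, ny1)
                    )
                    branch_meta.append((next_w, p_succ))
            entries.append(
                _Entry(
                    behaviour,
                    rows,
                    [b[0] for b in branches],
                    [b[1] for b in branches],
                    weather_probs(branch_meta),
                    hazard(behaviour, ys[:n_forage_rows], n_forage_rows),
                )
            )
        elif behaviour == bh.REST:
            rows = slice(0, 1)
            iy_next = np.zeros(1, dtype=np.int64)
            branches, branch_meta = [], []
            for next_w in (GOOD, BAD):
                c = c_rm[:, None] * (gamma[:, None] if next_w == BAD else 1.0)
                x_next = np.minimum(xs[None, :] - c, grid.fat_values[-1])[:, :, None]
                branches.append(
                    _branch_tables(x_next, iy_next, next_w, grid, V, nx1, ny1)
                )
                branch_meta.append((next_w, np.ones(V)))
            entries.append(
                _Entry(
                    behaviour,
                    rows,
                    [b[0] for b in branches],
                    [b[1] for b in branches],
                    weather_probs(branch_meta),
                    hazard(behaviour, ys[:1], 1),
                )
            )
        else:  # COOL / WARM / HOLD
            if behaviour == bh.COOL:
                rows = slice(0, grid.n_hypo)
            else:
                rows = slice(1, grid.n_hypo + 1)
            row_idx = np.arange(rows.start, rows.stop)
            nrows = len(row_idx)
            # per-variant destination depth (ladders may differ)
            iy_next_v = np.empty((V, nrows), dtype=np.int64)
            for v in range(V):
                if behaviour == bh.COOL:
                    iy_next_v[v] = down[v][row_idx]
                elif behaviour == bh.WARM:
                    iy_next_v[v] = up[v][row_idx]
                else:
                    iy_next_v[v] = row_idx
            eps = np.array([p.epsilon for p in variants])
            surcharge = np.array(
                [
                    p.derived.warmup_surcharge if behaviour == bh.WARM else 0.0
                    for p in variants
                ]
            )
            y_next_vals = ys[iy_next_v]  # (V, nrows)
            base = c_rm[:, None] * (
                1.0 - eps[:, None] * y_next_vals / grid.hypo_values[-1]
            )  # (V, nrows)
            branches, branch_meta = [], []
            for next_w in (GOOD, BAD):
                c = base * (gamma[:, None] if next_w == BAD else 1.0)
                c = c + surcharge[:, None]
                x_next = xs[None, :, None] - c[:, None, :]  # (V, nx1, nrows)
                x_next = np.minimum(x_next, grid.fat_values[-1])
                idx_x, frac = interp_index_frac(x_next, grid.fat_step, grid.n_fat)
                dead = x_next <= 0.0
                idx_x = np.where(dead, 0, idx_x)
                frac = np.where(dead, 0.0, frac)
                v_ix = np.arange(V, dtype=np.int64).reshape(V, 1, 1)
                flat = (
                    (v_ix * nx1 + idx_x) * ny1 + iy_next_v[:, None, :]
                ) * 2 + next_w
                branches.append((flat, hermite_basis(frac)))
                branch_meta.append((next_w, np.ones(V)))
            # hazard is evaluated at the post-change depth, per variant
            omb = np.empty((V, nx1, nrows))
            for v, r in enumerate(risks):
                b = predation_hazard(
                    r,
                    behaviour,
                    xs[:, None],
                    ys[iy_next_v[v]][None, :],
                    daylight,
                )
                omb[v] = 1.0 - np.broadcast_to(b, (nx1, nrows))
            entries.append(
                _Entry(
                    behaviour,
                    rows,
                    [b[0] for b in branches],
                    [b[1] for b in branches],
                    weather_probs(branch_meta),
                    omb,
                )
            )
    return entries


def backward_induction(
    params: ModelParams,
    *,
    policy_horizon: int | None = None,
    checkpoints: Sequence[int] | None = None,
    store_F: bool = False,
) -> SolveResult:
    """Solve one parameter set; see :func:`solve_batch`."""
    return solve_batch(
        [params],
        policy_horizon=policy_horizon,
        checkpoints=checkpoints,
        store_F=store_F,
    )


def solve_batch(
    variants: Sequence[ModelParams],
    *,
    policy_horizon: int | None = None,
    checkpoints: Sequence[int] | None = None,
    store_F: bool = False,
) -> SolveResult:
    """Backward induction for a batch of variants sharing one lattice.

    Parameters
    ----------
    variants
        Parameter sets differing only in rate-like values (epsilon, food
        multiplier, rewarming cost, hazards, ...); the state lattice and
        time layout must be identical.
    policy_horizon
        Store the optimal behaviour for periods ``t < policy_horizon``
        (default: the whole winter; pass 0 to skip policy storage when
        only the value function is needed).
    checkpoints
        Extra periods at which to keep a copy of the full value array.
        The day-1 daybreak (the forward start period) is always kept.
    store_F
        Keep the value function at every period (small toy models only).
    """
    variants = [p.validate() for p in variants]
    base = variants[0]
    for p in variants[1:]:
        for name in _STRUCTURAL:
            if getattr(p, name) != getattr(base, name):
                raise ValueError(
                    f"batch variants must share the lattice; {name} differs"
                )
    grid = build_grid(base)
    V = len(variants)
    nx1, ny1 = grid.n_fat + 1, grid.n_hypo + 1
    T = grid.n_periods_total
    H = T if policy_horizon is None else min(policy_horizon, T)
    policy_bytes = H * V * nx1 * ny1 * 2
    if policy_bytes > 1.6e9:
        raise MemoryError(
            f"policy array would need {policy_bytes/1e9:.1f} GB; "
            "reduce policy_horizon or batch size"
        )

    risks = [build_risk_model(p) for p in variants]
    terminal = build_terminal_model(base, grid)
    phi = np.stack(
        [terminal_reward_array(terminal, p, grid) for p in variants]
    )  # (V, nx1, ny1)
    end_p = {
        int(t): daybreak_end_probability(terminal, int(t))
        for t in terminal.candidate_daybreaks[:-1]
    }

    day_entries = _build_entries(variants, grid, risks, daylight=True)
    night_entries = _build_entries(variants, grid, risks, daylight=False)

    start_period = grid.daybreak_period(1)
    want_checkpoints = set(int(c) for c in (checkpoints or ()))
    want_checkpoints.add(start_period)

    F = np.repeat(phi[:, :, :, None], 2, axis=3).astype(float)  # value at T
    F_at: dict[int, np.ndarray] = {}
    if T in want_checkpoints:
        F_at[T] = F.copy()
    policy = (
        np.zeros((H, V, nx1, ny1, 2), dtype=np.int8) if H > 0 else None
    )
    F_full = None
    if store_F:
        F_full = np.empty((T + 1, V, nx1, ny1, 2))
        F_full[T] = F

    stride_x = ny1 * 2
    best = np.empty((V, nx1, ny1, 2))
    pol_t = np.zeros((V, nx1, ny1, 2), dtype=np.int8)

    for t in range(T - 1, -1, -1):
        entries = day_entries if grid.is_daylight(t) else night_entries
        F_flat = F.reshape(-1)
        # monotone-cubic slopes along the fat axis, frozen per period
        D_flat = (pchip_slopes(F, grid.fat_step, axis=1) * grid.fat_step).reshape(-1)
        best.fill(-1.0)
        pol_t.fill(0)
        for e in entries:
            vals = []
            for flat, (h00, h10, h01, h11) in zip(e.idx, e.basis):
                lo = F_flat.take(flat)
                hi = F_flat.take(flat + stride_x)
                dlo = D_flat.take(flat)
                dhi = D_flat.take(flat + stride_x)
                vals.append(lo * h00 + dlo * h10 + hi * h01 + dhi * h11)
            stacked = np.stack(vals)  # (n_br, V, nx1, nrows)
            for w in (GOOD, BAD):
                ev = np.einsum("bvxr,vb->vxr", stacked, e.probs[w])
                net = e.one_minus_beta * ev
                slot = best[:, :, e.rows, w]
                better = net > slot
                np.copyto(slot, net, where=better)
                np.copyto(pol_t[:, :, e.rows, w], e.behaviour, where=better)
        F_new = best.copy()
        F_new[:, 0, :, :] = 0.0
        if policy is not None and t < H:
            policy[t] = pol_t
        if t in end_p:
            p = end_p[t]
            F_new = p * phi[:, :, :, None] + (1.0 - p) * F_new
        F = F_new
        if t in want_checkpoints:
            F_at[t] = F.copy()
        if store_F:
            F_full[t] = F

    start_slice = F_at[start_period]
    F_start = np.array(
        [
            interpolate_value(
                start_slice[v, :, 0, GOOD], variants[v].x_start, grid.fat_step
            )
            for v in range(V)
        ]
    )
    return SolveResult(
        variants=list(variants),
        grid=grid,
        terminal=terminal,
        F_start=F_start,
        F_at=F_at,
        policy=policy,
        F_full=F_full,
    )
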