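"""Forward Monte-Carlo simulation of a cohort following the optimal policy.

Birds start at the day-1 daybreak with the configured fat load,
normothermic, in good weather, and each period look up the solved optimal
behaviour for their (rounded-to-node fat, depth, weather) state, then draw
foraging success, the weather transition, predation, and starvation.  At
the candidate end-of-winter daybreaks the winter ends with the same
uniform hazard the solver used; a bird alive at that moment survives the
winter if it can still afford to rewarm.

All draws are vectorised across the cohort from a single seeded PCG64
stream, so a run is exactly reproducible given (seed, cohort size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behaviours as bh
from .config import ModelParams
from .grid import BAD, GOOD, StateGrid
from .risk import build_risk_model, predation_hazard
from .solver import Policy
from .thermo import down_map, up_map, warmup_fat_requirement
from .winter_end import build_terminal_model, daybreak_end_probability

__all__ = ["BirdStatus", "TrajectoryEnsemble", "simulate_cohort"]


class BirdStatus:
    ALIVE = 0
    SURVIVED_WINTER = 1
    DEAD_PREDATION = 2
    DEAD_STARVATION = 3
    DEAD_AT_WINTER_END = 4   #: winter ended, too lean/deep to rewarm
    CENSORED = 5             #: simulation horizon reached before winter's end


@dataclass
class TrajectoryEnsemble:
    """Per-period cohort records plus final per-bird statuses.

    Record arrays are indexed by ``t - t0`` and aggregate over birds alive
    at the *start* of the period; behaviour counts are over birds that act
    in the period.
    """

    params: ModelParams
    grid: StateGrid
    n_birds: int
    seed: int
    t0: int
    t_end: int
    status: np.ndarray          #: final per-bird status, shape (N,)
    alive_n: np.ndarray         #: birds alive at start of period
    fat_sum: np.ndarray         #: kJ, summed over alive birds
    fat_sqsum: np.ndarray
    y_sum: np.ndarray           #: degC, summed over alive birds
    hypo_n: np.ndarray          #: alive birds with y > 0
    beh_counts: np.ndarray      #: (L, 6) acting birds per behaviour
    fat_traj: np.ndarray | None = field(default=None, repr=False)
    y_traj: np.ndarray | None = field(default=None, repr=False)
    beh_traj: np.ndarray | None = field(default=None, repr=False)

    # -- bookkeeping ---------------------------------------------------------

    def status_counts(self) -> dict[str, int]:
        names = {
            BirdStatus.ALIVE: "alive",
            BirdStatus.SURVIVED_WINTER: "survived_winter",
            BirdStatus.DEAD_PREDATION: "dead_predation",
            BirdStatus.DEAD_STARVATION: "dead_starvation",
            BirdStatus.DEAD_AT_WINTER_END: "dead_at_winter_end",
            BirdStatus.CENSORED: "censored",
        }
        return {
            name: int(np.sum(self.status == code)) for code, name in names.items()
        }

    def survival_fraction(self) -> float:
        """Fraction of the cohort that survived the whole winter."""
        return float(np.mean(self.status == BirdStatus.SURVIVED_WINTER))

    # -- per-period accessors -------------------------------------------------

    def _i(self, t: int) -> int:
        if not self.t0 <= t <= self.t_end:
            raise IndexError(f"period {t} outside simulated range")
        return t - self.t0

    def mean_fat(self, t: int) -> float:
        """Mean fat (kJ) of birds alive at the start of period ``t``."""
        i = self._i(t)
        n = self.alive_n[i]
        return float(self.fat_sum[i] / n) if n else float("nan")

    def mean_depth(self, t: int) -> float:
        i = self._i(t)
        n = self.alive_n[i]
        return float(self.y_sum[i] / n) if n else float("nan")

    # -- daily summaries ------------------------------------------------------

    def dawn_fat(self, day: int) -> float:
        return self.mean_fat(self.grid.daybreak_period(day))

    def dusk_fat(self, day: int) -> float:
        t = (day - 1) * self.grid.periods_per_day + self.grid.daylight_end
        return self.mean_fat(t)

    def daily_gain_g(self, day: int) -> float:
        """Mean dusk-minus-dawn fat gain on one day, in grams."""
        return (self.dusk_fat(day) - self.dawn_fat(day)) / self.params.fat_energy_density

    def dusk_mass_g(self, day: int) -> float:
        return self.params.lean_mass_g + self.dusk_fat(day) / self.params.fat_energy_density

    def _night_window(self, day: int) -> np.ndarray:
        """Absolute periods of the night following daylight of ``day``."""
        ppd = self.grid.periods_per_day
        start = (day - 1) * ppd + self.grid.daylight_end
        stop = day * ppd + self.grid.daylight_start
        stop = min(stop, self.t_end)
        return np.arange(start, stop)

    def night_hypo_fraction(self, day: int) -> float:
        """Fraction of alive-bird night periods spent hypothermic (y > 0)."""
        win = self._night_window(day) - self.t0
        total = self.alive_n[win].sum()
        return float(self.hypo_n[win].sum() / total) if total else float("nan")

    def warming_onset_minutes(self, day: int) -> float | None:
        """Minutes before the next dawn at which rewarming becomes the modal
        behaviour during the night after ``day``; None if it never does."""
        win = self._night_window(day)
        dawn = day * self.grid.periods_per_day + self.grid.daylight_start
        minutes_per_period = 24 * 60 / self.grid.periods_per_day
        for t in win:
            counts = self.beh_counts[t - self.t0]
            if counts.sum() and counts.argmax() + 1 == bh.WARM:
                return float((dawn - t) * minutes_per_period)
        return None

    def day_summary(self, day: int) -> pd.DataFrame:
        """Per-period means over one day: mass, body temperature, behaviour
        time budget, alive count."""
        ppd = self.grid.periods_per_day
        t_first = (day - 1) * ppd
        rows = []
        for t in range(max(t_first, self.t0), min(t_first + ppd, self.t_end + 1)):
            i = self._i(t)
            n = self.alive_n[i]
            acting = self.beh_counts[i].sum()
            row = {
                "period": t % ppd,
                "clock": self.grid.clock(t),
                "alive": int(n),
                "mean_mass_g": self.params.lean_mass_g
                + (self.fat_sum[i] / n) / self.params.fat_energy_density
                if n
                else float("nan"),
                "mean_temp_c": self.params.normal_body_temp - self.y_sum[i] / n
                if n
                else float("nan"),
            }
            for code, name in bh.NAMES.items():
                row[f"frac_{name}"] = (
                    self.beh_counts[i][code - 1] / acting if acting else 0.0
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Full per-bird trajectories (only when recorded)."""
        if self.fat_traj is None:
            raise ValueError("run simulate_cohort with record_full=True")
        n, length = self.fat_traj.shape
        ppd = self.grid.periods_per_day
        t_abs = np.arange(self.t0, self.t0 + length)
        return pd.DataFrame(
            {
                "bird": np.repeat(np.arange(n), length),
                "period": np.tile(t_abs, n),
                "day": np.tile(t_abs // ppd + 1, n),
                "fat_kj": self.fat_traj.reshape(-1),
                "mass_g": self.params.lean_mass_g
                + self.fat_traj.reshape(-1) / self.params.fat_energy_density,
                "temp_c": self.params.normal_body_temp
                - self.y_traj.reshape(-1) * (self.params.y_max / self.params.n_hypo_steps),
                "behaviour": self.beh_traj.reshape(-1),
            }
        )


def simulate_cohort(
    policy: Policy,
    n_birds: int,
    seed: int,
    *,
    horizon: int | None = None,
    record_full: bool = False,
) -> TrajectoryEnsemble:
    """Simulate ``n_birds`` birds following ``policy`` from day-1 daybreak.

    ``horizon`` (absolute period) truncates the simulation before the end
    of winter -- used for mid-winter summaries where the end window is
    irrelevant; birds still alive then are censored.
    """
    params = policy.params
    grid = policy.grid
    d = params.derived
    T = grid.n_periods_total
    t_end = T if horizon is None else min(horizon, T)
    if policy.horizon < t_end:
        raise ValueError(
            f"policy stored to period {policy.horizon} but simulation needs {t_end}"
        )
    risk = build_risk_model(params)
    terminal = build_terminal_model(params, grid)
    end_p = {
        int(t): daybreak_end_probability(terminal, int(t))
        for t in terminal.candidate_daybreaks
    }
    down = down_map(params)
    up = up_map(params)
    ys = grid.hypo_values
    xc_by_iy = np.array([warmup_fat_requirement(params, y) for y in ys])
    nx = grid.n_fat
    h = grid.fat_step
    gamma = params.bad_weather_multiplier
    lam = params.success_prob

    rng = np.random.default_rng(seed)
    t0 = grid.daybreak_period(1)
    length = t_end - t0 + 1

    x = np.full(n_birds, float(params.x_start))
    iy = np.zeros(n_birds, dtype=np.int64)
    w = np.full(n_birds, GOOD, dtype=np.int64)
    status = np.full(n_birds, BirdStatus.ALIVE, dtype=np.int8)

    alive_n = np.zeros(length, dtype=np.int64)
    fat_sum = np.zeros(length)
    fat_sqsum = np.zeros(length)
    y_sum = np.zeros(length)
    hypo_n = np.zeros(length, dtype=np.int64)
    beh_counts = np.zeros((length, 6), dtype=np.int64)
    if record_full:
        fat_traj = np.full((n_birds, length), np.nan, dtype=np.float32)
        y_traj = np.zeros((n_birds, length), dtype=np.int16)
        beh_traj = np.zeros((n_birds, length), dtype=np.int8)
    else:
        fat_traj = y_traj = beh_traj = None

    for t in range(t0, t_end + 1):
        i = t - t0
        alive = status == BirdStatus.ALIVE
        alive_n[i] = alive.sum()
        fat_sum[i] = x[alive].sum()
        fat_sqsum[i] = (x[alive] ** 2).sum()
        y_sum[i] = ys[iy[alive]].sum()
        hypo_n[i] = np.sum(alive & (iy > 0))
        if record_full:
            fat_traj[alive, i] = x[alive]
            y_traj[alive, i] = iy[alive]

        if t in end_p:
            u_end = rng.random(n_birds)
            ended = alive & (u_end < end_p[t])
            if ended.any():
                ok = x[ended] >= xc_by_iy[iy[ended]]
                codes = np.where(
                    ok, BirdStatus.SURVIVED_WINTER, BirdStatus.DEAD_AT_WINTER_END
                )
                status[ended] = codes
                alive = status == BirdStatus.ALIVE
        if t == t_end:
            if t_end < T:
                status[alive] = BirdStatus.CENSORED
            break

        act = alive
        if not act.any():
            break
        ix = np.clip(np.rint(x / h).astype(np.int64), 0, nx)
        beh = policy.behaviour[t, ix, iy, w]
        daylight = bool(grid.is_daylight(t))

        # post-change depth determines both the hazard class and the cost
        y_new = iy.copy()
        m_cool = act & (beh == bh.COOL)
        m_warm = act & (beh == bh.WARM)
        y_new[m_cool] = down[iy[m_cool]]
        y_new[m_warm] = up[iy[m_warm]]

        beta = np.zeros(n_birds)
        for b in np.unique(beh[act]):
            m = act & (beh == b)
            beta[m] = predation_hazard(risk, int(b), x[m], ys[y_new[m]], daylight)

        np.add.at(beh_counts, (i, beh[act] - 1), 1)
        if record_full:
            beh_traj[act, i] = beh[act]

        u_pred, u_succ, u_w = rng.random((3, n_birds))
        killed = act & (u_pred < beta)
        status[killed] = BirdStatus.DEAD_PREDATION
        act = status == BirdStatus.ALIVE

        stay = np.where(w == GOOD, params.p_gg, params.p_bb)
        w_next = np.where(u_w < stay, w, 1 - w)
        gfac = np.where(w_next == BAD, gamma, 1.0)

        gain = np.zeros(n_birds)
        cost = np.zeros(n_birds)
        for b, g_per in (
            (bh.FORAGE_HIGH, d.g_period_high),
            (bh.FORAGE_LOW, d.g_period_low),
        ):
            m = act & (beh == b)
            if m.any():
                success = u_succ[m] < lam
                gain[m] = g_per * np.where(success, 1.0, params.unsuccessful_gain)
                activity = (
                    params.mu_forage
                    * d.c_rm_period
                    * (1.0 + x[m] / params.x_max)
                )
                if params.bad_weather_scope == "total_cost":
                    cost[m] = (d.c_rm_period + activity) * gfac[m]
                else:
                    cost[m] = d.c_rm_period * gfac[m] + activity
        m = act & (beh == bh.REST)
        cost[m] = d.c_rm_period * gfac[m]
        m = act & np.isin(beh, (bh.COOL, bh.WARM, bh.HOLD))
        if m.any():
            base = d.c_rm_period * (
                1.0 - params.epsilon * ys[y_new[m]] / params.y_max
            )
            cost[m] = base * gfac[m]
            mw = act & (beh == bh.WARM)
            cost[mw] += d.warmup_surcharge

        x_next = np.minimum(x + gain - cost, params.x_max)
        starved = act & (x_next <= 0.0)
        status[starved] = BirdStatus.DEAD_STARVATION
        act = status == BirdStatus.ALIVE

        x[act] = x_next[act]
        iy[act] = y_new[act]
        w[act] = w_next[act]

    return TrajectoryEnsemble(
        params=params,
        grid=grid,
        n_birds=n_birds,
        seed=seed,
        t0=t0,
        t_end=t_end,
        status=status,
        alive_n=alive_n,
        fat_sum=fat_sum,
        fat_sqsum=fat_sqsum,
        y_sum=y_sum,
        hypo_n=hypo_n,
        beh_counts=beh_counts,
        fat_traj=fat_traj,
        y_traj=y_traj,
        beh_traj=beh_traj,
    )
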