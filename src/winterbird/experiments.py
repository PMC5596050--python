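"""The model's standard numerical experiments.

Each experiment solves the model (for one or more parameter variants) and,
where behaviour rather than fitness is the question, forward-simulates a
cohort and summarises a stabilised mid-winter day.  Variants that share
the state lattice are solved together in chunks, which is what makes the
1%-step saving scan affordable.  Results are plain DataFrames / dicts; the
CLI writes them as CSV plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .config import ModelParams, serialize
from .simulate import TrajectoryEnsemble, simulate_cohort
from .solver import SolveResult, solve_batch

__all__ = [
    "DEFAULT_MIDWINTER_DAY",
    "solve_and_simulate",
    "sweep_max_saving",
    "find_abandonment_saving",
    "sweep_delta",
    "warmup_cost_contrast",
    "baseline_day_metrics",
    "write_manifest",
]

#: mid-winter summary day: well after the start-up transient of the forward
#: iteration (the policy stabilises within the first week) and well before
#: the end-of-winter window opens
DEFAULT_MIDWINTER_DAY = 40

_CHUNK = 8  # variants solved per batch; bounds the policy array at ~0.5 GB


def _sim_horizon(params: ModelParams, day: int) -> int:
    """Simulate one day past the summary day (the night after it included)."""
    return min(
        (day + 1) * params.periods_per_day + params.daylight_start,
        params.derived.n_periods_total,
    )


def solve_and_simulate(
    variants: Sequence[ModelParams],
    n_birds: int,
    seed: int,
    day: int = DEFAULT_MIDWINTER_DAY,
) -> list[tuple[float, TrajectoryEnsemble]]:
    """Solve each variant and simulate a cohort up to the night after
    ``day``; returns (survival value at the start state, ensemble) pairs.

    Variants are processed in chunks so policies for at most ``_CHUNK``
    variants are held in memory at a time.
    """
    horizon = _sim_horizon(variants[0], day)
    out: list[tuple[float, TrajectoryEnsemble]] = []
    for lo in range(0, len(variants), _CHUNK):
        chunk = list(variants[lo : lo + _CHUNK])
        res = solve_batch(chunk, policy_horizon=horizon)
        for v in range(len(chunk)):
            ens = simulate_cohort(
                res.policy_for(v), n_birds, seed, horizon=horizon
            )
            out.append((float(res.F_start[v]), ens))
    return out


def latest_viable_day(
    ens: TrajectoryEnsemble, day: int, min_alive: int = 100, earliest: int = 8
) -> int | None:
    """Latest day <= ``day`` (but past the start-up transient) on which at
    least ``min_alive`` birds are alive at dusk.

    Paired-cohort contrasts (e.g. the rewarming-cost comparison) need a
    common day with enough survivors in both cohorts; under parameter
    settings where a cohort collapses before mid-winter this backs off to
    the latest day the summary is still well estimated.
    """
    ppd = ens.grid.periods_per_day
    for d in range(day, earliest - 1, -1):
        t = (d - 1) * ppd + ens.grid.daylight_end
        if ens.t0 <= t <= ens.t_end and ens.alive_n[t - ens.t0] >= min_alive:
            return d
    return None


def sweep_max_saving(
    params: ModelParams, savings: Sequence[float]
) -> pd.DataFrame:
    """Whole-winter survival at the start state as a function of the
    maximum hypothermic saving fraction (no simulation needed)."""
    rows = []
    for lo in range(0, len(savings), _CHUNK):
        chunk = [params.replace(epsilon=float(e)) for e in savings[lo : lo + _CHUNK]]
        res = solve_batch(chunk, policy_horizon=0)
        for e, f in zip(savings[lo : lo + _CHUNK], res.F_start):
            rows.append({"saving": float(e), "survival": float(f)})
    return pd.DataFrame(rows)


def find_abandonment_saving(
    params: ModelParams,
    *,
    step: float = 0.01,
    start: float = 0.30,
    n_birds: int = 1000,
    seed: int = 0,
    day: int = DEFAULT_MIDWINTER_DAY,
) -> tuple[float | None, pd.DataFrame]:
    """Scan the maximum saving downward in ``step`` increments from
    ``start`` and find the largest value at which the simulated cohort
    uses no night-time hypothermia at all on the mid-winter summary day.

    Returns (saving or None, table of saving / hypothermia-use /
    survival).
    """
    n = int(round(start / step))
    savings = [round(k * step, 10) for k in range(n, 0, -1)]
    variants = [params.replace(epsilon=e) for e in savings]
    results = solve_and_simulate(variants, n_birds, seed, day)
    rows = []
    for e, (f, ens) in zip(savings, results):
        rows.append(
            {
                "saving": e,
                "night_hypo_fraction": ens.night_hypo_fraction(day),
                "survival_value": f,
            }
        )
    table = pd.DataFrame(rows)
    zero = table[table["night_hypo_fraction"] == 0.0]
    best = float(zero["saving"].max()) if len(zero) else None
    return best, table


def sweep_delta(
    params: ModelParams,
    deltas: Sequence[float],
    *,
    n_birds: int = 1000,
    seed: int = 0,
    day: int = DEFAULT_MIDWINTER_DAY,
) -> pd.DataFrame:
    """Behavioural response to food availability: for each gain multiplier,
    mid-winter dusk mass, night-time hypothermia use, and the daylight
    time budget of foraging/resting."""
    variants = [params.replace(food_multiplier=float(dl)) for dl in deltas]
    results = solve_and_simulate(variants, n_birds, seed, day)
    rows = []
    for dl, (f, ens) in zip(deltas, results):
        summary = ens.day_summary(day)
        daylight = summary[
            (summary["period"] >= params.daylight_start)
            & (summary["period"] < params.daylight_end)
        ]
        rows.append(
            {
                "food_multiplier": float(dl),
                "survival_value": f,
                "dusk_fat_g": ens.dusk_fat(day) / params.fat_energy_density,
                "dusk_mass_g": ens.dusk_mass_g(day),
                "night_hypo_fraction": ens.night_hypo_fraction(day),
                "frac_forage_high": daylight["frac_forage_high"].mean(),
                "frac_forage_low": daylight["frac_forage_low"].mean(),
                "frac_rest": daylight["frac_rest"].mean(),
            }
        )
    return pd.DataFrame(rows)


def warmup_cost_contrast(
    params: ModelParams,
    *,
    warmup_cost: float = 6.0,
    n_birds: int = 1000,
    seed: int = 0,
    day: int = DEFAULT_MIDWINTER_DAY,
) -> dict[str, float]:
    """Mid-winter dusk fat with and without the extra rewarming cost."""
    variants = [params.replace(warmup_cost=0.0), params.replace(warmup_cost=warmup_cost)]
    (f0, ens0), (f1, ens1) = solve_and_simulate(variants, n_birds, seed, day)
    g = params.fat_energy_density
    return {
        "dusk_fat_g_no_cost": ens0.dusk_fat(day) / g,
        "dusk_fat_g_with_cost": ens1.dusk_fat(day) / g,
        "dusk_fat_diff_g": (ens1.dusk_fat(day) - ens0.dusk_fat(day)) / g,
        "survival_no_cost": f0,
        "survival_with_cost": f1,
    }


def baseline_day_metrics(
    params: ModelParams,
    *,
    n_birds: int = 1000,
    seed: int = 0,
    day: int = DEFAULT_MIDWINTER_DAY,
) -> dict[str, Any]:
    """Headline mid-winter quantities of the baseline model."""
    ((f, ens),) = solve_and_simulate([params], n_birds, seed, day)
    return {
        "survival_value": f,
        "dawn_fat_g": ens.dawn_fat(day) / params.fat_energy_density,
        "dusk_fat_g": ens.dusk_fat(day) / params.fat_energy_density,
        "daily_gain_g": ens.daily_gain_g(day),
        "night_hypo_fraction": ens.night_hypo_fraction(day),
        "warming_onset_min": ens.warming_onset_minutes(day),
        "ensemble": ens,
    }


def write_manifest(
    out_dir: str | Path, params: ModelParams, seed: int | None, **extra: Any
) -> Path:
    """Write a JSON manifest sufficient to reproduce a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    text = serialize(params)
    manifest = {
        "params_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "params": text,
        "seed": seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        **extra,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
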