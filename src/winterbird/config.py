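"""Model parameters: loading, validation, and per-period derived rates.

All energetic parameters are entered per *day* (kJ/day, risk/day), which is
how they are usually reported in the literature, and converted here to the
5-min decision periods the model actually runs on.  This module is the single
source of truth for units and conversions.

Units used throughout the package: energy in kJ, hypothermia depth in degrees
Celsius *below* the normothermic set point (so y = 0 means normothermic and
y = y_max is the deepest allowed hypothermia), time in periods of
24*60/periods_per_day minutes (5 min at the default 288 periods per day).
"""

from __future__ import annotations

import dataclasses
import io
import math
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

__all__ = [
    "ConfigError",
    "ValidationError",
    "ModelParams",
    "PerPeriodRates",
    "load_params",
    "loads_params",
    "parse_overrides",
    "serialize",
    "derive_per_period",
    "baseline_params",
    "preset",
]

#: day-time predation risk for hypothermic behaviours (4-6) is one of
#:   constant_high   -- a high, depth-independent hazard (baseline),
#:   linear_in_depth -- rest hazard plus a term growing linearly with depth,
#:   safe_as_rest    -- same hazard as resting in a safe spot.
RISK_MODES = ("constant_high", "linear_in_depth", "safe_as_rest")


class ConfigError(ValueError):
    """A configuration key is missing, unknown, or of the wrong type."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


@dataclass
class ModelParams:
    """Complete parameter set of the winter survival model.

    Defaults are the baseline values for a 10-13 g non-hoarding parid
    (blue-tit-like) in a boreal winter.
    """

    # --- state space -----------------------------------------------------
    x_max: float = 148.0          #: ceiling of fat reserves, kJ (~4 g fat)
    n_fat_steps: int = 100        #: number of fat grid intervals
    fat_energy_density: float = 37.0  #: kJ per g of fat
    y_max: float = 7.0            #: deepest hypothermia, degC below normal
    n_hypo_steps: int = 20        #: number of hypothermia grid intervals

    # --- time ------------------------------------------------------------
    n_days: int = 100             #: length of winter, days
    periods_per_day: int = 288    #: decision periods per 24 h (5-min default)
    extra_periods: int = 96       #: periods appended after the last midnight
    daylight_start: int = 96      #: first daylight period of the day (08:00)
    daylight_end: int = 192       #: first night period after daylight (16:00)
    t_f_day: int = 80             #: first day winter can end

    # --- energetics (per day) ---------------------------------------------
    gain_forage_high: float = 80.0   #: gross gain, intensive foraging, kJ/day
    gain_forage_low: float = 60.0    #: gross gain, cautious foraging, kJ/day
    food_multiplier: float = 1.0     #: food availability scaling on both gains
    resting_metabolism: float = 45.0  #: resting expenditure, kJ/day
    mu_forage: float = 2.0           #: activity multiplier while foraging
    bad_weather_multiplier: float = 1.2   #: expenditure factor in bad weather
    unsuccessful_gain: float = 0.8   #: gain fraction kept when foraging fails
    success_prob: float = 0.8        #: per-period foraging success probability

    # --- hypothermia -------------------------------------------------------
    epsilon: float = 0.3          #: max fraction of resting cost saved
    n_warmup_periods: int = 6     #: periods for a full transit of the y range
    warmup_cost: float = 0.0      #: extra total rewarming cost, kJ (0 or 6)

    # --- predation (per day / per night) -----------------------------------
    beta_forage_high: float = 2.5e-3   #: daily risk, intensive foraging, lean
    beta_forage_low: float = 1.25e-3   #: daily risk, cautious foraging, lean
    beta_rest: float = 2.5e-4          #: daily risk, resting in safety
    beta_hypo_day: float = 5.0e-2      #: daily risk, hypothermic in daylight
    beta_hypo_night: float = 3.7e-4    #: nightly risk, hypothermic at night
    x_cr: float = 37.0            #: fat load (kJ) above which risk accelerates
    alpha_exp: float = 3.0        #: exponent of the mass-dependent hazard

    # --- weather -----------------------------------------------------------
    p_gg: float = 0.9983          #: per-period persistence of good weather
    p_bb: float = 0.9965          #: per-period persistence of bad weather

    # --- forward simulation / presentation ---------------------------------
    x_start: float = 12.0         #: fat at the start of the forward iteration
    morning_mass_day1: float = 11.2   #: day-1 dawn body mass, g
    normal_body_temp: float = 42.0    #: normothermic body temperature, degC

    # --- variants -----------------------------------------------------------
    #: what the bad-weather multiplier gamma applies to.  "resting_component"
    #: scales only the resting-metabolism part of expenditure (cold raises
    #: thermoregulatory costs; the heat of activity substitutes for
    #: thermoregulation below thermoneutrality, so the foraging increment is
    #: weather-independent).  "total_cost" scales the whole per-period cost
    #: including the activity increment.
    bad_weather_scope: str = "resting_component"
    daytime_hypo_risk_mode: str = "constant_high"
    shallow_forage_limit: float = 0.0  #: forage allowed when y < limit (0 =
    #: only normothermic birds forage, the baseline assumption)

    _derived: "PerPeriodRates | None" = field(
        default=None, init=False, repr=False, compare=False
    )

    # -- helpers ------------------------------------------------------------

    def validate(self) -> "ModelParams":
        """Check all invariants; raise :class:`ValidationError` on failure."""
        p = self

        def check(cond: bool, msg: str) -> None:
            if not cond:
                raise ValidationError(msg)

        check(p.x_max > 0, "x_max must be positive")
        check(p.n_fat_steps >= 2, "n_fat_steps must be at least 2")
        check(p.fat_energy_density > 0, "fat_energy_density must be positive")
        check(p.y_max > 0, "y_max must be positive")
        check(p.n_hypo_steps >= 1, "n_hypo_steps must be at least 1")
        check(0.0 <= p.epsilon <= 1.0, "epsilon must lie in [0, 1]")
        check(0.0 < p.success_prob <= 1.0, "success_prob must lie in (0, 1]")
        check(
            p.bad_weather_multiplier >= 1.0,
            "bad_weather_multiplier must be at least 1",
        )
        check(
            0.0 < p.unsuccessful_gain <= 1.0,
            "unsuccessful_gain must lie in (0, 1]",
        )
        check(p.food_multiplier > 0, "food_multiplier must be positive")
        check(0.0 < p.p_gg < 1.0, "p_gg must lie in (0, 1)")
        check(0.0 < p.p_bb < 1.0, "p_bb must lie in (0, 1)")
        check(p.n_days >= 1, "n_days must be at least 1")
        check(p.periods_per_day >= 2, "periods_per_day must be at least 2")
        check(
            0 <= p.daylight_start < p.daylight_end <= p.periods_per_day,
            "daylight window must lie inside one day",
        )
        check(
            p.extra_periods == p.daylight_start,
            "extra_periods must equal daylight_start so that the final "
            "period of winter falls on a daybreak",
        )
        check(1 <= p.t_f_day <= p.n_days, "t_f_day must lie in [1, n_days]")
        check(
            1 <= p.n_warmup_periods <= p.n_hypo_steps,
            "n_warmup_periods must lie in [1, n_hypo_steps]",
        )
        check(p.warmup_cost >= 0, "warmup_cost must be non-negative")
        check(0 < p.x_start <= p.x_max, "x_start must lie in (0, x_max]")
        check(p.resting_metabolism > 0, "resting_metabolism must be positive")
        check(p.mu_forage >= 0, "mu_forage must be non-negative")
        check(p.gain_forage_high >= 0, "gain_forage_high must be non-negative")
        check(p.gain_forage_low >= 0, "gain_forage_low must be non-negative")
        for name in (
            "beta_forage_high",
            "beta_forage_low",
            "beta_rest",
            "beta_hypo_day",
            "beta_hypo_night",
        ):
            check(0.0 <= getattr(p, name) < 1.0, f"{name} must lie in [0, 1)")
        check(p.x_cr > 0, "x_cr must be positive")
        check(p.alpha_exp > 0, "alpha_exp must be positive")
        check(
            p.daytime_hypo_risk_mode in RISK_MODES,
            f"daytime_hypo_risk_mode must be one of {RISK_MODES}",
        )
        check(
            p.bad_weather_scope in ("resting_component", "total_cost"),
            "bad_weather_scope must be 'resting_component' or 'total_cost'",
        )
        check(
            0.0 <= p.shallow_forage_limit <= p.y_max,
            "shallow_forage_limit must lie in [0, y_max]",
        )
        check(
            p.morning_mass_day1 * p.fat_energy_density > p.x_start,
            "morning mass must exceed the mass of the starting fat load",
        )
        return self

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a validated copy with the given fields changed."""
        new = dataclasses.replace(self, **changes)
        new._derived = None
        return new.validate()

    @property
    def derived(self) -> "PerPeriodRates":
        if self._derived is None:
            self._derived = derive_per_period(self)
        return self._derived

    @property
    def lean_mass_g(self) -> float:
        """Lean body mass such that x_start corresponds to the day-1 mass."""
        return self.morning_mass_day1 - self.x_start / self.fat_energy_density


@dataclass(frozen=True)
class PerPeriodRates:
    """Per-period quantities derived from the daily entries of ModelParams.

    Daily predation risks convert by compounding, beta_period =
    1 - (1 - beta_daily)**(1/n), over the n periods the behaviour is
    available (daylight periods for foraging and day-time hazards, night
    periods for night hazards), so that surviving all n periods at the
    per-period hazard reproduces the daily value exactly.
    """

    n_daylight: int
    n_night: int
    n_periods_total: int
    c_rm_period: float            #: resting cost per period, kJ
    g_period_high: float          #: gross foraging gain per period, kJ
    g_period_low: float
    beta_forage_high_p: float
    beta_forage_low_p: float
    beta_rest_day_p: float
    beta_rest_night_p: float
    beta_hypo_day_p: float
    beta_hypo_night_p: float
    warmup_surcharge: float       #: extra cost per rewarming period, kJ


def _compound(daily: float, n: int) -> float:
    return 1.0 - (1.0 - daily) ** (1.0 / n)


def derive_per_period(params: ModelParams) -> PerPeriodRates:
    """Convert the per-day parameter entries into per-period rates."""
    p = params
    n_daylight = p.daylight_end - p.daylight_start
    n_night = p.periods_per_day - n_daylight
    return PerPeriodRates(
        n_daylight=n_daylight,
        n_night=n_night,
        n_periods_total=p.n_days * p.periods_per_day + p.extra_periods,
        c_rm_period=p.resting_metabolism / p.periods_per_day,
        g_period_high=p.gain_forage_high * p.food_multiplier / n_daylight,
        g_period_low=p.gain_forage_low * p.food_multiplier / n_daylight,
        beta_forage_high_p=_compound(p.beta_forage_high, n_daylight),
        beta_forage_low_p=_compound(p.beta_forage_low, n_daylight),
        beta_rest_day_p=_compound(p.beta_rest, n_daylight),
        beta_rest_night_p=_compound(p.beta_rest, n_night),
        beta_hypo_day_p=_compound(p.beta_hypo_day, n_daylight),
        beta_hypo_night_p=_compound(p.beta_hypo_night, n_night),
        warmup_surcharge=p.warmup_cost / p.n_warmup_periods,
    )


# ---------------------------------------------------------------------------
# loading / serialisation
# ---------------------------------------------------------------------------

_FIELD_TYPES = {
    f.name: f.type for f in fields(ModelParams) if not f.name.startswith("_")
}


def _coerce(key: str, value: Any) -> Any:
    """Coerce a raw config value to the field's declared type."""
    want = _FIELD_TYPES[key]
    if want == "int":
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"key {key!r} must be an integer, got {value!r}")
        return value
    if want == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"key {key!r} must be a number, got {value!r}")
        value = float(value)
        if not math.isfinite(value):
            raise ConfigError(f"key {key!r} must be finite, got {value!r}")
        return value
    if want == "str":
        if not isinstance(value, str):
            raise ConfigError(f"key {key!r} must be a string, got {value!r}")
        return value
    raise ConfigError(f"unsupported key {key!r}")  # pragma: no cover


def _from_mapping(mapping: Mapping[str, Any]) -> ModelParams:
    kwargs = {}
    for key, value in mapping.items():
        if key not in _FIELD_TYPES:
            raise ConfigError(f"unknown configuration key: {key!r}")
        kwargs[key] = _coerce(key, value)
    return ModelParams(**kwargs).validate()


def loads_params(text: str) -> ModelParams:
    """Parse a TOML configuration string.  Unspecified keys take defaults."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse configuration: {exc}") from exc
    return _from_mapping(data)


def load_params(
    source: str | Path | Mapping[str, Any] | None = None,
    overrides: list[str] | None = None,
) -> ModelParams:
    """Load and validate model parameters.

    Parameters
    ----------
    source
        ``None`` for all-baseline values, a mapping of key -> value, or the
        path of a TOML file.  Every key must name a :class:`ModelParams`
        field; unspecified keys take their baseline defaults.
    overrides
        Optional ``["key=value", ...]`` strings (the CLI's ``--set``) applied
        on top of the source.
    """
    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        path = Path(source)
        try:
            data = tomllib.loads(path.read_text())
        except FileNotFoundError:
            raise ConfigError(f"configuration file not found: {path}")
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if overrides:
        data.update(parse_overrides(overrides))
    return _from_mapping(data)


def parse_overrides(pairs: list[str]) -> dict[str, Any]:
    """Parse ``key=value`` override strings (values in TOML syntax)."""
    out: dict[str, Any] = {}
    for pair in pairs:
        key, sep, raw = pair.partition("=")
        key = key.strip()
        if not sep or not key:
            raise ConfigError(f"override must look like key=value: {pair!r}")
        try:
            parsed = tomllib.loads(f"v = {raw.strip()}")["v"]
        except tomllib.TOMLDecodeError:
            parsed = raw.strip()  # bare string, e.g. --set mode=safe_as_rest
        out[key] = parsed
    return out


def serialize(params: ModelParams) -> str:
    """Serialise parameters to TOML text; round-trips through load."""
    buf = io.StringIO()
    for f in fields(ModelParams):
        if f.name.startswith("_"):
            continue
        value = getattr(params, f.name)
        if isinstance(value, str):
            buf.write(f'{f.name} = "{value}"\n')
        elif isinstance(value, float):
            buf.write(f"{f.name} = {value!r}\n")
        else:
            buf.write(f"{f.name} = {value}\n")
    return buf.getvalue()


def baseline_params() -> ModelParams:
    """The full baseline parameterisation (100-day winter)."""
    return ModelParams().validate()


def preset(name: str) -> ModelParams:
    """Named parameter presets.

    ``full``
        The 100-day baseline winter.
    ``ci``
        A scaled-down 20-day winter on a coarse state grid (12 fat steps,
        4 hypothermia steps) for fast test runs; per-period rates are
        unchanged so the behavioural structure is preserved.
    """
    if name == "full":
        return baseline_params()
    if name == "ci":
        return ModelParams(
            n_days=20,
            n_fat_steps=12,
            n_hypo_steps=4,
            n_warmup_periods=4,
            t_f_day=16,
        ).validate()
    raise ConfigError(f"unknown preset: {name!r}")
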