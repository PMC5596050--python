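# Model and methods

## The model

`winterbird` implements a dynamic state variable model of a small (10–13 g)
non-hoarding parid wintering in the boreal zone.  The bird's state is

* `x` — fat reserves in kJ, on a uniform grid over [0, 148] kJ (≈ 4 g fat,
  37 kJ/g); `x ≤ 0` is death by starvation, and the ceiling is far above
  anything an optimal bird carries;
* `y` — hypothermic depth in °C below the normothermic 42 °C, on a uniform
  grid over [0, 7]; energetically only the *saving fraction* `ε·y/y_max`
  matters, the °C axis is presentation;
* `w` — weather, a two-state Markov chain (good/bad) whose only effect is a
  multiplicative increase `γ = 1.2` of expenditure in bad weather;
* `t` — time, in 5-minute decision periods: 288 per day, 100 days, plus 96
  periods after the last midnight so the horizon falls on a daybreak
  (28,896 periods in total; daylight is 08:00–16:00, periods 96–191 of
  each day).

Each period the bird picks one of six behaviours: intensive foraging,
cautious foraging (daylight and normothermia only), resting in a safe spot
(normothermia only), deepening hypothermia, rewarming, or holding depth.
`F_w(x, y, t)` — the maximum probability of surviving to the end of winter
— is computed by backward induction

    F_w(x,y,t) = max_i (1 − β_i) · E[ F_{w'}(x', y', t+1) ],

where the expectation runs over foraging success (probability λ = 0.8 of
the full gain, otherwise a fraction δ = 0.8 of it) and the weather
transition, and `β_i` is the per-period predation hazard of behaviour `i`.
The winter's end is uncertain: it ends on the morning after any of the last
21 nights with equal probability, implemented as a per-candidate-daybreak
hazard 1/(candidates remaining).  A bird alive at that moment survives iff
it can still pay for rewarming from its current depth
(`x ≥ x_C(y) = (y/y_max)·C_WU + n_rewarm(y)·C_RM_period`).  A cohort
(1000 birds by default) is then simulated forward under the stored policy.

## Energetics

All rates are entered per day and divided into periods.  Resting
metabolism is 45 kJ/day (`C_RM_period = 0.15625` kJ).  A forager pays
`C_RM·(1 + μ + μ·x/x_max)` with μ = 2 — three times resting when lean,
five times when maximally fat — and gains gross 80 (intensive) or 60
(cautious) kJ per 8-h day, scaled by the food multiplier Δ.  A hypothermic
bird pays `C_RM·(1 − ε·y/y_max)`, i.e. saves up to ε = 30 % of resting
expenditure at the deepest depth; a rewarming bird additionally pays
`C_WU/6` per period (C_WU = 0 or 6 kJ).

**Scope of the bad-weather factor.**  Two readings of "bad weather raises
expenditure by 20 %" are possible: scale the *whole* per-period cost, or
scale only its resting-metabolism component.  Physiologically the second
is the sound one — cold raises thermoregulatory costs, while the heat
produced by foraging movement substitutes for thermoregulation below
thermoneutrality (the same substitution argument that motivates the low
activity multiplier μ = 2).  The first reading is also quantitatively
self-defeating here: a fully bad day then runs a ≈13 kJ deficit, and with
~1/3 of days bad the whole cohort starves at any saving level, leaving no
starvation–predation trade-off to study.  The package therefore defaults
to `bad_weather_scope = "resting_component"`: γ multiplies the
resting-metabolism part of every cost (which is the entire cost for
resting and hypothermic behaviours, so those are identical under both
readings) while the foraging activity increment is weather-independent.
The all-cost scaling remains available as `bad_weather_scope =
"total_cost"`.

## Predation

Daily hazards (Table values) are converted to per-period hazards by
compounding, `β_p = 1 − (1 − β_daily)^(1/n)`, over the periods the
behaviour is available — 96 daylight periods for foraging/day hazards,
192 night periods for night hazards — so that surviving the whole block
reproduces the daily value exactly.  Above a critical fat load
`x_cr = 37` kJ (1 g of fat) every daylight hazard of an active bird is
multiplied by `1 + ((x − x_cr)/x_cr)^α`; the exponent is not fixed by the
source and defaults to `alpha_exp = 3` (an accelerating, cubic agility
cost), exposed in the configuration.

Hypothermic birds in daylight are conspicuous and slow: the baseline mode
(`constant_high`) gives behaviours 4–6 a flat 5×10⁻² per-day hazard in
daylight.  Variants: `linear_in_depth` (the resting hazard plus a
depth-proportional share of the high hazard) and `safe_as_rest`.  At
night, hypothermic sleep carries 3.7×10⁻⁴ per night versus 2.5×10⁻⁴ for
normothermic sleep; that ~50 % lethargy surcharge is the predation cost
that makes shallow savings not worth having and drives the abandonment
threshold measured by the saving scan.

## Hypothermia dynamics

Depth moves at a fixed rate: a full transit of the y range takes
`n_warmup_periods = 6` periods (30 min), the only rate consistent with
rewarming beginning about half an hour before dawn.  Because 6 does not
divide the 20-step presentation grid, transitions follow a "ladder" of
rounded grid nodes (0, 3, 7, 10, 13, 17, 20 at baseline): every
transition lands exactly on a node, down-then-up returns to the same
rung, and no interpolation in y is ever needed.  Off-ladder nodes
(unreachable from a normothermic start) step to the nearest rung in the
direction of movement.  Behaviours 4/5 pay the period at the post-change
depth, and a behaviour-4 choice in daylight puts the bird in the
hypothermic risk class that same period.

## Numerics

* **Interpolation.**  Per-period fat changes (~0.1–0.8 kJ) are far smaller
  than the 1.48 kJ fat grid step, and the value function is evaluated off
  the grid ~29,000 times along a trajectory.  Composing *linear*
  interpolation that often against the absorbing starvation node acts as
  numerical diffusion and collapses the value function (measured: F at
  the start state 6× below the simulated survival of its own policy).
  The fat axis therefore uses monotone (Fritsch–Carlson) cubic
  interpolation: linear data are reproduced exactly, interpolants never
  overshoot the bracketing nodes, and forward simulation agrees with the
  backward value within Monte-Carlo error on fine grids.  On a model
  whose dynamics land exactly on nodes (no interpolation at all) the two
  agree within 1 SE at N = 200,000, which isolates interpolation as the
  only approximation.
* **Grid refinement.**  With the cubic scheme, backward value and forward
  survival converge to each other as the fat grid is refined (gap ≈ +0.09
  at 100 steps, +0.013 at 400 steps on a 20-day test winter).  Absolute
  survival numbers are therefore read on a 400-step fat grid; the
  policy-structure scans (saving and food-availability thresholds), which
  compare variants against each other, run on the native 100-step grid.
* **Tie-breaking.**  Behaviours are evaluated in the order (3, 2, 1, 4,
  5, 6) — lower predation risk first, then lower index — and a strictly
  greater value is required to displace the incumbent, so policies are
  deterministic and reproducible.
* **Batching.**  Variants that share the lattice (saving sweeps, food
  sweeps, the rewarming-cost contrast) are solved together with a leading
  batch axis; chunks are sized so the stored policy stays ≈0.5 GB.
* **Forward simulation.**  One seeded PCG64 stream per cohort with fully
  vectorised per-period draws; runs are reproducible given (seed, cohort
  size).  Birds look up the policy at the nearest fat node but carry
  continuous fat.  Mid-winter summaries use day 40 by default: safely
  after the start-up transient (the policy stabilises within the first
  week) and before the end window opens on day 80.

## What the model does and does not capture

The weather chain is a deliberately minimal source of unpredictability —
two states, time-homogeneous, no photoperiod or temperature trend; its
persistence values (0.9983/0.9965 per period) reproduce the intended 24-h
persistence of 61.3 % (good) and 36.4 % (bad).  Lean mass is constant
(10.88 g, so that 12 kJ of fat gives the 11.2 g day-1 dawn mass);
individual variation, immune or sleep costs of hypothermia, food
hoarding, and within-day temperature structure are out of scope.  Because
the daily energy budget is deliberately knife-edge (expected maximum
intake ≈ 77 kJ versus ≈ 75 kJ expenditure for a lean bird on a good day),
headline survival numbers are sensitive to the budget constants at the
1-kJ/day scale; thresholds and trajectory shapes are considerably more
robust than absolute survival probabilities.

## Known limitations

* The survival read at the start state retains a small positive
  discretisation bias on coarse fat grids (quantified above); use the
  refined grid for absolute numbers.
* The saving scan's "no hypothermia use" criterion is evaluated on a
  finite cohort (zero observed use), so its threshold is resolved only to
  the 1 % scan step.
* With `bad_weather_scope = "total_cost"` (bad weather scaling the whole
  per-period cost) the baseline winter is essentially unsurvivable; the
  option exists for comparison, not as a recommended configuration.
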