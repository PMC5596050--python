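import numpy as np
import pytest

from winterbird import behaviours as bh
from winterbird.config import baseline_params
from winterbird.grid import BAD, GOOD, build_grid
from winterbird.risk import build_risk_model, predation_hazard
from winterbird.solver import (
    backward_induction,
    expected_value,
    feasible_behaviours,
    solve_batch,
)

from conftest import naive_solve, toy_params


class TestFeasibility:
    def test_normothermic_daylight(self):
        p = baseline_params()
        assert feasible_behaviours(p, 0.0, 96) == {1, 2, 3, 4}

    def test_max_depth_at_night(self):
        p = baseline_params()
        assert feasible_behaviours(p, 7.0, 200) == {5, 6}

    def test_normothermic_night(self):
        p = baseline_params()
        assert feasible_behaviours(p, 0.0, 10) == {3, 4}

    def test_intermediate_depth_daylight(self):
        p = baseline_params()
        assert feasible_behaviours(p, 3.5, 100) == {4, 5, 6}

    def test_shallow_forage_variant(self):
        p = baseline_params().replace(shallow_forage_limit=2.0)
        assert feasible_behaviours(p, 1.05, 100) == {1, 2, 4, 5, 6}
        assert feasible_behaviours(p, 2.1, 100) == {4, 5, 6}


class TestExpectedValue:
    def test_certainty_propagates_without_hazard(self):
        p = toy_params(
            beta_forage_high=0.0,
            beta_forage_low=0.0,
            beta_rest=0.0,
            beta_hypo_day=0.0,
            beta_hypo_night=0.0,
        )
        grid = build_grid(p)
        risk = build_risk_model(p)
        F1 = np.ones((grid.n_fat + 1, grid.n_hypo + 1, 2))
        v = expected_value(F1, p, grid, risk, bh.REST, 5.0, 0.0, GOOD, 0)
        assert v == pytest.approx(1.0)

    def test_hazard_scales_certain_future(self):
        p = toy_params()
        grid = build_grid(p)
        risk = build_risk_model(p)
        F1 = np.ones((grid.n_fat + 1, grid.n_hypo + 1, 2))
        v = expected_value(F1, p, grid, risk, bh.FORAGE_HIGH, 5.0, 0.0, GOOD, 2)
        beta = float(predation_hazard(risk, bh.FORAGE_HIGH, 5.0, 0.0, True))
        assert v == pytest.approx(1.0 - beta)


TOY_VARIANTS = [
    {},
    {"warmup_cost": 2.0, "bad_weather_scope": "total_cost"},
    {"shallow_forage_limit": 1.0, "daytime_hypo_risk_mode": "linear_in_depth"},
    {"epsilon": 0.0, "daytime_hypo_risk_mode": "safe_as_rest"},
]


class TestAgainstReferenceSolver:
    @pytest.mark.parametrize("overrides", TOY_VARIANTS)
    def test_value_function_matches_direct_recursion(self, overrides):
        """The vectorised solver reproduces a plain state-by-state backward
        recursion on enumerable toy models to near machine precision."""
        p = toy_params(**overrides)
        F_ref, _ = naive_solve(p)
        res = backward_induction(p, store_F=True)
        got = res.F_full[:, 0]
        assert got.shape == F_ref.shape
        np.testing.assert_allclose(got, F_ref, atol=1e-12)

    @pytest.mark.parametrize("overrides", TOY_VARIANTS[:2])
    def test_policy_is_optimal_under_direct_recursion(self, overrides):
        """Every stored decision attains the reference maximum (checked via
        the reference expected values, robust to float ties)."""
        p = toy_params(**overrides)
        F_ref, _ = naive_solve(p)
        res = backward_induction(p, store_F=True)
        grid = res.grid
        risk = build_risk_model(p)
        T = grid.n_periods_total
        for t in range(T):
            for iy, y in enumerate(grid.hypo_values):
                feas = feasible_behaviours(p, y, t)
                for ix, x in enumerate(grid.fat_values):
                    if ix == 0:
                        continue
                    for w in (GOOD, BAD):
                        chosen = int(res.policy[t, 0, ix, iy, w])
                        assert chosen in feas
                        vals = {
                            b: expected_value(
                                F_ref[t + 1], p, grid, risk, b, x, y, w, t
                            )
                            for b in feas
                        }
                        assert vals[chosen] == pytest.approx(
                            max(vals.values()), abs=1e-12
                        )

    def test_terminal_base_case(self):
        """With a single-period horizon the value is the terminal reward."""
        p = toy_params()
        res = backward_induction(p, store_F=True)
        T = res.grid.n_periods_total
        from winterbird.winter_end import terminal_reward_array

        phi = terminal_reward_array(res.terminal, p, res.grid)
        np.testing.assert_array_equal(res.F_full[T, 0, :, :, GOOD], phi)
        np.testing.assert_array_equal(res.F_full[T, 0, :, :, BAD], phi)


class TestStructure:
    def test_values_are_probabilities_and_dead_row_is_zero(self):
        res = backward_induction(toy_params(), store_F=True)
        assert np.all(res.F_full >= 0.0)
        assert np.all(res.F_full <= 1.0)
        assert np.all(res.F_full[:, :, 0, :, :] == 0.0)

    def test_deterministic_tie_breaking(self):
        a = backward_induction(toy_params())
        b = backward_induction(toy_params())
        np.testing.assert_array_equal(a.policy, b.policy)
        np.testing.assert_array_equal(a.F_start, b.F_start)

    def test_batch_equals_individual_solves(self):
        """A heterogeneous batch gives bit-comparable values to separate
        single-variant solves (variants share the lattice and the
        foraging-feasibility structure, as the solver requires)."""
        variants = [
            toy_params(**ov)
            for ov in TOY_VARIANTS
            if "shallow_forage_limit" not in ov
        ]
        batch = solve_batch(variants, store_F=True)
        for v, p in enumerate(variants):
            single = backward_induction(p, store_F=True)
            np.testing.assert_allclose(
                batch.F_full[:, v], single.F_full[:, 0], atol=1e-13
            )
            np.testing.assert_array_equal(
                batch.policy[:, v], single.policy[:, 0]
            )

    def test_batch_rejects_mismatched_lattice(self):
        with pytest.raises(ValueError, match="lattice"):
            solve_batch([toy_params(), toy_params(n_fat_steps=6)])

    def test_policy_horizon_zero_skips_policy(self):
        res = backward_induction(toy_params(), policy_horizon=0)
        assert res.policy is None
        with pytest.raises(ValueError):
            res.policy_for(0)

    def test_start_value_is_interpolated_at_start_fat(self):
        p = toy_params()
        res = backward_induction(p)
        from winterbird.grid import interpolate_value

        slice_g = res.F_at[res.grid.daybreak_period(1)][0, :, 0, GOOD]
        assert res.F_start[0] == pytest.approx(
            interpolate_value(slice_g, p.x_start, res.grid.fat_step)
        )

    def test_survival_monotone_in_saving_fraction(self):
        """Hypothermia is optional, so a larger maximum saving can never
        reduce survival."""
        eps = [0.0, 0.25, 0.5, 0.75, 1.0]
        variants = [toy_params(epsilon=e) for e in eps]
        res = solve_batch(variants, policy_horizon=0)
        assert np.all(np.diff(res.F_start) >= -1e-12)
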