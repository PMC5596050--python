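import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from winterbird import behaviours as bh
from winterbird.config import baseline_params
from winterbird.energetics import activity_cost, fat_transition, hypothermic_cost
from winterbird.grid import BAD, GOOD


@pytest.fixture(scope="module")
def params():
    return baseline_params()


C_RM = 45.0 / 288.0


class TestActivityCost:
    def test_lean_forager_pays_three_times_resting(self, params):
        assert activity_cost(params, bh.FORAGE_HIGH, 0.0) == pytest.approx(
            3 * C_RM
        )

    def test_fat_forager_pays_five_times_resting(self, params):
        assert activity_cost(params, bh.FORAGE_HIGH, 148.0) == pytest.approx(
            5 * C_RM
        )

    def test_rest_pays_resting_metabolism(self, params):
        for x in (0.0, 50.0, 148.0):
            assert activity_cost(params, bh.REST, x) == pytest.approx(C_RM)

    def test_bad_weather_scales_resting_component_only(self, params):
        """Default scope: cold multiplies thermoregulation, not the
        activity increment."""
        got = activity_cost(params, bh.FORAGE_HIGH, 0.0, weather=BAD)
        assert got == pytest.approx(1.2 * C_RM + 2 * C_RM)

    def test_bad_weather_total_scope(self):
        p = baseline_params().replace(bad_weather_scope="total_cost")
        got = activity_cost(p, bh.FORAGE_HIGH, 0.0, weather=BAD)
        assert got == pytest.approx(1.2 * 3 * C_RM)

    def test_rest_cost_same_under_both_scopes(self):
        p = baseline_params().replace(bad_weather_scope="total_cost")
        q = baseline_params()
        assert activity_cost(p, bh.REST, 30.0, weather=BAD) == pytest.approx(
            float(activity_cost(q, bh.REST, 30.0, weather=BAD))
        )

    def test_hypothermic_behaviours_rejected(self, params):
        with pytest.raises(ValueError):
            activity_cost(params, bh.COOL, 10.0)


class TestHypothermicCost:
    def test_max_depth_saves_the_full_fraction(self, params):
        """At the deepest depth the bird saves exactly epsilon = 30% of
        resting expenditure."""
        assert hypothermic_cost(params, 7.0, GOOD) == pytest.approx(0.7 * C_RM)

    def test_normothermia_saves_nothing(self, params):
        assert hypothermic_cost(params, 0.0, GOOD) == pytest.approx(C_RM)

    def test_bad_weather_multiplies(self, params):
        assert hypothermic_cost(params, 7.0, BAD) == pytest.approx(
            0.7 * C_RM * 1.2
        )

    def test_warming_surcharge_pro_rated(self):
        p = baseline_params().replace(warmup_cost=6.0)
        base = hypothermic_cost(p, 3.5, GOOD)
        warm = hypothermic_cost(p, 3.5, GOOD, warming=True)
        assert warm - base == pytest.approx(1.0)  # 6 kJ over 6 periods

    def test_depth_out_of_range_raises(self, params):
        with pytest.raises(ValueError):
            hypothermic_cost(params, 7.5, GOOD)


class TestFatTransition:
    @pytest.mark.parametrize("behaviour", [bh.FORAGE_HIGH, bh.FORAGE_LOW])
    @pytest.mark.parametrize("weather", [GOOD, BAD])
    def test_foraging_has_four_outcomes_product_measure(
        self, params, behaviour, weather
    ):
        tr = fat_transition(params, behaviour, 30.0, 0.0, weather, daylight=True)
        assert len(tr.outcomes) == 4
        probs = sorted(o.probability for o in tr.outcomes)
        stay = params.p_gg if weather == GOOD else params.p_bb
        lam = params.success_prob
        expect = sorted(
            [lam * stay, lam * (1 - stay), (1 - lam) * stay, (1 - lam) * (1 - stay)]
        )
        assert probs == pytest.approx(expect)

    @pytest.mark.parametrize("behaviour", [bh.REST, bh.COOL, bh.WARM, bh.HOLD])
    def test_non_foraging_has_two_outcomes(self, params, behaviour):
        y = 0.0 if behaviour in (bh.REST, bh.COOL) else 7.0
        tr = fat_transition(params, behaviour, 30.0, y, GOOD, daylight=False)
        assert len(tr.outcomes) == 2

    @pytest.mark.parametrize("behaviour", list(bh.ALL))
    @pytest.mark.parametrize("weather", [GOOD, BAD])
    def test_probabilities_sum_to_one(self, params, behaviour, weather):
        y = 3.5 if behaviour in (bh.WARM, bh.HOLD) else 0.0
        tr = fat_transition(params, behaviour, 50.0, y, weather, daylight=True)
        assert sum(o.probability for o in tr.outcomes) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_unsuccessful_cautious_gain(self, params):
        """A failed cautious bout still yields delta * G: 60/96 * 0.8 = 0.5 kJ."""
        tr = fat_transition(params, bh.FORAGE_LOW, 30.0, 0.0, GOOD, daylight=True)
        gains = {
            round(o.next_fat - 30.0 + activity_cost(
                params, bh.FORAGE_LOW, 30.0, weather=o.next_weather
            ), 10)
            for o in tr.outcomes
        }
        assert round(0.5, 10) in gains
        assert round(60.0 / 96.0, 10) in gains

    def test_fat_is_capped_at_ceiling(self, params):
        tr = fat_transition(
            params, bh.FORAGE_HIGH, 147.9, 0.0, GOOD, daylight=True
        )
        assert all(o.next_fat <= params.x_max for o in tr.outcomes)

    def test_rest_decrements_by_resting_cost(self, params):
        tr = fat_transition(params, bh.REST, 30.0, 0.0, GOOD, daylight=False)
        decs = sorted(30.0 - o.next_fat for o in tr.outcomes)
        assert decs == pytest.approx([C_RM, C_RM * 1.2])

    def test_depth_change_prices_post_change_depth(self, params):
        tr = fat_transition(params, bh.COOL, 30.0, 0.0, GOOD, daylight=False)
        y1 = tr.outcomes[0].next_y
        assert y1 > 0
        good = next(o for o in tr.outcomes if o.next_weather == GOOD)
        assert 30.0 - good.next_fat == pytest.approx(
            hypothermic_cost(params, y1, GOOD)
        )

    def test_infeasible_behaviours_raise(self, params):
        with pytest.raises(ValueError):
            fat_transition(params, bh.FORAGE_HIGH, 30.0, 0.0, GOOD, daylight=False)
        with pytest.raises(ValueError):
            fat_transition(params, bh.FORAGE_HIGH, 30.0, 3.5, GOOD, daylight=True)
        with pytest.raises(ValueError):
            fat_transition(params, bh.REST, 30.0, 3.5, GOOD, daylight=False)

    def test_shallow_forage_variant_allows_hypothermic_foraging(self):
        p = baseline_params().replace(shallow_forage_limit=2.0)
        tr = fat_transition(p, bh.FORAGE_HIGH, 30.0, 1.75, GOOD, daylight=True)
        assert len(tr.outcomes) == 4
        with pytest.raises(ValueError):
            fat_transition(p, bh.FORAGE_HIGH, 30.0, 2.1, GOOD, daylight=True)

    @settings(max_examples=40, deadline=None)
    @given(
        x1=st.floats(1.0, 140.0),
        dx=st.floats(0.1, 5.0),
    )
    def test_next_fat_monotone_in_current_fat(self, params, x1, dx):
        """Per outcome branch, more fat now never means less fat next
        period (cost slope in x is below 1)."""
        a = fat_transition(params, bh.FORAGE_HIGH, x1, 0.0, GOOD, daylight=True)
        b = fat_transition(
            params, bh.FORAGE_HIGH, x1 + dx, 0.0, GOOD, daylight=True
        )
        for oa, ob in zip(a.outcomes, b.outcomes):
            assert ob.next_fat >= oa.next_fat - 1e-12


class TestDailyBudget:
    def test_expected_daily_net_gain_matches_accumulation(self, params):
        """Closed form for a lean bird foraging intensively all daylight in
        good weather versus an independent period-by-period accumulation."""
        d = params.derived
        lam, delta = params.success_prob, params.unsuccessful_gain
        closed = d.n_daylight * (
            d.g_period_high * (lam + (1 - lam) * delta) - 3 * d.c_rm_period
        )
        acc = 0.0
        for _ in range(d.n_daylight):
            gain = lam * d.g_period_high + (1 - lam) * d.g_period_high * delta
            acc += gain - float(activity_cost(params, bh.FORAGE_HIGH, 0.0))
        assert acc == pytest.approx(closed, abs=1e-9)
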