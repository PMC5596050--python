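import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from winterbird import behaviours as bh
from winterbird.config import baseline_params
from winterbird.risk import build_risk_model, mass_multiplier, predation_hazard


@pytest.fixture(scope="module")
def risk():
    return build_risk_model(baseline_params())


class TestMassDependence:
    def test_at_or_below_critical_mass_base_hazard(self, risk):
        for x in (0.0, 20.0, 37.0):
            assert predation_hazard(
                risk, bh.FORAGE_HIGH, x, 0.0, daylight=True
            ) == pytest.approx(risk.beta_forage_high)

    @pytest.mark.parametrize("alpha", [1.0, 2.0, 3.0, 7.0])
    def test_double_critical_mass_doubles_hazard(self, alpha):
        """At x = 2 x_cr the excess ratio is 1, so the hazard is exactly
        twice the base for any exponent."""
        r = build_risk_model(baseline_params().replace(alpha_exp=alpha))
        assert predation_hazard(
            r, bh.FORAGE_HIGH, 2 * r.x_cr, 0.0, daylight=True
        ) == pytest.approx(2 * r.beta_forage_high)

    @settings(max_examples=50, deadline=None)
    @given(x1=st.floats(0, 148), x2=st.floats(0, 148))
    def test_hazard_monotone_in_fat(self, risk, x1, x2):
        lo, hi = sorted((x1, x2))
        for b in (bh.FORAGE_HIGH, bh.FORAGE_LOW, bh.REST):
            assert predation_hazard(
                risk, b, hi, 0.0, daylight=True
            ) >= predation_hazard(risk, b, lo, 0.0, daylight=True)

    def test_multiplier_vectorised(self, risk):
        x = np.array([0.0, 37.0, 74.0, 148.0])
        m = mass_multiplier(risk, x)
        assert m[0] == 1.0 and m[1] == 1.0 and m[2] == 2.0
        assert m[3] == pytest.approx(1.0 + 3.0**3)


class TestActivityClasses:
    def test_daylight_ordering(self, risk):
        """Rest < cautious < intensive < hypothermic by day."""
        x = 10.0
        b3 = predation_hazard(risk, bh.REST, x, 0.0, daylight=True)
        b2 = predation_hazard(risk, bh.FORAGE_LOW, x, 0.0, daylight=True)
        b1 = predation_hazard(risk, bh.FORAGE_HIGH, x, 0.0, daylight=True)
        bh4 = predation_hazard(risk, bh.HOLD, x, 3.5, daylight=True)
        assert b3 < b2 < b1 < bh4

    def test_night_hypothermia_riskier_than_night_rest(self, risk):
        """A torpid bird is slower to flee a nocturnal predator than a
        normothermic sleeper."""
        rest = predation_hazard(risk, bh.REST, 10.0, 0.0, daylight=False)
        hypo = predation_hazard(risk, bh.HOLD, 10.0, 7.0, daylight=False)
        assert float(hypo) > float(rest)
        # per-night totals recover the configured nightly hazards
        p = baseline_params()
        assert 1 - (1 - float(rest)) ** 192 == pytest.approx(p.beta_rest)
        assert 1 - (1 - float(hypo)) ** 192 == pytest.approx(p.beta_hypo_night)

    def test_foraging_hazard_undefined_at_night(self, risk):
        with pytest.raises(ValueError):
            predation_hazard(risk, bh.FORAGE_HIGH, 10.0, 0.0, daylight=False)

    def test_unknown_behaviour(self, risk):
        with pytest.raises(ValueError):
            predation_hazard(risk, 7, 10.0, 0.0, daylight=True)


class TestDaytimeHypothermiaModes:
    def test_constant_high_ignores_depth_and_mass(self, risk):
        a = predation_hazard(risk, bh.HOLD, 5.0, 0.35, daylight=True)
        b = predation_hazard(risk, bh.HOLD, 120.0, 7.0, daylight=True)
        assert float(a) == float(b) == pytest.approx(risk.beta_hypo_day)

    def test_linear_mode_endpoints(self):
        r = build_risk_model(
            baseline_params().replace(daytime_hypo_risk_mode="linear_in_depth")
        )
        rest = predation_hazard(r, bh.REST, 10.0, 0.0, daylight=True)
        at0 = predation_hazard(r, bh.HOLD, 10.0, 0.0, daylight=True)
        atmax = predation_hazard(r, bh.HOLD, 10.0, 7.0, daylight=True)
        assert float(at0) == pytest.approx(float(rest))
        assert float(atmax) == pytest.approx(float(rest) + r.beta_hypo_day)

    def test_linear_mode_monotone_in_depth(self):
        r = build_risk_model(
            baseline_params().replace(daytime_hypo_risk_mode="linear_in_depth")
        )
        ys = np.linspace(0, 7, 21)
        h = [
            float(predation_hazard(r, bh.HOLD, 10.0, y, daylight=True))
            for y in ys
        ]
        assert np.all(np.diff(h) >= 0)

    def test_safe_as_rest_mode(self):
        r = build_risk_model(
            baseline_params().replace(daytime_hypo_risk_mode="safe_as_rest")
        )
        rest = predation_hazard(r, bh.REST, 40.0, 0.0, daylight=True)
        hypo = predation_hazard(r, bh.COOL, 40.0, 7.0, daylight=True)
        assert float(hypo) == pytest.approx(float(rest))

    def test_night_hazard_identical_across_modes(self):
        vals = []
        for mode in ("constant_high", "linear_in_depth", "safe_as_rest"):
            r = build_risk_model(
                baseline_params().replace(daytime_hypo_risk_mode=mode)
            )
            vals.append(
                float(predation_hazard(r, bh.HOLD, 10.0, 3.5, daylight=False))
            )
        assert vals[0] == vals[1] == vals[2]
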