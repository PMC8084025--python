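"""Development-rate curve: evaluation, rate summation, fitting, thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydricniche import devrate as dr
from hydricniche.errors import (
    InvalidInputError,
    NonCompletionError,
)
from hydricniche.synth import GeneratorConfig, gen_development_data


class TestRateFunction:
    def test_peak_rate_equals_b1(self, alba, vitellina):
        for p in (alba, vitellina):
            assert dr.dev_rate(p.b3, p) == pytest.approx(p.b1, rel=1e-6)

    def test_unimodal_with_argmax_at_b3(self, alba, vitellina):
        grid = np.arange(-5.0, 45.0, 0.01)
        for p in (alba, vitellina):
            rates = dr.dev_rate(grid, p)
            assert np.all(np.isfinite(rates)) and np.all(rates >= 0)
            assert abs(grid[np.argmax(rates)] - p.b3) <= 0.01

    def test_strictly_decreasing_above_optimum(self, alba):
        # operational range: from the optimum up to where the rate vanishes
        grid = np.arange(alba.b3 + 0.01, alba.t_zero - 0.01, 0.01)
        rates = dr.dev_rate(grid, alba)
        assert np.all(np.diff(rates) < 0)

    def test_cold_tail_is_negligible(self, alba):
        assert dr.dev_rate(-40.0, alba) < 0.01 * alba.b1

    def test_hand_evaluated_value_at_28C(self, alba):
        # independent arithmetic: v=(28-23.33)/(23.33-8.94),
        # r = 3.02 * 10**(-v^2) * (1 - 5.3 v^2)
        assert dr.dev_rate(28.0, alba) == pytest.approx(1.0469226466320731, rel=1e-12)

    def test_nonfinite_temperature_rejected(self, alba):
        with pytest.raises(InvalidInputError):
            dr.dev_rate(float("nan"), alba)
        with pytest.raises(InvalidInputError):
            dr.dev_rate(float("inf"), alba)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"b1": -1.0, "b2": 8.0, "b3": 23.0, "b4": 5.0, "b5": 0.4},
            {"b1": 3.0, "b2": 25.0, "b3": 23.0, "b4": 5.0, "b5": 0.4},
            {"b1": 3.0, "b2": 8.0, "b3": 23.0, "b4": -1.0, "b5": 0.4},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            dr.RateCurveParams(**kwargs)


class TestPredictDuration:
    def test_constant_regime_equals_closed_form(self, alba, constant_regime):
        for temp in np.arange(10.0, 28.0, 0.5):
            rate = dr.dev_rate(temp, alba)
            if rate <= 0.1 * alba.b1:
                continue
            dur = dr.predict_duration(constant_regime(temp), alba)
            assert abs(dur - 100.0 / rate) / dur < 0.005

    def test_peak_constant_duration(self, alba, constant_regime):
        # 100 / b1 at the optimum
        dur = dr.predict_duration(constant_regime(23.33), alba)
        assert dur == pytest.approx(100.0 / 3.02, rel=1e-9)

    def test_square_wave_matches_brute_force(self, alba, square_wave_regime):
        regime = square_wave_regime(20.0, 25.0)
        dur = dr.predict_duration(regime, alba)
        # brute-force hour-by-hour accumulation, fully independent loop
        r_low, r_high = dr.dev_rate(20.0, alba), dr.dev_rate(25.0, alba)
        dev, hour = 0.0, 0
        while True:
            r = r_low if hour % 2 == 0 else r_high
            if dev + r / 24.0 >= 100.0:
                brute = (hour + (100.0 - dev) / (r / 24.0)) / 24.0
                break
            dev += r / 24.0
            hour += 1
        assert abs(dur - brute) < max(r_low, r_high) / 24.0  # one step's increment
        # and the square wave equals 100 / mean(rate)
        assert dur == pytest.approx(100.0 / ((r_low + r_high) / 2.0), rel=1e-3)

    def test_recycled_series_matches_repeated_series(self, alba):
        one_day = tuple(21.0 + 2.5 * math.sin(2 * math.pi * h / 24) for h in range(24))
        short = dr.IncubationRegime("short", "fluctuating", hourly_temps=one_day)
        long = dr.IncubationRegime("long", "fluctuating", hourly_temps=one_day * 10)
        assert dr.predict_duration(short, alba) == pytest.approx(
            dr.predict_duration(long, alba), rel=1e-12
        )

    def test_entirely_nonviable_regime_raises(self, alba, constant_regime):
        with pytest.raises(NonCompletionError):
            dr.predict_duration(constant_regime(45.0), alba)

    def test_invalid_step(self, alba, constant_regime):
        with pytest.raises(InvalidInputError):
            dr.predict_duration(constant_regime(20.0), alba, step_hours=0.0)


class TestFitRateCurve:
    def test_zero_noise_recovery(self, alba):
        cfg = GeneratorConfig(seed=3, duration_noise_sd=0.0)
        regimes, obs = gen_development_data(cfg)
        fit = dr.fit_rate_curve(obs, regimes, fixed={"b5": 0.4})
        for name in ("b1", "b2", "b3", "b4"):
            truth = getattr(alba, name)
            assert abs(getattr(fit, name) - truth) < 1e-3 * abs(truth)
        assert fit.b5 == 0.4  # honoured exactly
        assert fit.rss < 1e-6

    def test_noisy_b3_recovery_within_published_se(self, alba):
        cfg = GeneratorConfig(seed=1)  # duration noise SD 1 day, 4 clutches/regime
        regimes, obs = gen_development_data(cfg)
        fit = dr.fit_rate_curve(obs, regimes, fixed={"b5": 0.4})
        assert abs(fit.b3 - alba.b3) <= 0.7
        assert fit.se is not None and all(v > 0 for v in fit.se.values())

    def test_fixed_b5_rss_at_least_free_rss(self):
        cfg = GeneratorConfig(seed=5)
        regimes, obs = gen_development_data(cfg)
        fixed = dr.fit_rate_curve(obs, regimes, fixed={"b5": 0.4})
        free = dr.fit_rate_curve(obs, regimes, fixed={})
        assert fixed.rss >= free.rss - 1e-6  # nested models

    def test_too_few_regimes_rejected(self, alba, constant_regime):
        obs = [
            dr.DevObservation(f"c{i}", "const20", 40.0 + i) for i in range(8)
        ]
        with pytest.raises(InvalidInputError):
            dr.fit_rate_curve(obs, [constant_regime(20.0)], fixed={"b5": 0.4})

    def test_too_few_observations_rejected(self, constant_regime):
        regimes = [constant_regime(t) for t in (15.0, 20.0, 25.0)]
        obs = [
            dr.DevObservation("c1", "const15", 60.0),
            dr.DevObservation("c2", "const20", 40.0),
            dr.DevObservation("c3", "const25", 37.0),
        ]
        with pytest.raises(InvalidInputError):
            dr.fit_rate_curve(obs, regimes, fixed={"b5": 0.4})


class TestThresholds:
    def test_published_parameters_reproduce_ctmax(self, alba, vitellina):
        assert dr.estimate_ctmax(alba).ct_max == pytest.approx(29.6, abs=0.1)
        assert dr.estimate_ctmax(vitellina).ct_max == pytest.approx(30.0, abs=0.1)

    def test_topt_is_b3_and_rule_recorded(self, alba):
        thr = dr.estimate_ctmax(alba)
        assert thr.t_opt == alba.b3
        assert thr.ct_max > thr.t_opt
        assert thr.ct_max_rule["criterion"] in ("exact-zero", "epsilon")
        assert thr.ct_max_rule["grid_step"] == 0.01

    def test_grid_convergence(self, alba):
        coarse = dr.estimate_ctmax(alba, grid_step=0.01).ct_max
        fine = dr.estimate_ctmax(alba, grid_step=0.005).ct_max
        assert abs(coarse - fine) < 0.01

    def test_monotone_nonincreasing_in_epsilon(self, alba):
        cts = [dr.estimate_ctmax(alba, epsilon=e).ct_max for e in (0.001, 0.01, 0.05, 0.2)]
        assert all(a >= b for a, b in zip(cts, cts[1:]))

    def test_warming_tolerance(self):
        assert dr.warming_tolerance(29.6, 29.6) == 0.0
        assert dr.warming_tolerance(29.6, 23.2) == pytest.approx(6.4)
        assert dr.warming_tolerance(29.6, 30.0) == pytest.approx(-0.4)
        with pytest.raises(InvalidInputError):
            dr.warming_tolerance(float("nan"), 20.0)

    def test_thermal_safety_margin(self):
        assert dr.thermal_safety_margin(23.3, 23.3) == 0.0
        assert dr.thermal_safety_margin(23.3, 18.0) == pytest.approx(5.3)
        assert dr.thermal_safety_margin(23.3, 25.0) == pytest.approx(-1.7)


@settings(deadline=None, max_examples=40)
@given(
    temp=st.floats(min_value=-5.0, max_value=44.0),
    b3=st.floats(min_value=15.0, max_value=30.0),
    width=st.floats(min_value=5.0, max_value=20.0),
    b4=st.floats(min_value=0.5, max_value=20.0),
)
def test_rate_never_exceeds_peak(temp, b3, width, b4):
    """Property: b1 is a global maximum of the rate curve."""
    params = dr.RateCurveParams(b1=3.0, b2=b3 - width, b3=b3, b4=b4, b5=0.4)
    assert dr.dev_rate(temp, params) <= params.b1 * (1 + 1e-12)
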