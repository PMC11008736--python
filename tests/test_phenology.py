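"""Rate function, hourly accumulation engine and closed-form oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricephen import (
    SeriesExhaustedError,
    SpeciesModel,
    StageParams,
    TemperatureSeries,
    accumulate_stage,
    closed_form_constant_period,
    development_rate,
    predict_generation_period,
)

from conftest import make_series


class TestDevelopmentRate:
    @pytest.mark.parametrize(
        "temp, expected",
        [
            (12.7, 0.0),  # exactly at the lower threshold
            (35.0, 0.0),  # at the critical maximum development ceases
            (40.0, 0.0),
            (5.0, 0.0),
            (25.0, (25.0 - 12.7) / 109.4),
            (30.0, (28.5 - 12.7) / 109.4),  # plateau between t_upper and t_stop
        ],
    )
    def test_nl_egg_branches(self, nl_model, temp, expected):
        assert development_rate(temp, nl_model.stage("egg")) == pytest.approx(expected)

    def test_vectorized_matches_scalar(self, nl_model):
        egg = nl_model.stage("egg")
        temps = np.linspace(-5, 45, 101)
        vec = development_rate(temps, egg)
        assert vec == pytest.approx([development_rate(t, egg) for t in temps])

    def test_continuous_at_t_upper_and_monotone_below_t_stop(self, all_stage_params):
        for _, p in all_stage_params:
            left = development_rate(p.t_upper - 1e-9, p)
            plateau = development_rate(p.t_upper, p)
            assert left == pytest.approx(plateau, abs=1e-9)
            grid = np.linspace(p.t_min - 5, p.t_stop - 1e-6, 400)
            rates = development_rate(grid, p)
            assert (rates >= 0).all()
            assert (np.diff(rates) >= -1e-12).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            StageParams("egg", t_min=20.0, t_upper=15.0, t_stop=35.0, k=100.0)
        with pytest.raises(ValueError):
            StageParams("egg", t_min=12.7, t_upper=28.5, t_stop=35.0, k=0.0)


class TestAccumulateStage:
    def test_constant_temperature_matches_closed_form(self, nl_model):
        egg = nl_model.stage("egg")
        series = TemperatureSeries.constant(25.0, 24 * 20)
        result = accumulate_stage(series, egg, "2021-07-30")
        assert result.completed
        assert result.duration_days == pytest.approx(109.4 / 12.3, abs=1 / 24)

    def test_plateau_constant_temperature(self, nl_model):
        egg = nl_model.stage("egg")
        series = TemperatureSeries.constant(30.0, 24 * 15)  # t_upper <= T < t_stop
        result = accumulate_stage(series, egg, "2021-07-30")
        assert result.duration_days == pytest.approx(109.4 / 15.8, abs=1 / 24)

    def test_oracle_equivalence_all_stages(self, all_stage_params):
        # hourly engine vs K/(min(T, t_upper) - t_min) across the valid band
        for _, p in all_stage_params:
            for temp in np.arange(p.t_min + 2.0, p.t_stop - 0.2, 2.0):
                expected = p.k / (min(temp, p.t_upper) - p.t_min)
                series = TemperatureSeries.constant(temp, int(expected * 24) + 72)
                got = accumulate_stage(series, p, series.timestamps[0]).duration_days
                assert got == pytest.approx(expected, abs=1 / 24)

    def test_below_threshold_incomplete_with_zero_trace(self, nl_model):
        egg = nl_model.stage("egg")
        series = TemperatureSeries.constant(10.0, 24 * 30)
        result = accumulate_stage(series, egg, "2021-07-30")
        assert not result.completed
        assert result.cumulative_r_trace.max() == 0.0
        with pytest.raises(SeriesExhaustedError):
            _ = result.duration_days

    def test_trace_is_nondecreasing_and_reaches_one_iff_completed(self, nl_model):
        egg = nl_model.stage("egg")
        rng = np.random.default_rng(0)
        series = make_series(25.0 + 5 * rng.standard_normal(24 * 30))
        result = accumulate_stage(series, egg, "2021-07-31")
        assert (np.diff(result.cumulative_r_trace) >= -1e-12).all()
        assert result.completed == (result.cumulative_r_trace[-1] >= 1.0)

    def test_out_of_coverage_start_is_a_distinct_error(self, nl_model):
        egg = nl_model.stage("egg")
        series = TemperatureSeries.constant(25.0, 24)
        with pytest.raises(ValueError):
            accumulate_stage(series, egg, "2021-06-01")

    def test_subhour_completion_is_fractional(self, nl_model):
        egg = nl_model.stage("egg")
        series = TemperatureSeries.constant(25.0, 24 * 20)
        result = accumulate_stage(series, egg, "2021-07-30")
        frac = result.duration_days * 24 % 1
        assert 0 < frac < 1  # 213.46 h, not an integer hour count

    def test_degree_day_conservation_on_varying_series(self, nl_model):
        # independent recount: effective degree-days from start to the hour
        # before completion must equal K within one hourly increment
        egg = nl_model.stage("egg")
        rng = np.random.default_rng(7)
        temps = 24.0 + 4.0 * np.sin(np.arange(24 * 30) * 2 * np.pi / 24)
        temps += rng.normal(0, 1.0, temps.size)
        temps = np.clip(temps, None, egg.t_stop - 1.0)  # never reach t_stop
        series = make_series(temps)
        result = accumulate_stage(series, egg, series.timestamps[0])
        assert result.completed
        n_full = int((result.completion_time - result.start_time) / pd.Timedelta(hours=1))
        eff = np.clip(np.minimum(temps[:n_full], egg.t_upper) - egg.t_min, 0, None)
        assert eff.sum() / 24 == pytest.approx(egg.k, abs=(egg.t_upper - egg.t_min) / 24)


class TestGenerationPeriod:
    @pytest.mark.parametrize(
        "species, temp, expected",
        [
            ("N_lugens", 25.0, 109.4 / 12.3 + 194.9 / 13.7 + 35.9 / 13.6),
            ("L_striatellus", 25.0, 114.0 / 13.3 + 212.1 / 14.2 + 54.3 / 13.8),
            ("S_furcifera", 28.5, 78.0 / 15.9 + 178.9 / 17.3 + 65.2 / 17.8),
        ],
    )
    def test_constant_temperature_sum_of_stage_closed_forms(
        self, registry, species, temp, expected
    ):
        model = registry[species]
        series = TemperatureSeries.constant(temp, 24 * 45)
        got = predict_generation_period(series, model, "2021-07-30")
        assert got == pytest.approx(expected, abs=0.05)
        assert closed_form_constant_period(temp, model) == pytest.approx(expected)

    def test_closed_form_rejects_out_of_band(self, nl_model):
        with pytest.raises(ValueError):
            closed_form_constant_period(12.7, nl_model)  # at max stage t_min
        with pytest.raises(ValueError):
            closed_form_constant_period(35.0, nl_model)  # at min stage t_stop

    def test_closed_form_monotone_decreasing_in_band(self, nl_model):
        grid = np.arange(14.0, 28.0, 0.5)
        periods = [closed_form_constant_period(t, nl_model) for t in grid]
        assert all(b < a for a, b in zip(periods, periods[1:]))

    def test_series_exhaustion_propagates(self, nl_model):
        series = TemperatureSeries.constant(25.0, 24 * 10)  # too short for 25.76 d
        with pytest.raises(SeriesExhaustedError):
            predict_generation_period(series, nl_model, "2021-07-30")

    def test_stage_order_sensitivity_below_one_day(self, nl_model):
        # slowly varying season: chaining order changes the answer < 1 day
        days = np.arange(60).repeat(24)
        hod = np.tile(np.arange(24), 60)
        temps = 26.0 - 0.05 * days + 3.0 * np.sin(2 * np.pi * (hod - 9) / 24)
        series = make_series(temps)
        a = predict_generation_period(
            series, nl_model, "2021-07-30", stage_order=("preoviposition", "egg", "nymph")
        )
        b = predict_generation_period(
            series, nl_model, "2021-07-30", stage_order=("egg", "nymph", "preoviposition")
        )
        assert abs(a - b) < 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_warmer_series_never_lengthens_period(self, registry, seed):
        # pointwise-warmer temperatures within [t_min, t_upper] for every stage
        model = registry["N_lugens"]
        lo = max(p.t_min for p in model.stages)
        hi = min(p.t_upper for p in model.stages)
        rng = np.random.default_rng(seed)
        n = 24 * 60
        base = rng.uniform(lo + 0.5, hi - 2.0, n)
        warmer = np.minimum(base + rng.uniform(0.0, 1.5, n), hi - 0.1)
        p_base = predict_generation_period(make_series(base), model, "2021-07-30")
        p_warm = predict_generation_period(make_series(warmer), model, "2021-07-30")
        assert p_warm <= p_base + 1e-9

    def test_incomplete_species_model_rejected(self, nl_model):
        with pytest.raises(ValueError):
            SpeciesModel("N_lugens", stages=nl_model.stages[:2])
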