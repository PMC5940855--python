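"""Growth-model fitting, adjusted R^2, model selection and statistics."""

import numpy as np
import pandas as pd
import pytest

from spherodyn.dynamics import (
    FitError,
    ModelFit,
    adjusted_r2,
    aggregate_replicates,
    compare_all,
    compare_conditions,
    fit_model,
    select_best_model,
)


def _fits(model, feature, values_by_origin, adj=1.0):
    return [
        ModelFit(model=model, a=v, b=0.0, c=None, adj_r2=adj, r2=adj,
                 n_points=10, feature=feature, origin=o)
        for o, v in values_by_origin.items()
    ]


class TestFitModel:
    def test_exact_linear_interpolation(self):
        t = np.arange(10.0)
        fit = fit_model(t, 2 * t + 3, "linear")
        assert fit.a == pytest.approx(2.0)
        assert fit.b == pytest.approx(3.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_exact_quadratic_interpolation(self):
        t = np.arange(10.0)
        fit = fit_model(t, t**2, "quadratic")
        assert fit.a == pytest.approx(1.0)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-9)

    def test_exponential_recovers_generating_parameters(self):
        t = np.arange(0, 5.01, 0.5)
        fit = fit_model(t, 2.0 * np.exp(0.5 * t), "exponential")
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.b == pytest.approx(0.5, abs=1e-6)

    def test_exponential_needs_positive_values(self):
        t = np.arange(5.0)
        with pytest.raises(FitError, match="positive"):
            fit_model(t, -np.ones(5), "exponential", feature="area_px2")

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match=">="):
            fit_model([0, 1, 2], [1, 2, 3], "quadratic")

    def test_invalid_frames_dropped_pairwise(self):
        t = np.arange(8.0)
        y = 3 * t + 1
        y[2] = np.nan
        fit = fit_model(t, y, "linear")
        assert fit.n_points == 7
        assert fit.a == pytest.approx(3.0)

    def test_time_origin_shift_preserves_fit_quality(self):
        rng = np.random.default_rng(0)
        t = np.arange(20.0) / 4
        y = 1.5 * t**2 - 2 * t + 4 + rng.normal(0, 0.3, 20)
        for model in ("linear", "quadratic"):
            f0 = fit_model(t, y, model)
            f1 = fit_model(t + 11.0, y, model)
            assert f1.adj_r2 == pytest.approx(f0.adj_r2, abs=1e-9)
            if model == "quadratic":
                assert f1.a == pytest.approx(f0.a, abs=1e-9)

    def test_quadratic_r2_never_below_linear(self):
        rng = np.random.default_rng(1)
        t = np.arange(15.0)
        for _ in range(20):
            y = rng.normal(size=15).cumsum()
            assert (
                fit_model(t, y, "quadratic").r2
                >= fit_model(t, y, "linear").r2 - 1e-12
            )


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(0.0, 5.0, 10, 1) == 1.0

    def test_unexplained_variance_goes_negative(self):
        assert adjusted_r2(5.0, 5.0, 10, 1) < 0

    def test_hand_computed_value(self):
        # SS_res/SS_tot = 0.1, n = 85, k = 1
        assert adjusted_r2(0.1, 1.0, 85, 1) == pytest.approx(0.8987951807228916)

    def test_constant_series_undefined(self):
        assert np.isnan(adjusted_r2(0.0, 0.0, 10, 1))


class TestModelSelection:
    def test_highest_mean_adjusted_r2_wins(self):
        fits = (
            _fits("linear", "area_px2", {"r1": 1, "r2": 2}, adj=0.99)
            + _fits("quadratic", "area_px2", {"r1": 1, "r2": 2}, adj=0.80)
            + _fits("exponential", "area_px2", {"r1": 1, "r2": 2}, adj=0.70)
        )
        assert select_best_model(fits) == "linear"

    def test_tie_breaks_toward_simpler_model(self):
        fits = (
            _fits("linear", "f", {"r1": 1}, adj=0.9)
            + _fits("quadratic", "f", {"r1": 1}, adj=0.9)
            + _fits("exponential", "f", {"r1": 1}, adj=0.9)
        )
        assert select_best_model(fits) == "linear"

    def test_exponential_preferred_over_quadratic_on_tie(self):
        fits = _fits("quadratic", "f", {"r1": 1}, adj=0.9) + _fits(
            "exponential", "f", {"r1": 1}, adj=0.9
        )
        assert select_best_model(fits) == "exponential"

    def test_missing_replicate_fit_flags_feature(self):
        fits = _fits("linear", "f", {"r1": 1, "r2": 2}) + _fits(
            "quadratic", "f", {"r1": 1}
        )
        assert select_best_model(fits) is None


class TestComparisons:
    def test_identical_samples_give_t_zero_p_one(self):
        res = compare_conditions(
            {"a": _fits("linear", "f", {"r1": 1, "r2": 2, "r3": 3}),
             "b": _fits("linear", "f", {"r1": 1, "r2": 2, "r3": 3})},
            "a",
        )
        assert res.test == "t_test"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_one_way_anova(self):
        # groups {1,2,3}, {2,3,4}, {3,4,5}: SS_between = 6, SS_within = 6,
        # df = (2, 6) => F = 3.0, p = 0.125
        res = compare_conditions(
            {"a": _fits("linear", "f", {"r1": 1, "r2": 2, "r3": 3}),
             "b": _fits("linear", "f", {"r1": 2, "r2": 3, "r3": 4}),
             "c": _fits("linear", "f", {"r1": 3, "r2": 4, "r3": 5})},
            "a",
        )
        assert res.test == "anova"
        assert res.statistic == pytest.approx(3.0)
        assert res.p_value == pytest.approx(0.125)

    def test_underpowered_condition_skipped(self):
        with pytest.raises(FitError):
            compare_conditions(
                {"a": _fits("linear", "f", {"r1": 1}),
                 "b": _fits("linear", "f", {"r1": 1, "r2": 2})},
                "a",
            )

    def test_compare_all_tests_a_and_b_for_quadratic(self):
        rows = []
        for cond, base in (("x", 1.0), ("y", 2.0)):
            for i, rep in enumerate(("r1", "r2", "r3")):
                rows.append(
                    dict(condition=cond, replicate=rep, feature="perimeter_px",
                         model="quadratic", a=base + 0.1 * i,
                         b=base - 0.05 * i, c=0.0, adj_r2=0.9)
                )
        df = compare_all(
            pd.DataFrame(rows), {"perimeter_px": "quadratic"}, bh_correction=True
        )
        assert set(df.parameter) == {"a", "b"}
        assert "p_bh" in df.columns
        assert ((df.p_value >= 0) & (df.p_value <= 1)).all()


class TestAggregation:
    @staticmethod
    def _series(values):
        return [
            pd.DataFrame(
                {"frame": [0], "time_hours": [0.0], "core_radius_px": [v]}
            )
            for v in values
        ]

    def test_t_interval_matches_hand_computation(self):
        agg = aggregate_replicates(self._series([10, 12, 14]), "core_radius_px")
        assert agg["mean"][0] == pytest.approx(12.0)
        assert agg["ci_high"][0] - agg["mean"][0] == pytest.approx(
            4.9682754235006605
        )

    def test_single_replicate_band_collapses(self):
        agg = aggregate_replicates(self._series([10]), "core_radius_px")
        assert agg["ci_low"][0] == agg["ci_high"][0] == 10.0

    def test_identical_replicates_zero_width_band(self):
        agg = aggregate_replicates(self._series([7, 7, 7]), "core_radius_px")
        assert agg["ci_low"][0] == agg["ci_high"][0] == 7.0
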