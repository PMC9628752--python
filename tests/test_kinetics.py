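"""Growth-rate estimation, logistic light-response fitting and regimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppblight.kinetics import (
    CycleSeries,
    LightResponseModel,
    classify_regime,
    estimate_growth_rate,
    logistic,
    select_substrate_window,
    washout_rate,
)


def make_series(time, biomass, acetate=None, irradiance=100.0):
    if acetate is None:
        acetate = np.full(len(time), np.nan)
    return CycleSeries(
        condition_irradiance=irradiance,
        cycle_id="c1",
        time=np.asarray(time, float),
        biomass=np.asarray(biomass, float),
        acetate=np.asarray(acetate, float),
    )


def grid_search_logistic(x, y, a_grid, b_grid, c_grid):
    """Brute-force least-squares oracle over an explicit parameter grid."""
    best, best_rss = None, np.inf
    for a in a_grid:
        for b in b_grid:
            for c in c_grid:
                rss = float(np.sum((logistic(x, a, b, c) - y) ** 2))
                if rss < best_rss:
                    best, best_rss = (a, b, c), rss
    return best, best_rss


class TestGrowthRate:
    def test_one_per_hour_on_e_fold(self):
        s = make_series([0, 1], [1.0, np.e])
        assert estimate_growth_rate(s).mu == pytest.approx(1.0)

    def test_no_growth(self):
        s = make_series([0, 2, 4], [1.5, 1.5, 1.5])
        assert estimate_growth_rate(s).mu == pytest.approx(0.0)

    def test_doubling_over_reaction_phase(self):
        s = make_series([0, 4.68], [1.40, 2.80])
        assert estimate_growth_rate(s).mu == pytest.approx(np.log(2) / 4.68, rel=1e-9)
        assert estimate_growth_rate(s).mu == pytest.approx(0.148, abs=5e-4)

    def test_methods_agree_on_exponential_series(self):
        t = np.linspace(0, 4, 9)
        s = make_series(t, 0.7 * np.exp(0.21 * t))
        ep = estimate_growth_rate(s, method="endpoint").mu
        ll = estimate_growth_rate(s, method="log-linear-regression").mu
        assert ep == pytest.approx(0.21, rel=1e-9)
        assert ll == pytest.approx(ep, rel=1e-9)

    def test_negative_mu_for_decay(self):
        s = make_series([0, 2], [1.0, 0.5])
        assert estimate_growth_rate(s).mu < 0

    def test_errors(self):
        with pytest.raises(ValueError):
            estimate_growth_rate(make_series([0, 1], [1.0, 0.0]))  # zero biomass
        with pytest.raises(ValueError):
            estimate_growth_rate(make_series([0, 1, 2], [1, 2, 4]), window=(0, 0.5))

    def test_window_restricts_observations(self):
        t = np.array([0, 1, 2, 3, 4.0])
        x = np.concatenate([np.exp(0.3 * t[:3]), [np.exp(0.9), np.exp(0.9)]])
        est = estimate_growth_rate(make_series(t, x), window=(0, 2))
        assert est.mu == pytest.approx(0.3, rel=1e-9)
        assert est.n_points == 3

    def test_substrate_window_ends_at_depletion(self):
        t = np.arange(0, 5.0, 0.5)
        ace = np.maximum(3.35 - 1.5 * t, 0.0)
        s = make_series(t, np.exp(0.2 * t), ace)
        t0, t1 = select_substrate_window(s)
        assert t0 == 0.0
        assert t1 == pytest.approx(2.5)  # first sample with acetate below 5%

    def test_substrate_window_full_phase_without_depletion(self):
        t = np.arange(0, 5.0, 0.5)
        s = make_series(t, np.exp(0.01 * t), np.full(len(t), 3.0))
        assert select_substrate_window(s) == (0.0, t[-1])


class TestLogisticFit:
    def test_generative_identity(self):
        x = np.arange(0, 401, 25, dtype=float)
        y = logistic(x, 0.25, 0.03, 150.0)
        res = LightResponseModel(x, y).fit()
        assert res.converged
        assert res.params == pytest.approx([0.25, 0.03, 150.0], rel=1e-6)

    def test_midpoint_identity_exact(self):
        x = np.arange(0, 401, 25, dtype=float)
        y = logistic(x, 0.25, 0.03, 150.0) + 0.003 * np.sin(x)
        res = LightResponseModel(x, y).fit()
        assert res.predict(res.c) == pytest.approx(res.a / 2, rel=1e-12)

    def test_prediction_monotone_and_asymptotic(self):
        x = np.arange(0, 401, 25, dtype=float)
        res = LightResponseModel(x, logistic(x, 0.2, 0.02, 120.0)).fit()
        grid = np.linspace(0, 2000, 200)
        pred = res.predict(grid)
        assert np.all(np.diff(pred) >= -1e-15)
        assert pred[-1] == pytest.approx(res.a, rel=1e-4)

    def test_flat_data_degenerate_flag(self):
        # With c bounded inside the data range, flat data collapse onto the
        # b -> 0 ridge where the prediction is the constant a/2; the fitted
        # level must equal the data and the degeneracy must be flagged.
        x = np.array([0.0, 100.0, 250.0, 400.0])
        y = np.full(4, 0.2)
        res = LightResponseModel(x, y).fit()
        assert res.converged
        assert res.degenerate
        assert res.predict(x) == pytest.approx(y, abs=1e-4)
        # a grid-search oracle under the same bounds lands on the same ridge
        (a, b, _), rss = grid_search_logistic(
            x, y, np.linspace(0.05, 0.45, 81), [1e-6, 0.01, 0.1], np.linspace(0, 400, 21)
        )
        assert logistic(200.0, a, b, 200.0) == pytest.approx(0.2, abs=0.01)
        assert res.rss <= rss + 1e-12

    def test_four_point_fit_matches_grid_oracle(self):
        x = np.array([0.0, 100.0, 200.0, 350.0])
        y = logistic(x, 0.24, 0.02, 180.0)
        res = LightResponseModel(x, y).fit()
        (a, b, c), _ = grid_search_logistic(
            x,
            y,
            np.linspace(0.20, 0.28, 41),
            np.linspace(0.01, 0.03, 41),
            np.linspace(150, 210, 61),
        )
        assert res.a == pytest.approx(a, abs=0.002)  # oracle grid resolution
        assert res.b == pytest.approx(b, abs=0.0005)
        assert res.c == pytest.approx(c, abs=1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        x = np.arange(0, 401, 50, dtype=float)
        y = logistic(x, 0.22, 0.025, 170.0) + rng.normal(0, 0.005, len(x))
        res1 = LightResponseModel(x, y).fit()
        perm = rng.permutation(len(x))
        res2 = LightResponseModel(x[perm], y[perm]).fit()
        assert res1.params == pytest.approx(res2.params, rel=1e-8)

    def test_scale_consistency(self):
        rng = np.random.default_rng(11)
        x = np.arange(0, 401, 50, dtype=float)
        y = logistic(x, 0.22, 0.025, 170.0) + rng.normal(0, 0.005, len(x))
        res = LightResponseModel(x, y).fit()
        s = 0.1  # rescale the light axis (e.g. W m^-2 -> a supply-rate scale)
        res_s = LightResponseModel(x * s, y).fit()
        assert res_s.a == pytest.approx(res.a, rel=1e-4)
        assert res_s.c == pytest.approx(res.c * s, rel=1e-3)
        assert res_s.b == pytest.approx(res.b / s, rel=1e-3)

    def test_parameter_recovery_under_noise(self):
        # 9 light levels x 3 replicates, sigma = 0.01/h, many seeds
        x_levels = np.array([0, 3, 7, 15, 30, 87, 175, 264, 350], dtype=float)
        a_err, c_err = [], []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = np.repeat(x_levels, 3)
            y = logistic(x, 0.25, 0.025, 189.0) + rng.normal(0, 0.01, len(x))
            res = LightResponseModel(x, y).fit()
            a_err.append(abs(res.a - 0.25))
            c_err.append(abs(res.c - 189.0) / 189.0)
        assert np.median(a_err) < 0.02
        assert np.median(c_err) < 0.15

    def test_input_validation(self):
        with pytest.raises(ValueError):
            LightResponseModel([1, 2, 3], [0.1, 0.2, 0.3])  # <4 points
        with pytest.raises(ValueError):
            LightResponseModel([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])  # 1 distinct x
        with pytest.raises(ValueError):
            LightResponseModel([-1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4])

    def test_summary_reports_parameters(self):
        x = np.arange(0, 401, 50, dtype=float)
        res = LightResponseModel(x, logistic(x, 0.22, 0.02, 150.0)).fit()
        text = res.summary()
        assert "mu_max" in text and "K_L" in text and "converged: True" in text


class TestWashout:
    def test_srt_31h(self):
        assert washout_rate(31.0) == pytest.approx(0.0323, abs=5e-5)
        assert round(washout_rate(31.0), 2) == 0.03

    @pytest.mark.parametrize("srt, expected", [(1.0, 1.0), (50.0, 0.02)])
    def test_reciprocal(self, srt, expected):
        assert washout_rate(srt) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            washout_rate(0.0)


class TestRegime:
    def test_depleted_high_supply_is_acetate_limited(self):
        call = classify_regime(0.0, rEX=28.0, irradiance=350.0)
        assert call.regime == "acetate_limited"

    def test_residual_low_supply_is_light_limited(self):
        call = classify_regime(3.28, rEX=2.0, irradiance=3.0)
        assert call.regime == "light_limited"

    def test_dark(self):
        assert classify_regime(3.79, rEX=None, irradiance=0.0).regime == "dark"

    def test_rex_threshold_overrides_residual(self):
        # photon supply above threshold marks acetate limitation even with
        # measurable residual (transition condition)
        call = classify_regime(0.27, rEX=10.5, irradiance=87.0)
        assert call.regime == "acetate_limited"

    def test_missing_rex_falls_back_to_residual(self):
        assert classify_regime(0.01, rEX=None, irradiance=175.0).regime == "acetate_limited"
        assert classify_regime(1.5, rEX=None, irradiance=30.0).regime == "light_limited"

    def test_negative_residual_rejected(self):
        with pytest.raises(ValueError):
            classify_regime(-0.1, rEX=None, irradiance=10.0)


@settings(max_examples=50, derandomize=True)
@given(
    a=st.floats(0.05, 0.5),
    b=st.floats(0.005, 0.1),
    c=st.floats(10.0, 350.0),
)
def test_logistic_midpoint_and_bounds_property(a, b, c):
    assert float(logistic(c, a, b, c)) == pytest.approx(a / 2, rel=1e-12)
    x = np.linspace(0, 1000, 101)
    vals = logistic(x, a, b, c)
    assert np.all(vals >= 0) and np.all(vals <= a)
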