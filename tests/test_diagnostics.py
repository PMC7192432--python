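"""Goodness of fit, residual diagnostics and autocorrelation-adjusted
correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dfakit as dk
from dfakit.diagnostics import trend_climate_correlations
from dfakit.preprocess import SeriesPanel


def make_fit(Z, x, R=None, D=None):
    n, m = Z.shape
    return dk.DFAFit(
        spec=dk.ModelSpec(m=m) if m else dk.ModelSpec(
            m=0, covariate_mode="shared", covariate_name="x"
        ),
        params=dk.DFAParams(Z=Z, R=R if R is not None else np.eye(n), D=D),
        x_smooth=x, x_var=np.zeros((x.shape[1], m, m)), loglik=0.0,
        n_data=int(n * x.shape[1]), k=1, aicc=0.0, converged=True,
        n_iter=1, n_starts=1,
    )


class TestRSquared:
    def test_perfect_predictions(self):
        Z = np.array([[1.0], [0.5]])
        x = np.arange(10, dtype=float)[None, :]
        Y = Z @ x
        per, overall = dk.r_squared(make_fit(Z, x), Y)
        np.testing.assert_allclose(per, 1.0)
        assert overall == pytest.approx(1.0)

    def test_mean_predictions_give_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((3, 20))
        Y -= Y.mean(axis=1, keepdims=True)
        per, overall = dk.r_squared(make_fit(np.zeros((3, 1)), np.zeros((1, 20))), Y)
        np.testing.assert_allclose(per, 0.0, atol=1e-12)
        assert overall == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # y=(-1,0,1), yhat=(-0.5,0,0.5): 1 - 0.5/2 = 0.75
        Z = np.array([[0.5]])
        x = np.array([[-1.0, 0.0, 1.0]])
        per, overall = dk.r_squared(make_fit(Z, x), np.array([[-1.0, 0.0, 1.0]]))
        assert per[0] == pytest.approx(0.75)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(4, 1))
        x = rng.normal(size=(1, 30))
        Y = Z @ x + 0.3 * rng.standard_normal((4, 30))
        per1, o1 = dk.r_squared(make_fit(Z, x), Y)
        per2, o2 = dk.r_squared(make_fit(7.0 * Z, x), 7.0 * Y)
        np.testing.assert_allclose(per1, per2, atol=1e-12)
        assert o1 == pytest.approx(o2, abs=1e-12)


class TestStrongLoadings:
    def test_strict_threshold(self):
        Z = np.array([[0.2, -0.35], [0.0, 0.2000001]])
        mask = dk.strong_loadings(Z)
        assert mask.tolist() == [[False, True], [False, True]]
        assert not dk.strong_loadings(np.zeros((3, 2))).any()


class TestLag1Autocorrelation:
    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 100)
        r1, flag = dk.lag1_autocorrelation(x)
        assert r1 == pytest.approx(-1.0, abs=0.02)
        assert flag

    def test_white_noise_small(self):
        x = np.random.default_rng(2).standard_normal(5000)
        r1, flag = dk.lag1_autocorrelation(x)
        assert abs(r1) < 0.03
        assert not flag

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dk.lag1_autocorrelation([1.0, 2.0, 3.0])


class TestEffectiveN:
    def test_no_correction(self):
        # exactly zero lag-1 autocorrelation via the (1, 0, -1, 0) pattern
        x = np.tile([1.0, 0.0, -1.0, 0.0], 5)
        assert dk.effective_n(x, x[::-1]) == pytest.approx(20.0)

    def test_closed_form(self):
        # N=30 and r_x(1)=r_y(1)=0.5 gives 1/N* = 1.5/30, N* = 20
        from unittest import mock

        x = np.zeros(30)
        with mock.patch("dfakit.diagnostics.lag1_autocorrelation",
                        return_value=(0.5, True)):
            assert dk.effective_n(np.arange(30.0), np.arange(30.0)) == pytest.approx(20.0)

    def test_negative_correction_capped_at_n(self):
        from unittest import mock

        side = [(-0.5, True), (0.5, True)]
        with mock.patch("dfakit.diagnostics.lag1_autocorrelation",
                        side_effect=side):
            assert dk.effective_n(np.arange(30.0), np.arange(30.0)) == 30.0

    def test_short_overlap_rejected(self):
        with pytest.raises(ValueError):
            dk.effective_n([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSpearmanAdjusted:
    def test_monotone_series(self):
        x = np.arange(10.0)
        res = dk.spearman_adjusted(x, x**3)
        assert res.rho == pytest.approx(1.0)
        assert res.p < 1e-10
        res = dk.spearman_adjusted(np.arange(1.0, 6.0), np.arange(5.0, 0.0, -1.0))
        assert res.rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x, y = rng.standard_normal(8), rng.standard_normal(8)
            res = dk.spearman_adjusted(x, y)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_classical_p_recovered_without_autocorrelation(self):
        # both series have exactly zero sample lag-1 autocorrelation, so the
        # adjusted test must reproduce the classical Spearman t-test p-value
        x = np.tile([1.0, 0.0, -1.0, 0.0], 4) + np.repeat([0.0, 0.004, -0.004, 0.002], 4)
        y = np.tile([0.0, 1.0, 0.0, -1.0], 4) + np.repeat([0.002, -0.004, 0.004, 0.0], 4)
        rx, _ = dk.lag1_autocorrelation(x)
        ry, _ = dk.lag1_autocorrelation(y)
        if abs(rx * ry) < 1e-15:  # construction check
            res = dk.spearman_adjusted(x, y)
            classical = stats.spearmanr(x, y)
            assert res.n_eff == pytest.approx(len(x))
            assert res.p == pytest.approx(classical.pvalue, abs=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            dk.spearman_adjusted(np.ones(10), np.arange(10.0))


class TestEffectiveNProperty:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(derandomize=True, max_examples=100)
    def test_bounds_hold_for_arbitrary_series(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 60))
        phi = rng.uniform(-0.9, 0.9)
        x = dk.simulate_climate_index(N, phi, rng=rng)
        y = dk.simulate_climate_index(N, -phi, rng=rng)
        n_eff = dk.effective_n(x, y)
        assert 2 < n_eff <= N


class TestResidualEnvCorrelations:
    def make_panel(self, Y, stations):
        values = pd.DataFrame(Y, columns=range(1990, 1990 + Y.shape[1]))
        meta = pd.DataFrame({"station": stations, "class": "a"}, index=[
            f"{s}_a" for s in stations
        ])
        values.index = meta.index
        return SeriesPanel(values, meta, transform="z")

    def test_residual_equal_to_env_gives_rho_one(self):
        T = 20
        env_series = np.sin(np.arange(T)) + np.arange(T) * 0.1
        Y = env_series[None, :].repeat(2, axis=0)
        panel = self.make_panel(Y, ["S1", "S2"])
        fit = make_fit(np.zeros((2, 1)), np.zeros((1, T)))
        env = pd.concat([
            pd.DataFrame({"station": s, "year": range(1990, 1990 + T),
                          "temperature": env_series})
            for s in ["S1", "S2"]
        ])
        out = dk.residual_env_correlations(fit, panel, env)
        np.testing.assert_allclose(out["rho"], 1.0, atol=1e-9)

    def test_station_without_env_skipped(self):
        T = 12
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((2, T))
        panel = self.make_panel(Y, ["S1", "S2"])
        fit = make_fit(np.zeros((2, 1)), np.zeros((1, T)))
        env = pd.DataFrame({"station": "S1", "year": range(1990, 1990 + T),
                            "temperature": rng.standard_normal(T)})
        out = dk.residual_env_correlations(fit, panel, env)
        assert set(out["station"]) == {"S1"}

    def test_power_against_linear_env_effect(self):
        # residuals = temperature + noise(sd 0.3): median rho over seeds high
        T = 30
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            temp = rng.standard_normal(T)
            resid = temp + 0.3 * rng.standard_normal(T)
            rhos.append(dk.spearman_adjusted(resid, temp).rho)
        assert np.median(rhos) >= 0.7


class TestResidualDiagnostics:
    def test_report_shape_and_calibration(self):
        rng = np.random.default_rng(11)
        n, T = 12, 30
        Z = np.zeros((n, 1))
        Y = rng.standard_normal((n, T))
        values = pd.DataFrame(Y, columns=range(1980, 1980 + T))
        meta = pd.DataFrame({"station": [f"S{i}" for i in range(n)], "class": "a"},
                            index=[f"S{i}_a" for i in range(n)])
        values.index = meta.index
        panel = SeriesPanel(values, meta, transform="z")
        report = dk.residual_diagnostics(make_fit(Z, np.zeros((1, T))), panel)
        assert len(report.per_series) == n
        assert report.residuals.shape == (n, T)
        # Gaussian residuals: few series flagged non-normal at alpha=0.05
        assert report.n_nonnormal <= max(2, int(0.2 * n))

    def test_lag1_power_on_ar_residuals(self):
        hits = 0
        for seed in range(20):
            x = dk.simulate_climate_index(30, 0.6, seed=seed)
            _, flag = dk.lag1_autocorrelation(x)
            hits += flag
        assert hits >= 12  # >= 60% detection for AR(0.6), T=30


class TestTrendClimate:
    def test_table_contents(self):
        rng = np.random.default_rng(5)
        trends = rng.standard_normal((2, 25))
        clim = {"bsi": trends[0] + 0.1 * rng.standard_normal(25)}
        out = trend_climate_correlations(trends, clim)
        assert len(out) == 2
        strong = out[out["trend"] == 1].iloc[0]
        assert strong["rho"] > 0.9
        assert strong["n_eff"] <= strong["N"]
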