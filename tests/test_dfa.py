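"""DFA engine: parameter counting, exact Kalman inference, EM behaviour,
varimax rotation and fitted values."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import dfakit as dk
from dfakit.dfa import _groups_from_metadata, _init_params

# Published model grid for 68 class-by-station series (17 stations, 4
# classes): (R structure, trends, free parameters).
GRID_68 = [
    ("grouped-by-class", 3, 205),
    ("grouped-by-class", 4, 270),
    ("grouped-by-class", 2, 139),
    ("diagonal-equal", 3, 202),
    ("diagonal-equal", 2, 136),
    ("grouped-by-class", 1, 72),
    ("diagonal-equal", 4, 267),
    ("grouped-by-station", 2, 152),
    ("grouped-by-station", 3, 218),
    ("diagonal-equal", 1, 69),
    ("diagonal-unequal", 3, 269),
    ("diagonal-unequal", 4, 334),
    ("grouped-by-station", 4, 283),
    ("grouped-by-station", 1, 85),
    ("diagonal-unequal", 2, 203),
    ("diagonal-unequal", 1, 136),
]


def brute_force_loglik(Z, R, kappa, Y, D=None, d=None):
    """Joint-Gaussian oracle: build Cov(y) explicitly and evaluate it.

    With random-walk states started from N(0, kappa I),
    Cov(x_s, x_t) = (kappa + 1 + min(s, t)) I (s, t zero-based), so
    Cov(y_{i,s}, y_{j,t}) = z_i' z_j (kappa + 1 + min(s, t)) + delta_st R_ij.
    """
    n, T = Y.shape
    idx = [(i, t) for t in range(T) for i in range(n) if not np.isnan(Y[i, t])]
    cov = np.array(
        [
            [
                Z[i] @ Z[j] * (kappa + 1 + min(s, t)) + (R[i, j] if s == t else 0.0)
                for j, t in idx
            ]
            for i, s in idx
        ]
    )
    mean = np.array([D[i] * d[t] if D is not None else 0.0 for i, t in idx])
    y = np.array([Y[i, t] for i, t in idx])
    return multivariate_normal(mean=mean, cov=cov).logpdf(y)


class TestCountParameters:
    @pytest.mark.parametrize("rs,m,expected", GRID_68)
    def test_class_analysis_grid(self, rs, m, expected):
        spec = dk.ModelSpec(m=m, r_structure=rs)
        assert dk.count_parameters(spec, n=68, n_classes=4, n_stations=17) == expected

    def test_total_biomass_with_shared_covariate(self):
        spec = dk.ModelSpec(m=1, r_structure="diagonal-equal",
                            covariate_mode="shared", covariate_name="nao")
        assert dk.count_parameters(spec, n=17) == 19  # 17 loadings + 1 R + 1 D

    def test_covariate_parameter_increments(self):
        base = dk.ModelSpec(m=2, r_structure="diagonal-unequal")
        shared = dk.ModelSpec(m=2, r_structure="diagonal-unequal",
                              covariate_mode="shared", covariate_name="x")
        unique = dk.ModelSpec(m=2, r_structure="diagonal-unequal",
                              covariate_mode="unique", covariate_name="x")
        k0 = dk.count_parameters(base, n=20)
        assert dk.count_parameters(shared, n=20) == k0 + 1
        assert dk.count_parameters(unique, n=20) == k0 + 20

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            dk.ModelSpec(m=1, r_structure="chequered")


class TestKalman:
    def test_single_observation_closed_form(self):
        # n=1, m=1, T=1: y_1 ~ N(0, kappa + 1 + r)
        r, kappa, y = 0.7, 5.0, 1.3
        params = dk.DFAParams(Z=np.array([[1.0]]), R=np.array([[r]]), kappa=kappa)
        sm = dk.kalman_filter_smoother(params, np.array([[y]]))
        var = kappa + 1 + r
        expected = -0.5 * (np.log(2 * np.pi * var) + y**2 / var)
        assert sm.loglik == pytest.approx(expected, abs=1e-12)

    def test_matches_joint_gaussian_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n, m, T = int(rng.integers(1, 4)), int(rng.integers(1, 3)), int(rng.integers(1, 6))
            Z = rng.normal(size=(n, m))
            A = 0.4 * rng.normal(size=(n, n))
            R = A @ A.T + 0.3 * np.eye(n)
            Y = rng.normal(size=(n, T))
            Y[rng.random((n, T)) < 0.2] = np.nan
            if np.isnan(Y).all():
                continue
            sm = dk.kalman_filter_smoother(dk.DFAParams(Z=Z, R=R, kappa=5.0), Y)
            assert sm.loglik == pytest.approx(
                brute_force_loglik(Z, R, 5.0, Y), abs=1e-8
            )

    def test_missing_series_marginalizes(self):
        rng = np.random.default_rng(5)
        Z = np.array([[0.8], [0.5]])
        R = np.diag([0.3, 0.4])
        Y = rng.normal(size=(2, 12))
        Y[1] = np.nan  # series 2 entirely missing
        both = dk.kalman_filter_smoother(dk.DFAParams(Z=Z, R=R), Y)
        alone = dk.kalman_filter_smoother(
            dk.DFAParams(Z=Z[:1], R=R[:1, :1]), Y[:1]
        )
        assert both.loglik == pytest.approx(alone.loglik, abs=1e-10)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            dk.kalman_filter_smoother(
                dk.DFAParams(Z=np.ones((2, 1)), R=np.eye(2)), np.full((2, 4), np.nan)
            )


class TestEM:
    def test_monotone_loglik_across_structures(self, small_panel):
        Y, meta = small_panel["Y"], small_panel["meta"]
        for rs in ("diagonal-equal", "diagonal-unequal",
                   "equal-variance-covariance", "grouped-by-class"):
            spec = dk.ModelSpec(m=2, r_structure=rs)
            groups = _groups_from_metadata(spec, meta)
            params = _init_params(spec, Y.shape[0], np.random.default_rng(3), 5.0)
            lls = []
            for _ in range(40):
                sm = dk.kalman_filter_smoother(params, Y)
                lls.append(sm.loglik)
                params = dk.em_step(params, sm, Y, None, spec, groups)
            assert np.diff(lls).min() > -1e-8, rs

    def test_constrained_cells_stay_zero(self, small_panel):
        Y = small_panel["Y"]
        spec = dk.ModelSpec(m=3, r_structure="diagonal-unequal")
        params = _init_params(spec, Y.shape[0], np.random.default_rng(0), 5.0)
        for _ in range(15):
            sm = dk.kalman_filter_smoother(params, Y)
            params = dk.em_step(params, sm, Y, None, spec, None)
        upper = np.triu_indices(3, k=1)
        assert np.all(params.Z[upper] == 0.0)

    def test_fixed_point_near_truth_on_tiny_noise(self):
        # with essentially noise-free data, one step from the truth moves Z little
        rng = np.random.default_rng(8)
        X = dk.simulate_trends(1, 150, rng=rng)
        Z_true = rng.uniform(0.4, 0.9, size=(5, 1))
        Y = dk.simulate_observations(X, Z_true, 1e-6 * np.eye(5), rng=rng)
        spec = dk.ModelSpec(m=1, r_structure="diagonal-equal")
        params = dk.DFAParams(Z=Z_true.copy(), R=1e-6 * np.eye(5))
        sm = dk.kalman_filter_smoother(params, Y)
        updated = dk.em_step(params, sm, Y, None, spec, None)
        assert np.abs(updated.Z - Z_true).max() < 1e-3


class TestFit:
    def test_seeded_determinism(self, small_panel):
        Y = small_panel["Y"]
        spec = dk.ModelSpec(m=1, r_structure="diagonal-equal")
        a = dk.fit_dfa(Y, spec, n_starts=2, seed=7, max_iter=60)
        b = dk.fit_dfa(Y, spec, n_starts=2, seed=7, max_iter=60)
        assert a.loglik == b.loglik
        np.testing.assert_array_equal(a.params.Z, b.params.Z)
        np.testing.assert_array_equal(a.x_smooth, b.x_smooth)

    def test_mle_dominates_generating_parameters(self):
        rng = np.random.default_rng(21)
        X = dk.simulate_trends(1, 150, rng=rng)
        Z = rng.uniform(0.5, 1.0, size=(8, 1))
        R = 0.25 * np.eye(8)
        Y = dk.simulate_observations(X, Z, R, rng=rng)
        fit = dk.fit_dfa(Y, dk.ModelSpec(m=1, r_structure="diagonal-equal"),
                         n_starts=2, seed=0, max_iter=500)
        ll_truth = dk.kalman_filter_smoother(dk.DFAParams(Z=Z, R=R), Y).loglik
        assert fit.loglik >= ll_truth - 1e-6

    def test_trend_free_regression_recovers_shared_slope(self):
        rng = np.random.default_rng(9)
        T, n, b = 200, 6, 0.8
        d = dk.simulate_climate_index(T, 0.3, rng=rng)
        Y = np.outer(np.full(n, b), d) + 0.5 * rng.standard_normal((n, T))
        spec = dk.ModelSpec(m=0, r_structure="diagonal-equal",
                            covariate_mode="shared", covariate_name="idx")
        fit = dk.fit_dfa(Y, spec, covariates=d, n_starts=2, seed=0, max_iter=200)
        assert fit.params.D[0] == pytest.approx(b, abs=0.1)
        assert np.all(fit.params.D == fit.params.D[0])


class TestVarimax:
    def test_single_trend_identity_up_to_sign(self, small_panel):
        Y = small_panel["Y"]
        fit = dk.fit_dfa(Y, dk.ModelSpec(m=1, r_structure="diagonal-equal"),
                         n_starts=1, seed=0, max_iter=50)
        rot = dk.varimax_rotate(fit)
        assert rot.H.shape == (1, 1) and abs(abs(rot.H[0, 0]) - 1) < 1e-12
        assert rot.Z_rot.sum() >= 0  # sign convention

    def test_rotation_preserves_fitted_values(self, small_panel):
        Y = small_panel["Y"]
        fit = dk.fit_dfa(Y, dk.ModelSpec(m=2, r_structure="diagonal-equal"),
                         n_starts=1, seed=1, max_iter=80)
        rot = dk.varimax_rotate(fit)
        np.testing.assert_allclose(
            rot.Z_rot @ rot.x_rot, fit.params.Z @ fit.x_smooth, atol=1e-8
        )
        np.testing.assert_allclose(rot.H @ rot.H.T, np.eye(2), atol=1e-10)

    def test_criterion_matches_grid_search(self):
        # 2-column case: compare with brute-force maximization over angles
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(10, 2))

        def criterion(L):
            s = L**2
            return np.sum(s.var(axis=0))

        fit = dk.DFAFit(
            spec=dk.ModelSpec(m=2), params=dk.DFAParams(Z=Z, R=np.eye(10)),
            x_smooth=np.zeros((2, 5)), x_var=np.zeros((5, 2, 2)), loglik=0.0,
            n_data=50, k=1, aicc=0.0, converged=True, n_iter=1, n_starts=1,
        )
        rot = dk.varimax_rotate(fit)
        best = max(
            criterion(Z @ np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]))
            for a in np.linspace(0, 2 * np.pi, 20001)
        )
        assert criterion(rot.Z_rot) == pytest.approx(best, abs=1e-4)


class TestFittedValues:
    def test_noise_free_predictions_match_observations(self):
        rng = np.random.default_rng(2)
        X = dk.simulate_trends(1, 120, rng=rng)
        Z = rng.uniform(0.5, 1.0, size=(6, 1))
        Y = dk.simulate_observations(X, Z, 1e-6 * np.eye(6), rng=rng)
        fit = dk.fit_dfa(Y, dk.ModelSpec(m=1, r_structure="diagonal-equal"),
                         n_starts=3, seed=0, max_iter=400)
        pred = dk.fitted_values(fit)
        assert pred.shape == Y.shape
        assert np.abs(pred - Y).max() < 1e-2

    def test_trend_free_without_effect_predicts_zero(self):
        # m=0 and a zero covariate effect: the prediction is the z-scored mean
        rng = np.random.default_rng(3)
        d = rng.standard_normal(50)
        spec = dk.ModelSpec(m=0, r_structure="diagonal-equal",
                            covariate_mode="shared", covariate_name="x")
        fit = dk.DFAFit(
            spec=spec,
            params=dk.DFAParams(Z=np.zeros((4, 0)), R=np.eye(4), D=np.zeros(4)),
            x_smooth=np.zeros((0, 50)), x_var=np.zeros((50, 0, 0)), loglik=0.0,
            n_data=200, k=2, aicc=0.0, converged=True, n_iter=1, n_starts=1,
        )
        np.testing.assert_allclose(dk.fitted_values(fit, d), 0.0, atol=1e-12)
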