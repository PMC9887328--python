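import numpy as np
import pytest
from scipy.integrate import quad

import landmed as lm
from landmed.fpca import (
    conditional_scores,
    default_grid,
    eigendecompose,
    estimate_covariance,
    estimate_mean,
    integrate_trajectory,
    select_K,
    smooth_trajectory,
)

from conftest import analytic_eigensystem


def _dataset(trajs):
    pairs = tuple(
        (t, lm.SurvivalRecord(t.subject_id, 10.0, 1, 0)) for t in trajs
    )
    return lm.TrialDataset(pairs)


def _random_sparse(rng, n, fn, noise=0.0):
    trajs = []
    grid = default_grid()
    for i in range(n):
        k = rng.integers(3, 8)
        idx = np.sort(rng.choice(np.arange(1, 50), size=k, replace=False))
        t = np.concatenate([[0.0], grid[idx]])
        y = fn(t, i) + noise * rng.standard_normal(len(t))
        trajs.append(lm.SubjectTrajectory(f"s{i}", t, y))
    return _dataset(trajs)


class TestMean:
    def test_constant_trajectories_give_constant_mean(self):
        rng = np.random.default_rng(0)
        ds = _random_sparse(rng, 40, lambda t, i: np.full(len(t), 7.5))
        mean = estimate_mean(ds, bandwidth=0.1)
        np.testing.assert_allclose(mean, 7.5, atol=1e-8)

    def test_quadratic_mean_recovered_densely(self):
        # noiseless dense observations on the grid; small-bandwidth local linear
        grid = default_grid()
        f = lambda t: 1.0 + 2 * t - t**2
        trajs = [lm.SubjectTrajectory(f"s{i}", grid, f(grid)) for i in range(12)]
        mean = estimate_mean(_dataset(trajs), bandwidth=grid[1] - grid[0])
        assert np.max(np.abs(mean - f(grid))) < 1e-3

    def test_too_few_points_and_tiny_bandwidth_error(self):
        t = np.array([0.0, 0.5])
        ds = _dataset([lm.SubjectTrajectory("a", t, np.ones(2))])
        with pytest.raises(ValueError, match="pooled"):
            estimate_mean(ds)
        rng = np.random.default_rng(1)
        ds = _random_sparse(rng, 30, lambda t, i: np.ones(len(t)))
        with pytest.raises(ValueError, match="bandwidth"):
            estimate_mean(ds, bandwidth=1e-4)

    def test_mean_estimate_tightens_with_sample_size(self):
        errs = []
        for n, seed in ((100, 3), (1600, 5)):
            sim = lm.simulate_trial("a1", lm.SimConfig(n_subjects=n), seed=seed)
            es_mean = estimate_mean(sim.dataset)
            grid = default_grid()
            truth = sim.config.eta0(grid)  # eta1 = 0 in this setting, E[X] = 0
            errs.append(np.max(np.abs(es_mean - truth)))
        assert errs[1] < errs[0]
        assert errs[1] < 0.15


class TestCovariance:
    def test_white_noise_around_constant(self):
        rng = np.random.default_rng(7)
        ds = _random_sparse(rng, 500, lambda t, i: np.full(len(t), 2.0), noise=0.1)
        mean = estimate_mean(ds, bandwidth=0.15)
        surface, sigma2 = estimate_covariance(ds, mean, bandwidth=0.15)
        assert abs(sigma2 - 0.01) < 0.003  # within 30%
        assert np.max(np.abs(surface)) < 0.01

    def test_rank_one_process_recovered(self):
        rng = np.random.default_rng(8)
        lam = 2.0
        gammas = rng.normal(0, np.sqrt(lam), size=800)
        ds = _random_sparse(rng, 800, lambda t, i: np.full(len(t), gammas[i]), noise=0.01)
        mean = estimate_mean(ds, bandwidth=0.2)
        surface, _ = estimate_covariance(ds, mean, bandwidth=0.2)
        # G(s, t) ~ lam * rho(s) rho(t) with rho = 1; corners of the domain are
        # data-sparse, so assess the central 80%
        central = slice(5, 46)
        assert np.max(np.abs(surface[central, central] - lam)) < 0.3 * lam

    def test_surface_exactly_symmetric(self, trial_c):
        ds = trial_c.dataset
        mean = estimate_mean(ds, bandwidth=0.1)
        surface, _ = estimate_covariance(ds, mean, bandwidth=0.12)
        np.testing.assert_array_equal(surface, surface.T)

    def test_no_repeat_visits_unidentifiable(self):
        trajs = [
            lm.SubjectTrajectory(f"s{i}", np.array([0.1 * (i % 9)]), np.array([1.0]))
            for i in range(12)
        ]
        ds = _dataset(trajs)
        with pytest.raises(ValueError, match="2 visits"):
            estimate_covariance(ds, np.zeros(51))


class TestEigen:
    def test_rank_one_surface_recovery(self):
        grid = default_grid(101)
        rho = np.sqrt(2.0) * np.cos(np.pi * grid)
        rho /= np.sqrt(np.trapezoid(rho**2, grid))
        lam = 3.0
        es = eigendecompose(lam * np.outer(rho, rho), grid)
        assert es.eigenvalues[0] == pytest.approx(lam, abs=1e-6)
        sign = np.sign(np.dot(es.eigenfunctions[0], rho))
        np.testing.assert_allclose(sign * es.eigenfunctions[0], rho, atol=1e-6)
        if es.n_components > 1:
            assert es.eigenvalues[1] < 1e-8 * lam

    def test_orthonormality_under_trapezoid_weights(self, pace_c):
        grid = pace_c.grid
        Phi = pace_c.eigenfunctions
        gram = np.array([[np.trapezoid(a * b, grid) for b in Phi[:6]] for a in Phi[:6]])
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-6)

    def test_eigenvalues_nonincreasing_and_fve_monotone(self, pace_c):
        assert np.all(np.diff(pace_c.eigenvalues) <= 1e-12)
        assert np.all(pace_c.eigenvalues >= 0)
        assert np.all(np.diff(pace_c.fve) >= -1e-12)
        assert pace_c.fve[-1] == pytest.approx(1.0)

    def test_json_round_trip(self, pace_c, tmp_path):
        path = tmp_path / "es.json"
        pace_c.to_json(path)
        back = lm.EigenSystem.from_json(path)
        np.testing.assert_array_equal(back.eigenvalues, pace_c.eigenvalues)
        np.testing.assert_array_equal(back.eigenfunctions, pace_c.eigenfunctions)
        np.testing.assert_array_equal(back.mean, pace_c.mean)
        assert back.noise_variance == pace_c.noise_variance

    def test_all_nonpositive_surface_errors(self):
        grid = default_grid(21)
        with pytest.raises(ValueError, match="positive"):
            eigendecompose(-np.eye(21), grid)

    @pytest.mark.parametrize(
        "eigvals, thr, expected",
        [((9.0, 1.0), 0.9, 1), ((5.0, 4.0, 1.0), 0.9, 2), ((5.0, 4.0, 1.0), 1.0, 3)],
    )
    def test_select_K_threshold_rule(self, eigvals, thr, expected):
        es = analytic_eigensystem(lam=eigvals)
        es.fve = np.cumsum(eigvals) / np.sum(eigvals)
        assert select_K(es, thr) == expected


class TestScores:
    def test_zero_deviation_gives_zero_scores(self):
        es = analytic_eigensystem()
        subj = lm.SubjectTrajectory("a", es.grid, np.zeros_like(es.grid))
        ss = conditional_scores(subj, es, K=2)
        np.testing.assert_allclose(ss.scores, 0.0, atol=1e-6)

    def test_dense_noiseless_scores_match_inner_products(self):
        es = analytic_eigensystem(n_grid=401, sigma2=1e-8)
        y = 2.0 * es.eigenfunctions[0]
        subj = lm.SubjectTrajectory("a", es.grid, y)
        ss = conditional_scores(subj, es, K=2)
        # oracle: gamma_k = int (Y - mean) rho_k dt
        oracle = [np.trapezoid(y * es.eigenfunctions[k], es.grid) for k in range(2)]
        np.testing.assert_allclose(oracle, [2.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(ss.scores, oracle, atol=1e-3)

    def test_single_observation_shrinks_toward_zero(self):
        es = analytic_eigensystem(lam=(4.0, 1.0), sigma2=0.5)
        t0, y0 = 0.3, 1.7
        subj = lm.SubjectTrajectory("a", np.array([t0]), np.array([y0]))
        ss = conditional_scores(subj, es, K=1)
        phi = np.array([np.interp(t0, es.grid, p) for p in es.eigenfunctions])
        closed_form = es.eigenvalues[0] * phi[0] * y0 / (np.sum(es.eigenvalues * phi**2) + 0.5)
        assert ss.scores[0] == pytest.approx(closed_form, rel=1e-10)
        raw_projection = y0 * phi[0]  # |BLUP| < |raw|
        assert abs(ss.scores[0]) < abs(raw_projection)

    def test_window_saturation_equals_full_data(self, trial_c, pace_c):
        traj = trial_c.dataset.trajectories[0]
        full = conditional_scores(traj, pace_c, K=3)
        sat = conditional_scores(traj, pace_c, K=3, window_end=traj.last_time + 5.0)
        np.testing.assert_array_equal(full.scores, sat.scores)

    def test_no_pre_window_data_errors(self, trial_c, pace_c):
        traj = trial_c.dataset.trajectories[0]
        with pytest.raises(ValueError, match="window_end"):
            conditional_scores(traj, pace_c, K=1, window_end=0.0)


class TestReconstruction:
    def test_linearity_and_zero(self):
        es = analytic_eigensystem()
        zero = smooth_trajectory(lm.ScoreSet("a", np.zeros(2), 1.0), es)
        np.testing.assert_array_equal(zero, np.zeros_like(es.grid))
        two = smooth_trajectory(lm.ScoreSet("a", np.array([2.0, 0.0]), 1.0), es)
        np.testing.assert_allclose(two, 2.0 * es.eigenfunctions[0])
        with pytest.raises(ValueError, match="exceeds"):
            smooth_trajectory(lm.ScoreSet("a", np.zeros(2), 1.0), es, K=5)

    def test_reconstruction_error_decreases_in_K(self, trial_c, pace_c):
        traj = trial_c.dataset.trajectories[3]
        errs = []
        for K in (1, 3, 6):
            ss = conditional_scores(traj, pace_c, K=K)
            dhat = smooth_trajectory(ss, pace_c, K=K)
            yhat = pace_c.mean + dhat
            fitted = np.interp(traj.times, pace_c.grid, yhat)
            errs.append(np.mean((fitted - traj.values) ** 2))
        assert errs[2] <= errs[1] + 1e-9 and errs[1] <= errs[0] + 1e-9

    def test_integration_constant_linear_and_quad_oracle(self):
        grid = default_grid(201)
        assert integrate_trajectory(np.full_like(grid, 3.0), grid, 0.8) == pytest.approx(2.4, abs=1e-10)
        assert integrate_trajectory(grid.copy(), grid, 1.0) == pytest.approx(0.5, abs=1e-6)
        rng = np.random.default_rng(4)
        coef = rng.standard_normal(4)
        vals = coef[0] + coef[1] * grid + coef[2] * np.sin(3 * grid) + coef[3] * grid**2
        f = lambda t: coef[0] + coef[1] * t + coef[2] * np.sin(3 * t) + coef[3] * t**2
        oracle, _ = quad(f, 0, 0.63)
        assert integrate_trajectory(vals, grid, 0.63) == pytest.approx(oracle, abs=1e-4)
        with pytest.raises(ValueError):
            integrate_trajectory(vals, grid, 0.0)

    def test_fve_invariant_to_trajectory_rescaling(self, trial_c):
        ds = trial_c.dataset
        scaled = lm.TrialDataset(
            tuple(
                (lm.SubjectTrajectory(t.subject_id, t.times, 2.0 * t.values), s)
                for t, s in ds.subjects
            ),
            x_names=ds.x_names,
            z_names=ds.z_names,
        )
        es1 = lm.fit_pace(ds, mean_bandwidth=0.1, cov_bandwidth=0.12)
        es2 = lm.fit_pace(scaled, mean_bandwidth=0.1, cov_bandwidth=0.12)
        k = min(es1.n_components, es2.n_components, 5)
        np.testing.assert_allclose(es1.fve[:k], es2.fve[:k], atol=1e-8)
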