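import numpy as np
import pytest
from scipy.linalg import solve_sylvester
from scipy.optimize import minimize
from scipy.stats import ortho_group

from popwave import (
    PopulationPETH,
    RotationPlane,
    TimeGrid,
    finite_difference,
    fit_skew,
    jpca_pipeline,
    project_and_summarize,
    rotation_planes,
)


def circle_states(omega: float, dt: float, n: int, phase: float = 0.0) -> np.ndarray:
    t = dt * np.arange(n)
    return np.column_stack([np.cos(omega * t + phase), np.sin(omega * t + phase)])


def sylvester_skew(X: np.ndarray, Xdot: np.ndarray) -> np.ndarray:
    """Independent oracle: stationarity equation of the constrained problem."""
    A = X.T @ X
    return solve_sylvester(A, A, Xdot.T @ X - X.T @ Xdot)


class TestFiniteDifference:
    def test_linear_ramp_gives_constant_derivative(self):
        traj = np.outer(np.arange(10.0), np.array([2.0, -1.0]))
        X, Xdot = finite_difference(traj, dt=1.0)
        np.testing.assert_allclose(Xdot, np.tile([2.0, -1.0], (9, 1)))
        np.testing.assert_allclose(X, traj[:-1])

    def test_constant_trajectory_gives_zero_derivative(self):
        X, Xdot = finite_difference(np.ones((3, 7, 2)), dt=10.0)
        assert X.shape == Xdot.shape == (18, 2)
        np.testing.assert_array_equal(Xdot, 0.0)

    def test_first_order_convergence_on_sinusoid(self):
        omega = 0.01
        errs = []
        for dt in (1.0, 0.1):
            traj = circle_states(omega, dt, 200)
            X, Xdot = finite_difference(traj, dt)
            analytic = omega * np.column_stack([-X[:, 1], X[:, 0]])
            errs.append(np.abs(Xdot - analytic).max())
        assert errs[0] < 2 * omega * omega * 1.0  # O(dt) bound
        assert errs[1] < errs[0] / 5  # error shrinks with dt


class TestFitSkew:
    def test_recovers_planar_rotation_analytically(self):
        omega = 0.8
        X = circle_states(omega, 0.05, 400)
        Xdot = omega * np.column_stack([-X[:, 1], X[:, 0]])
        fit = fit_skew(X, Xdot)
        np.testing.assert_allclose(fit.M_skew, [[0.0, -omega], [omega, 0.0]], atol=1e-8)
        assert fit.r2_skew == pytest.approx(1.0, abs=1e-10)
        assert fit.r2_best - fit.r2_skew <= 1e-10

    def test_exact_antisymmetry_and_r2_ordering(self, rng):
        X = rng.standard_normal((300, 6))
        Xdot = rng.standard_normal((300, 6))
        fit = fit_skew(X, Xdot)
        assert np.abs(fit.M_skew + fit.M_skew.T).max() == 0.0
        assert fit.r2_skew <= fit.r2_best + 1e-12
        assert np.abs(fit.eigenvalues.real).max() <= 1e-10 * np.linalg.norm(fit.M_skew)

    def test_matches_sylvester_oracle(self, rng):
        X = rng.standard_normal((250, 6))
        Xdot = rng.standard_normal((250, 6))
        fit = fit_skew(X, Xdot)
        oracle = sylvester_skew(X, Xdot)
        np.testing.assert_allclose(fit.M_skew, oracle, atol=1e-6 * np.abs(oracle).max())

    def test_matches_direct_minimization_k3(self, rng):
        X = rng.standard_normal((80, 3))
        Xdot = rng.standard_normal((80, 3))
        fit = fit_skew(X, Xdot)

        def unpack(p):
            M = np.zeros((3, 3))
            M[0, 1], M[0, 2], M[1, 2] = p
            return M - M.T

        res = minimize(
            lambda p: np.sum((Xdot - X @ unpack(p).T) ** 2),
            np.zeros(3),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000, "maxfev": 50000},
        )
        np.testing.assert_allclose(fit.M_skew, unpack(res.x), atol=1e-6)

    def test_frequency_recovery_within_one_percent_at_1ms(self):
        # noiseless rotation, one full period sampled at 1 ms, derivatives
        # from the forward difference: first-order scheme, error < 1%
        omega_true = 2 * np.pi / 600.0
        errors = []
        for dt in (1.0, 0.25):
            n = int(round(600.0 / dt))
            traj = circle_states(omega_true, dt, n + 1)
            fit = fit_skew(*finite_difference(traj, dt))
            omega_hat = np.abs(fit.eigenvalues.imag).max()
            errors.append(abs(omega_hat - omega_true) / omega_true)
        assert errors[0] < 0.01
        assert errors[1] < errors[0]

    def test_conjugation_under_orthogonal_transform(self, rng):
        X = rng.standard_normal((300, 5))
        Xdot = rng.standard_normal((300, 5))
        fit = fit_skew(X, Xdot)
        Q = ortho_group.rvs(5, random_state=7)
        fit_q = fit_skew(X @ Q.T, Xdot @ Q.T)
        np.testing.assert_allclose(fit_q.M_skew, Q @ fit.M_skew @ Q.T, atol=1e-8)
        np.testing.assert_allclose(
            np.sort(fit_q.eigenvalues.imag), np.sort(fit.eigenvalues.imag), atol=1e-8
        )
        assert fit_q.r2_skew == pytest.approx(fit.r2_skew, abs=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_skew(np.zeros((5, 6)), np.zeros((5, 6)))


class TestRotationPlanes:
    def test_unit_rotation_yields_single_plane_omega_one(self):
        fit = fit_skew(*_exact_skew_data(np.array([[0.0, -1.0], [1.0, 0.0]])))
        planes = rotation_planes(fit)
        assert len(planes) == 1
        assert planes[0].omega == pytest.approx(1.0, abs=1e-8)

    def test_block_diagonal_planes_ordered_by_frequency(self):
        M = np.zeros((4, 4))
        M[0, 1], M[1, 0] = -0.5, 0.5
        M[2, 3], M[3, 2] = -2.0, 2.0
        fit = fit_skew(*_exact_skew_data(M))
        planes = rotation_planes(fit)
        assert [round(p.omega, 6) for p in planes] == [2.0, 0.5]

    def test_plane_bases_orthonormal(self, rng):
        fit = fit_skew(rng.standard_normal((200, 6)), rng.standard_normal((200, 6)))
        for plane in rotation_planes(fit):
            np.testing.assert_allclose(plane.basis.T @ plane.basis, np.eye(2), atol=1e-10)

    def test_odd_dimension_drops_zero_eigenvalue(self, rng):
        fit = fit_skew(rng.standard_normal((200, 5)), rng.standard_normal((200, 5)))
        assert len(rotation_planes(fit)) == 2


def _exact_skew_data(M: np.ndarray, n: int = 300, seed: int = 0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, M.shape[0]))
    return X, X @ M.T


class TestProjectAndSummarize:
    @staticmethod
    def _plane(k: int = 2) -> RotationPlane:
        basis = np.zeros((k, 2))
        basis[0, 0] = basis[1, 1] = 1.0
        return RotationPlane(basis=basis, omega=1.0)

    def test_identical_circles_fully_consistent(self):
        traj = np.tile(circle_states(0.5, 0.1, 50), (6, 1, 1))
        summary = project_and_summarize(traj, self._plane())
        assert summary.direction_consistency == 1.0
        assert np.all(summary.direction_signs == summary.direction_signs[0])

    def test_half_reversed_conditions_give_chance_consistency(self):
        fwd = circle_states(0.5, 0.1, 50)
        traj = np.stack([fwd, fwd[::-1]] * 3)
        summary = project_and_summarize(traj, self._plane(), orient=False)
        assert summary.direction_consistency == 0.5

    def test_orientation_flips_majority_to_counterclockwise(self):
        cw = circle_states(0.5, 0.1, 50)[:, ::-1]  # clockwise traversal
        plane = self._plane()
        summary = project_and_summarize(np.tile(cw, (4, 1, 1)), plane, orient=True)
        x, y = summary.projections[0, :, 0], summary.projections[0, :, 1]
        assert np.sum(x[:-1] * y[1:] - y[:-1] * x[1:]) > 0


class TestJPCAPipeline:
    def test_sine_cosine_population_rotates_without_mean_subtraction(self):
        # two neurons in quadrature, identical across conditions: an obvious
        # rotation that the default mean subtraction destroys
        grid = TimeGrid(-50.0, 550.0, 10.0)
        t = grid.times
        sine = 1.0 + np.sin(2 * np.pi * (t + 50) / 600.0)
        cosine = 1.0 + np.cos(2 * np.pi * (t + 50) / 600.0)
        rates = np.stack([np.tile(sine, (8, 1)), np.tile(cosine, (8, 1))])
        pop = PopulationPETH(rates, grid)
        fit, summary, report = jpca_pipeline(pop, subtract_mean=False, num_pcs=2)
        assert summary.direction_consistency == 1.0
        assert not report.degenerate

        _, _, report_on = jpca_pipeline(pop, subtract_mean=True, num_pcs=2)
        assert report_on.degenerate

    def test_window_outside_grid_rejected(self, small_wave):
        with pytest.raises(ValueError):
            jpca_pipeline(small_wave, window=(-500.0, 550.0))

    def test_degenerate_flag_propagates_to_summary(self, small_grid):
        rates = np.repeat(np.random.default_rng(0).random((8, 1, small_grid.n_samples)), 6, axis=1)
        pop = PopulationPETH(rates, small_grid)
        _, summary, report = jpca_pipeline(pop, num_pcs=4, window=None)
        assert report.degenerate and summary.degenerate
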