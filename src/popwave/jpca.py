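"""Skew-symmetric dynamical fit of population trajectories ("jPCA"-style).

The model is the linear dynamical system ``dX/dt = M X`` with ``M``
constrained to be skew-symmetric (``M = -M^T``). A skew matrix has purely
imaginary eigenvalues ``±i w_j``, so the induced flow rotates the state
around the origin without radial growth or decay; the real 2-planes spanned
by each conjugate eigenvector pair are the "rotation planes", and
projecting per-condition trajectories onto the strongest plane shows
whether all conditions rotate the same way.

The constrained least-squares fit is solved by parameterizing ``M`` with
the k(k-1)/2 elementary skew basis matrices and solving one ordinary
least-squares problem in the basis coefficients. The unconstrained
least-squares matrix is fitted alongside as a goodness-of-fit reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .population import PopulationPETH, TimeGrid
from .statespace import ConditioningReport, StateTrajectories, pca_reduce, subtract_cross_condition_mean

__all__ = [
    "SkewFit",
    "RotationPlane",
    "RotationSummary",
    "finite_difference",
    "fit_skew",
    "rotation_planes",
    "project_and_summarize",
    "jpca_pipeline",
]

log = logging.getLogger(__name__)


def skew_basis(k: int) -> list[np.ndarray]:
    """Elementary skew-symmetric basis matrices ``E_ij - E_ji`` for i < j."""
    basis = []
    for i in range(k):
        for j in range(i + 1, k):
            H = np.zeros((k, k))
            H[i, j] = 1.0
            H[j, i] = -1.0
            basis.append(H)
    return basis


@dataclass
class SkewFit:
    """Fitted skew-symmetric dynamics with diagnostics.

    Attributes
    ----------
    M_skew : ndarray, shape (k, k)
        Best skew-symmetric dynamics matrix (1/ms); exactly antisymmetric.
    M_best : ndarray, shape (k, k)
        Unconstrained least-squares dynamics matrix.
    eigenvalues : ndarray of complex
        Eigenvalues of ``M_skew`` (conjugate imaginary pairs ``±i w``).
    r2_skew, r2_best : float
        Fraction of derivative variance explained, ``1 - ||resid||^2 /
        ||Xdot||^2`` (uncentered; derivatives are near-centered already).
    """

    M_skew: np.ndarray
    M_best: np.ndarray
    eigenvalues: np.ndarray
    r2_skew: float
    r2_best: float


@dataclass
class RotationPlane:
    """One rotation plane of the fitted skew dynamics."""

    basis: np.ndarray  # (k, 2), orthonormal columns
    omega: float  # angular frequency, rad/ms


@dataclass
class RotationSummary:
    """Projection of per-condition trajectories onto one rotation plane.

    ``direction_consistency`` is the fraction of conditions whose net
    rotation (sign of the summed cross product of consecutive projected
    states) matches the majority sign; 1.0 means every condition rotates
    the same way, ~0.5 is chance.
    """

    projections: np.ndarray  # (n_conditions, n_times, 2)
    direction_signs: np.ndarray  # (n_conditions,), +1 / -1 / 0
    direction_consistency: float
    omega: float
    degenerate: bool = False


def finite_difference(traj: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Forward first difference of per-condition trajectories.

    ``traj`` is (n_times, k) or (n_conditions, n_times, k) on a uniform grid;
    returns pooled states ``X`` (left samples) and derivatives
    ``Xdot = diff / dt``, each with one row per retained sample.
    """
    traj = np.asarray(traj, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    single = traj.ndim == 2
    if single:
        traj = traj[None]
    if traj.shape[1] < 2:
        raise ValueError("need at least 2 time samples to differentiate")
    X = traj[:, :-1, :]
    Xdot = np.diff(traj, axis=1) / dt
    k = traj.shape[2]
    return X.reshape(-1, k), Xdot.reshape(-1, k)


def fit_skew(X: np.ndarray, Xdot: np.ndarray) -> SkewFit:
    """Least-squares fit of ``Xdot ≈ M X`` over skew-symmetric ``M``.

    ``X`` and ``Xdot`` are (n_samples, k) with matching rows (state and its
    derivative). ``M_skew`` minimizes ``||Xdot - X M^T||_F`` over skew
    matrices, solved in the elementary skew basis; ``M_best`` is the
    unconstrained minimizer. Rank-deficient designs are solved in the
    least-squares sense with a logged warning.
    """
    X = np.asarray(X, dtype=float)
    Xdot = np.asarray(Xdot, dtype=float)
    if X.shape != Xdot.shape or X.ndim != 2:
        raise ValueError("X and Xdot must be matching (n_samples, k) arrays")
    n, k = X.shape
    n_par = k * (k - 1) // 2
    if n < max(n_par, 1):
        raise ValueError(f"need at least {n_par} pooled samples to fit k={k} skew dynamics")

    basis = skew_basis(k)
    if basis:
        # column p of the design is vec(X @ H_p^T)
        D = np.stack([(X @ H.T).ravel() for H in basis], axis=1)
        coef, _, rank, _ = np.linalg.lstsq(D, Xdot.ravel(), rcond=None)
        if rank < n_par:
            log.warning("skew design rank-deficient (rank %d < %d); least-norm solution used", rank, n_par)
        M_skew = sum(c * H for c, H in zip(coef, basis))
    else:
        M_skew = np.zeros((1, 1))
    M_skew = np.asarray(M_skew)
    # enforce exact antisymmetry against accumulation error
    M_skew = (M_skew - M_skew.T) / 2.0

    G, _, rank_b, _ = np.linalg.lstsq(X, Xdot, rcond=None)
    if rank_b < k:
        log.warning("state matrix rank-deficient (rank %d < %d); least-norm solution used", rank_b, k)
    M_best = G.T

    sst = float(np.sum(Xdot**2))

    def r2(M: np.ndarray) -> float:
        if sst == 0:
            return 1.0
        return 1.0 - float(np.sum((Xdot - X @ M.T) ** 2)) / sst

    return SkewFit(
        M_skew=M_skew,
        M_best=M_best,
        eigenvalues=np.linalg.eigvals(M_skew),
        r2_skew=r2(M_skew),
        r2_best=r2(M_best),
    )


def rotation_planes(fit: SkewFit, tol: float = 1e-12) -> list[RotationPlane]:
    """Rotation planes of ``M_skew``, strongest (largest ``|w|``) first.

    Each conjugate eigenvalue pair ``±i w`` contributes one plane whose real
    orthonormal basis comes from the real and imaginary parts of one
    eigenvector (QR-orthonormalized, sign-fixed). For odd ``k`` the unpaired
    zero eigenvalue yields no plane.
    """
    w, V = np.linalg.eig(fit.M_skew)
    scale = max(float(np.abs(w).max()), 1.0)
    planes = []
    used = np.zeros(len(w), dtype=bool)
    order = np.argsort(-np.abs(w.imag), kind="stable")
    for idx in order:
        if used[idx] or w[idx].imag <= tol * scale:
            continue
        # mark this eigenvalue and its conjugate partner
        used[idx] = True
        partner = np.flatnonzero(~used & (np.abs(w - np.conj(w[idx])) < 1e-9 * scale))
        if partner.size:
            used[partner[0]] = True
        v = V[:, idx]
        B = np.column_stack([v.real, v.imag])
        Q, R = np.linalg.qr(B)
        Q = Q * np.sign(np.diag(R))  # deterministic orientation of the QR factors
        signs = np.sign(Q[np.argmax(np.abs(Q), axis=0), np.arange(2)])
        signs[signs == 0] = 1.0
        planes.append(RotationPlane(basis=Q * signs, omega=float(abs(w[idx].imag))))
    if fit.M_skew.shape[0] % 2 == 1:
        log.info("odd state dimension: one zero eigenvalue yields no rotation plane")
    return planes


def project_and_summarize(
    trajs: np.ndarray, plane: RotationPlane, orient: bool = True
) -> RotationSummary:
    """Project per-condition trajectories onto a plane and score rotation.

    ``trajs`` is (n_conditions, n_times, k). Each condition's net rotation
    sign is the sign of ``sum_t (x_t * y_{t+1} - y_t * x_{t+1})``; direction
    consistency is the majority fraction. With ``orient=True`` the plane's
    second axis is flipped if needed so the majority rotates counter-
    clockwise (deterministic plots; consistency is unaffected).
    """
    trajs = np.asarray(trajs, dtype=float)
    if trajs.ndim != 3 or trajs.shape[2] != plane.basis.shape[0]:
        raise ValueError("trajs must be (n_conditions, n_times, k) matching the plane basis")
    proj = trajs @ plane.basis  # (c, t, 2)
    x, y = proj[..., 0], proj[..., 1]
    cross = np.sum(x[:, :-1] * y[:, 1:] - y[:, :-1] * x[:, 1:], axis=1)
    signs = np.sign(cross)
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if orient and n_neg > n_pos:
        plane.basis = plane.basis * np.array([1.0, -1.0])
        proj = proj * np.array([1.0, -1.0])
        signs = -signs
        n_pos, n_neg = n_neg, n_pos
    consistency = max(n_pos, n_neg) / len(signs) if len(signs) else 0.0
    return RotationSummary(
        projections=proj,
        direction_signs=signs,
        direction_consistency=float(max(consistency, 0.5)),
        omega=plane.omega,
    )


def jpca_pipeline(
    pop: PopulationPETH,
    subtract_mean: bool = True,
    num_pcs: int = 6,
    window: tuple[float, float] | None = (-50.0, 550.0),
) -> tuple[SkewFit, RotationSummary, ConditioningReport]:
    """Full rotational-dynamics pipeline on a PETH population.

    Steps: restrict to the analysis window, optionally subtract each
    neuron's across-condition mean (the method's default preprocessing),
    reduce to ``num_pcs`` principal components, forward-difference the
    per-condition trajectories, fit the skew-symmetric dynamics, and project
    all conditions onto the strongest rotation plane.

    A degenerate :class:`ConditioningReport` does not abort the fit — the
    fit simply has nothing but amplitude noise to explain — but it is
    propagated on the summary and logged prominently.
    """
    if window is not None:
        pop = pop.window(*window)
    if subtract_mean:
        pop, report = subtract_cross_condition_mean(pop)
    else:
        # diagnostic only: what mean subtraction would have left
        _, report = subtract_cross_condition_mean(pop)
        report = ConditioningReport(
            report.residual_fraction,
            report.rescaling_residual_fraction,
            degenerate=False,
            tol=report.tol,
            applied=False,
        )
    traj: StateTrajectories = pca_reduce(pop, num_pcs)
    X, Xdot = finite_difference(traj.scores, pop.grid.step)
    fit = fit_skew(X, Xdot)
    planes = rotation_planes(fit)
    if not planes:
        # fitted dynamics are (numerically) non-rotational; summarize the
        # leading PC plane with omega 0 rather than fail
        log.warning("fitted skew dynamics have no rotation plane (all eigenvalues ~0)")
        basis = np.zeros((num_pcs, 2))
        basis[0, 0] = basis[1, 1] = 1.0
        planes = [RotationPlane(basis=basis, omega=0.0)]
    summary = project_and_summarize(traj.scores, planes[0])
    summary.degenerate = report.degenerate
    if report.degenerate:
        log.warning(
            "ill-conditioned input (residual fractions %.3g / %.3g): rotation summary is untrusted",
            report.residual_fraction,
            report.rescaling_residual_fraction,
        )
    return fit, summary, report
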