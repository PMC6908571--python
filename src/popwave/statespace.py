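"""Preprocessing and PCA for population state-space trajectories.

Two preprocessing steps are distinguished because they serve different
analyses: per-neuron *standardization* (z-scoring the condition-appended
time series) precedes plain PCA trajectory plots, while *cross-condition
mean subtraction* is the default preprocessing of the skew-symmetric
dynamical fit. Mean subtraction is also where ill-conditioning originates:
when conditions are (statistically) identical, the residual left after
subtracting each neuron's across-condition average carries no
condition-specific temporal structure, and the downstream dynamics fit is
dominated by noise. :class:`ConditioningReport` quantifies this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .population import PopulationPETH, TimeGrid

__all__ = [
    "ConditioningReport",
    "StateTrajectories",
    "standardize",
    "subtract_cross_condition_mean",
    "pca_reduce",
]

log = logging.getLogger(__name__)

DEGENERACY_TOL = 1e-8
"""Residual fraction below which mean-subtracted data are flagged ill-conditioned."""


@dataclass
class ConditioningReport:
    """Diagnostics of cross-condition mean subtraction.

    Attributes
    ----------
    residual_fraction : float
        ``||data after mean subtraction|| / ||data before||`` (Frobenius),
        in [0, 1]. Zero when all conditions are identical.
    rescaling_residual_fraction : float
        Residual fraction after additionally removing, per (neuron,
        condition), the best scalar multiple of that neuron's across-
        condition mean response. This detects the subtler degeneracy where
        conditions differ only by random amplitude rescalings of a common
        temporal profile: the plain residual is then large, yet it contains
        no condition-specific temporal structure for a dynamical fit to
        latch onto.
    degenerate : bool
        True when either fraction falls below ``tol``.
    applied : bool
        Whether mean subtraction was actually applied to the data the report
        accompanies (pipelines can compute the diagnostic without applying).
    """

    residual_fraction: float
    rescaling_residual_fraction: float
    degenerate: bool
    tol: float = DEGENERACY_TOL
    applied: bool = True


@dataclass
class StateTrajectories:
    """Per-condition low-dimensional PCA trajectories.

    Attributes
    ----------
    scores : ndarray, shape (n_conditions, n_times, k)
        Component scores per condition.
    loadings : ndarray, shape (n_neurons, k)
        Orthonormal component loadings (sign-fixed so each column's
        largest-magnitude entry is positive).
    explained_variance_ratio : ndarray, shape (k,)
        Fraction of total variance per retained component, non-increasing.
    grid : TimeGrid
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    grid: TimeGrid

    @property
    def k(self) -> int:
        return self.scores.shape[2]


def standardize(pop: PopulationPETH) -> PopulationPETH:
    """Z-score each neuron's condition-appended time series.

    For every neuron, the mean and standard deviation are computed over all
    conditions' samples appended together; the output series has mean 0 and
    SD 1 (population SD, ddof=0). Affine-invariant: rescaling or offsetting
    a neuron's rates does not change its standardized output.
    """
    flat = pop.rates.reshape(pop.n_neurons, -1)
    mu = flat.mean(axis=1)
    sd = flat.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        ids = pop.neuron_ids[zero]
        raise ValueError(f"zero-variance neuron(s), cannot standardize: {ids.tolist()}")
    out = (pop.rates - mu[:, None, None]) / sd[:, None, None]
    return pop.with_rates(out)


def subtract_cross_condition_mean(
    pop: PopulationPETH, tol: float = DEGENERACY_TOL
) -> tuple[PopulationPETH, ConditioningReport]:
    """Subtract each neuron's across-condition average PETH from every condition.

    Returns the centered data and a :class:`ConditioningReport`. The report's
    degenerate flag is raised when the residual data retain (essentially) no
    condition-specific temporal structure — either because conditions were
    identical, or because they differed only by per-condition amplitude
    rescalings of each neuron's common response profile.
    """
    if pop.n_conditions < 2:
        raise ValueError("mean subtraction requires at least 2 conditions")
    mean = pop.rates.mean(axis=1, keepdims=True)  # (n, 1, t)
    resid = pop.rates - mean
    total = float(np.linalg.norm(pop.rates))
    residual_fraction = float(np.linalg.norm(resid)) / total if total > 0 else 0.0

    # best per-(neuron, condition) scalar multiple of the neuron's mean profile
    m = mean[:, 0, :]  # (n, t)
    mm = np.einsum("nt,nt->n", m, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.einsum("nct,nt->nc", pop.rates, m) / mm[:, None]
    beta = np.where(mm[:, None] > 0, beta, 0.0)
    scaled_resid = pop.rates - beta[:, :, None] * m[:, None, :]
    rescaling_fraction = float(np.linalg.norm(scaled_resid)) / total if total > 0 else 0.0

    degenerate = residual_fraction < tol or rescaling_fraction < tol
    if degenerate:
        log.warning(
            "cross-condition mean subtraction left no condition-specific temporal "
            "structure (residual fraction %.3g, rescaling residual %.3g): the data "
            "are ill-conditioned for a dynamical fit",
            residual_fraction,
            rescaling_fraction,
        )
    report = ConditioningReport(residual_fraction, rescaling_fraction, degenerate, tol)
    return pop.with_rates(resid), report


def pca_reduce(pop: PopulationPETH, k: int, center: bool = True) -> StateTrajectories:
    """PCA of the condition-appended data, split back into per-condition scores.

    The data matrix has one row per time sample (conditions appended along
    time) and one column per neuron; PCA runs on the column-centered matrix
    via SVD. Loadings columns are sign-fixed (largest-magnitude entry
    positive) for backend-independent reproducibility.
    """
    n, c, t = pop.rates.shape
    total = c * t
    if not 1 <= k <= min(n, total):
        raise ValueError(f"k must be in 1..{min(n, total)}, got {k}")
    X = pop.rates.reshape(n, total).T  # (samples, neurons)
    if center:
        X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[:k].T
    signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    scores = X @ loadings
    var = s**2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    if k < len(var) and var.sum() > 0:
        log.info("first %d components explain %.1f%% of variance", k, 100 * var[:k].sum() / var.sum())
    return StateTrajectories(
        scores=scores.reshape(c, t, k),
        loadings=loadings,
        explained_variance_ratio=evr,
        grid=pop.grid,
    )
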