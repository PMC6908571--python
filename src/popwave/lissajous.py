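"""Fitting population activity to arbitrary target curves by linear regression.

A multiple linear regression from the neurons' firing rates onto the
coordinates of a parametric target curve — a circle ``(cos 2*pi*t/T,
sin 2*pi*t/T)`` or the figure-eight Lissajous curve ``(cos 2*pi*t/T,
sin 4*pi*t/T)`` — demonstrates that with enough free parameters a linear
readout can produce essentially any desired trajectory from the same data.
Generalization is probed by fitting on half of the conditions and
predicting the other half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .population import PopulationPETH, TimeGrid

__all__ = ["LissajousTarget", "RegressionFit", "make_targets", "fit_lissajous", "predict"]

log = logging.getLogger(__name__)

SHAPES = ("circle", "infinity")


@dataclass
class LissajousTarget:
    """Target curve sampled on the analysis grid.

    ``t`` is measured from the window start; ``T`` is the trial duration in
    ms (default: the window length, so the circle closes once per trial).
    For the circle, ``y`` completes one cycle per trial; for the infinity
    shape, ``y = sin(4*pi*t/T)`` completes two, tracing a figure eight.
    """

    shape: str
    T: float
    x: np.ndarray
    y: np.ndarray

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class RegressionFit:
    """Per-output OLS coefficients with the train/test condition protocol.

    ``coef`` has one row per neuron plus (if fitted) a final intercept row;
    columns are the (x, y) outputs. ``r2_train`` is the coefficient of
    determination per output on the training conditions.
    """

    coef: np.ndarray  # (n_neurons [+1], 2)
    intercept: bool
    train_conditions: np.ndarray  # 0-based condition indices
    target: LissajousTarget
    r2_train: tuple[float, float]


def make_targets(grid: TimeGrid, shape: str, T: float | None = None) -> LissajousTarget:
    """Evaluate the target curve on the grid (``t`` from window start)."""
    if shape not in SHAPES:
        raise ValueError(f"shape must be one of {SHAPES}, got {shape!r}")
    if T is None:
        T = grid.duration
    if T <= 0:
        raise ValueError("T must be > 0")
    t = grid.times - grid.times[0]
    x = np.cos(2 * np.pi * t / T)
    y = np.sin((4 if shape == "infinity" else 2) * np.pi * t / T)
    return LissajousTarget(shape=shape, T=float(T), x=x, y=y)


def _design(pop: PopulationPETH, conditions: np.ndarray, intercept: bool) -> np.ndarray:
    # rows: time samples of the selected conditions appended; columns: neurons
    D = pop.rates[:, conditions, :].reshape(pop.n_neurons, -1).T
    if intercept:
        D = np.column_stack([D, np.ones(len(D))])
    return D


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - yhat) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else -np.inf
    return 1.0 - sse / sst


def fit_lissajous(
    pop: PopulationPETH,
    target: LissajousTarget,
    train_conditions: np.ndarray | None = None,
    intercept: bool = True,
) -> RegressionFit:
    """OLS of the target coordinates on the neuron-rate design matrix.

    The design has one row per appended time sample of the training
    conditions and one column per neuron (plus an intercept column by
    default); the target is tiled across training conditions. The x and y
    outputs are fitted as two independent regressions on the same design.
    Singular designs are solved in the least-squares (minimum-norm) sense
    with a logged warning.
    """
    if train_conditions is None:
        train_conditions = np.arange(pop.n_conditions)
    train_conditions = np.asarray(train_conditions, dtype=int)
    if len(train_conditions) == 0:
        raise ValueError("need at least one training condition")
    D = _design(pop, train_conditions, intercept)
    n_par = D.shape[1]
    if D.shape[0] <= pop.n_neurons:
        log.warning(
            "underdetermined design (%d pooled samples <= %d neurons): "
            "minimum-norm interpolating fit",
            D.shape[0],
            pop.n_neurons,
        )
    Y = np.tile(target.xy, (len(train_conditions), 1))
    coef, _, rank, _ = np.linalg.lstsq(D, Y, rcond=None)
    if rank < n_par:
        log.warning("singular regression design (rank %d < %d); minimum-norm solution used", rank, n_par)
    fitted = D @ coef
    r2 = (_r2(Y[:, 0], fitted[:, 0]), _r2(Y[:, 1], fitted[:, 1]))
    return RegressionFit(
        coef=coef, intercept=intercept, train_conditions=train_conditions, target=target, r2_train=r2
    )


def predict(
    fit: RegressionFit,
    pop: PopulationPETH,
    test_conditions: np.ndarray,
    allow_overlap: bool = False,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Apply fitted coefficients to held-out conditions.

    Returns per-condition predicted 2D curves of shape (n_test, n_times, 2)
    and the test coefficient of determination per output against the same
    target. Overlapping train/test sets are an error unless explicitly
    allowed (useful for the fit-equals-prediction sanity check).
    """
    test_conditions = np.asarray(test_conditions, dtype=int)
    if not allow_overlap and np.intersect1d(test_conditions, fit.train_conditions).size:
        raise ValueError("test conditions overlap the training set")
    D = _design(pop, test_conditions, fit.intercept)
    pred = D @ fit.coef
    Y = np.tile(fit.target.xy, (len(test_conditions), 1))
    r2 = (_r2(Y[:, 0], pred[:, 0]), _r2(Y[:, 1], pred[:, 1]))
    return pred.reshape(len(test_conditions), pop.n_times, 2), r2
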