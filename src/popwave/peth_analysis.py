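"""Ordering, partitioning and correlating PETHs to expose temporal sequences.

The analyses here operationalize the classical view of a population "wave":
average each neuron's PETH across conditions, sort neurons by the time of
their peak rate, split the sorted population into early / intermediate /
late thirds, and correlate time courses pairwise. A consistent temporal
sequence shows up as a diagonal band in the sorted population plot, a tight
peak-time scatter across conditions, and a correlation matrix whose entries
decay with peak-time separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .population import PopulationPETH, TimeGrid

__all__ = [
    "PeakTable",
    "SubpopulationSplit",
    "average_across_conditions",
    "order_by_peak",
    "build_peak_table",
    "condition_peak_times",
    "split_subpopulations",
    "pairwise_correlation",
    "normalize_for_display",
]


@dataclass
class PeakTable:
    """Peak-response timing of each neuron.

    Attributes
    ----------
    peak_ms : ndarray, shape (n_neurons,)
        Time of the maximum of each neuron's across-condition average PETH.
    order : ndarray, shape (n_neurons,)
        Permutation of 0-based neuron indices sorting ``peak_ms`` ascending
        (stable: ties keep the original index order).
    degenerate : ndarray of bool
        True for all-constant rows, whose peak time defaults to the first
        grid sample.
    condition_peak_ms : ndarray, shape (n_neurons, n_conditions), optional
        Per-(neuron, condition) peak times (the peak-time scatter).
    """

    peak_ms: np.ndarray
    order: np.ndarray
    degenerate: np.ndarray
    condition_peak_ms: np.ndarray | None = None


@dataclass
class SubpopulationSplit:
    """Partition of the rank-ordered population into contiguous groups."""

    group_of_rank: np.ndarray  # group index per rank position
    sizes: tuple[int, ...]
    group_of_neuron: np.ndarray  # group index per original neuron index
    group_condition_avg: np.ndarray | None = None  # (n_groups, n_conditions, n_times)


def average_across_conditions(pop: PopulationPETH) -> np.ndarray:
    """Arithmetic mean over the condition axis; shape (n_neurons, n_times)."""
    return pop.rates.mean(axis=1)


def _peak_times(matrix: np.ndarray, grid: TimeGrid) -> tuple[np.ndarray, np.ndarray]:
    # argmax takes the earliest sample on ties, which is the tie-break rule
    idx = np.argmax(matrix, axis=-1)
    degenerate = np.ptp(matrix, axis=-1) == 0
    idx = np.where(degenerate, 0, idx)
    return grid.times[idx], degenerate


def order_by_peak(avg: np.ndarray, grid: TimeGrid) -> PeakTable:
    """Sort neurons by the peak time of their average PETH.

    Peak time is the grid time of the row maximum (earliest sample on ties).
    All-constant rows are flagged degenerate and assigned the first grid time.
    """
    avg = np.asarray(avg, dtype=float)
    if avg.ndim != 2 or avg.size == 0:
        raise ValueError("expected a nonempty (n_neurons, n_times) matrix")
    peak_ms, degenerate = _peak_times(avg, grid)
    order = np.argsort(peak_ms, kind="stable")
    return PeakTable(peak_ms=peak_ms, order=order, degenerate=degenerate)


def condition_peak_times(pop: PopulationPETH, method: str = "argmax") -> np.ndarray:
    """Per-(neuron, condition) peak times in ms.

    ``method="argmax"`` reads the grid time of the maximum sample and cannot
    resolve shifts smaller than one grid bin; ``method="centroid"`` uses the
    rate-weighted mean time, which recovers sub-bin lags exactly for
    symmetric bumps fully inside the window.
    """
    if method == "argmax":
        peak_ms, _ = _peak_times(pop.rates, pop.grid)
        return peak_ms
    if method == "centroid":
        t = pop.grid.times
        mass = pop.rates.sum(axis=2)
        with np.errstate(invalid="ignore"):
            cent = (pop.rates * t).sum(axis=2) / mass
        return np.where(mass > 0, cent, t[0])
    raise ValueError(f"unknown peak-time method {method!r}")


def build_peak_table(pop: PopulationPETH, method: str = "argmax") -> PeakTable:
    """Full peak table: average-PETH ordering plus the per-condition scatter."""
    table = order_by_peak(average_across_conditions(pop), pop.grid)
    table.condition_peak_ms = condition_peak_times(pop, method=method)
    return table


def split_subpopulations(
    order: PeakTable, n_groups: int, pop: PopulationPETH | None = None
) -> SubpopulationSplit:
    """Split the rank-ordered population into ``n_groups`` contiguous blocks.

    Block sizes differ by at most one; the remainder goes to the earlier
    blocks (218 neurons, 3 groups -> 73, 73, 72). If ``pop`` is given, the
    per-group per-condition average PETHs are computed on the raw rates
    (display normalization is never applied here).
    """
    n = len(order.order)
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in 1..{n}, got {n_groups}")
    base, rem = divmod(n, n_groups)
    sizes = tuple(base + (1 if g < rem else 0) for g in range(n_groups))
    group_of_rank = np.repeat(np.arange(n_groups), sizes)
    group_of_neuron = np.empty(n, dtype=int)
    group_of_neuron[order.order] = group_of_rank
    avg = None
    if pop is not None:
        avg = np.stack(
            [pop.rates[group_of_neuron == g].mean(axis=0) for g in range(n_groups)]
        )
    return SubpopulationSplit(group_of_rank, sizes, group_of_neuron, avg)


def pairwise_correlation(avg: np.ndarray) -> np.ndarray:
    """Pearson correlation between neurons' time courses.

    ``avg`` is a (n_neurons, n_times) matrix, typically the across-condition
    average PETHs; to correlate full condition-appended time courses instead,
    pass ``pop.rates.reshape(n_neurons, -1)``. Zero-variance rows yield NaN
    rows/columns with a warning.
    """
    avg = np.asarray(avg, dtype=float)
    if avg.shape[1] < 2:
        raise ValueError("need at least 2 time samples per neuron")
    flat = avg.std(axis=1) == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} neuron(s) have zero-variance time courses; "
            "their correlations are undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(avg)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, np.where(flat, np.nan, 1.0))
    return corr


def normalize_for_display(peth: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the peak of the original vector.

    Used only for plotting population color maps (it equalizes neurons with
    very different rate scales); analyses always run on raw rates.
    """
    x = np.asarray(peth, dtype=float)
    peak = x.max()
    if peak <= 0:
        raise ValueError("display normalization requires a positive peak value")
    return (x - x.mean()) / peak
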