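"""Surrogate-data operators: condition shuffling and forward time shifts.

``shuffle_conditions`` destroys condition-specific co-modulation between
neurons while preserving each neuron's multiset of PETHs (and therefore its
across-condition average exactly). ``shift_conditions`` displaces the PETHs
of a block of conditions later in time, padding the opened initial interval
with each PETH's original first sample — the pattern a uniformly delayed
movement onset would produce. Shifting introduces across-condition
variability without altering the temporal sequence of the population, which
is precisely what rescues the mean-subtracting dynamical fit from
ill-conditioning.
"""

from __future__ import annotations

import numpy as np

from .population import PopulationPETH

__all__ = ["shuffle_conditions", "shift_conditions", "cross_correlation_lag"]


def shuffle_conditions(pop: PopulationPETH, seed: int) -> PopulationPETH:
    """Independently permute the condition axis of every neuron.

    Deterministic given ``seed``. Each neuron keeps the same multiset of
    condition PETHs, so per-neuron across-condition averages are invariant.
    """
    if pop.n_conditions < 2:
        return pop.with_rates(pop.rates)
    rng = np.random.default_rng(seed)
    out = np.empty_like(pop.rates)
    for i in range(pop.n_neurons):
        out[i] = pop.rates[i, rng.permutation(pop.n_conditions)]
    return pop.with_rates(out)


def shift_conditions(
    pop: PopulationPETH,
    shift_ms: float = 100.0,
    condition_range: tuple[int, int] | None = None,
) -> PopulationPETH:
    """Shift the PETHs of a block of conditions forward (later) in time.

    Within the designated conditions (1-based inclusive range; default the
    second half), the sample at time ``t`` becomes the original sample at
    ``t - shift_ms``; the first ``shift_ms`` of each PETH is filled with that
    PETH's original first sample, and samples shifted beyond the window are
    dropped. All other conditions are untouched.
    """
    step = pop.grid.step
    k = shift_ms / step
    if shift_ms <= 0 or abs(k - round(k)) > 1e-9:
        raise ValueError(f"shift_ms must be a positive multiple of the grid step ({step} ms)")
    k = int(round(k))
    if condition_range is None:
        condition_range = (pop.n_conditions // 2 + 1, pop.n_conditions)
    lo, hi = condition_range
    if not 1 <= lo <= hi <= pop.n_conditions:
        raise ValueError(f"condition range {condition_range} outside 1..{pop.n_conditions}")
    out = pop.rates.copy()
    block = out[:, lo - 1 : hi]
    if k < pop.n_times:
        block[:, :, k:] = pop.rates[:, lo - 1 : hi, : pop.n_times - k]
    block[:, :, : min(k, pop.n_times)] = pop.rates[:, lo - 1 : hi, :1]
    return pop.with_rates(out)


def cross_correlation_lag(shifted: np.ndarray, original: np.ndarray, step: float) -> float:
    """Lag (ms) maximizing the Pearson correlation over the overlapping support.

    Positive lag means ``shifted`` trails ``original``: the correlation of
    ``shifted[k:]`` with ``original[:-k]`` is maximal at ``k = lag/step``.
    Brute-force scan over every admissible lag of both signs; ties resolve to
    the smallest |lag|.
    """
    shifted = np.asarray(shifted, dtype=float)
    original = np.asarray(original, dtype=float)
    n = len(shifted)
    if original.shape != (n,):
        raise ValueError("signals must be 1-D and equally long")
    best_lag, best_r = 0.0, -np.inf
    for k in range(-(n - 2), n - 1):
        a = shifted[k:] if k >= 0 else shifted[: n + k]
        b = original[: n - k] if k >= 0 else original[-k:]
        if a.std() == 0 or b.std() == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r > best_r + 1e-12 or (abs(r - best_r) <= 1e-12 and abs(k) < abs(best_lag / step)):
            best_r, best_lag = r, k * step
    return best_lag
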