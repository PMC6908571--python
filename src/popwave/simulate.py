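"""Synthetic PETH populations with a controllable temporal sequence of responses.

Each simulated PETH is a Gaussian bump ``a * exp(-(t - tau)^2 / w)`` whose
center ``tau`` follows a deterministic rule (a per-neuron lag plus a
per-condition-group onset) and whose amplitude ``a`` is drawn once per
(neuron, condition) from a uniform interval. Amplitudes are uncorrelated
across neurons and conditions; the *only* nonrandom structure is the
temporal sequence. This is deliberately minimal: no directional tuning, no
trial-level variability, no other feature of real motor cortical responses.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .population import DEFAULT_GRID, PopulationPETH, TimeGrid

__all__ = ["WaveConfig", "gaussian_bump", "simulate_wave", "simulate_synchronous"]

ConditionRange = tuple[int, int]


@dataclass(frozen=True)
class WaveConfig:
    """Full parameterization of the wave simulator.

    Parameters
    ----------
    n_neurons, n_conditions : int
        Population size; defaults (218, 108) match the shape of the monkey
        dataset the simulations are designed to emulate.
    kernel_width_param : float
        Divisor ``w`` (ms^2) of the Gaussian kernel exponent; default 50,
        i.e. a bump with standard deviation ``sqrt(50/2) = 5`` ms.
    per_neuron_lag : float
        Delay (ms) of neuron ``i`` relative to neuron ``i-1``; a positive
        value produces a wave of activity running through the population,
        zero a synchronous population.
    group_onsets : sequence of ((lo, hi), onset_ms)
        Contiguous 1-based inclusive condition ranges, each with the base
        peak time (ms) of neuron 1 for conditions in that range. The ranges
        must partition ``1..n_conditions``.
    amplitude_interval : (float, float)
        Half-open interval ``[low, high)`` for the uniform per-(neuron,
        condition) amplitude draw; default (0.2, 1.2), the semantics of a
        unit uniform deviate plus 0.2.
    seed : int
        Seed for the amplitude draws; peak times do not depend on it.
    grid : TimeGrid
        Sampling grid, default -50:10:550 ms.
    """

    n_neurons: int = 218
    n_conditions: int = 108
    kernel_width_param: float = 50.0
    per_neuron_lag: float = 1.0
    group_onsets: tuple[tuple[ConditionRange, float], ...] = (((1, 108), 50.0),)
    amplitude_interval: tuple[float, float] = (0.2, 1.2)
    seed: int = 0
    grid: TimeGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_conditions < 1:
            raise ValueError("n_neurons and n_conditions must be >= 1")
        if self.kernel_width_param <= 0:
            raise ValueError("kernel_width_param must be > 0")
        low, high = self.amplitude_interval
        if not low < high:
            raise ValueError("amplitude_interval must satisfy low < high")
        object.__setattr__(self, "group_onsets", tuple((tuple(r), float(o)) for r, o in self.group_onsets))
        self._check_partition()

    def _check_partition(self) -> None:
        covered = np.zeros(self.n_conditions, dtype=bool)
        for (lo, hi), _ in self.group_onsets:
            if not (1 <= lo <= hi <= self.n_conditions):
                raise ValueError(f"condition range ({lo}, {hi}) outside 1..{self.n_conditions}")
            if covered[lo - 1 : hi].any():
                raise ValueError("condition ranges overlap")
            covered[lo - 1 : hi] = True
        if not covered.all():
            raise ValueError("condition ranges do not cover 1..n_conditions")

    def condition_onsets(self) -> np.ndarray:
        """Per-condition base onset (ms), length ``n_conditions``."""
        onsets = np.empty(self.n_conditions)
        for (lo, hi), onset in self.group_onsets:
            onsets[lo - 1 : hi] = onset
        return onsets

    def peak_times(self) -> np.ndarray:
        """True bump centers ``tau[neuron, condition]`` in ms (seed-independent)."""
        lag = self.per_neuron_lag * np.arange(self.n_neurons)
        return lag[:, None] + self.condition_onsets()[None, :]


def gaussian_bump(grid: TimeGrid, tau: float, amplitude: float, width_param: float = 50.0) -> np.ndarray:
    """Evaluate ``amplitude * exp(-(t - tau)^2 / width_param)`` on the grid.

    ``width_param`` is the divisor of the squared deviation (ms^2), so the
    bump's Gaussian standard deviation is ``sqrt(width_param / 2)`` ms.
    """
    if width_param <= 0:
        raise ValueError(f"width_param must be > 0, got {width_param}")
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    t = grid.times
    return amplitude * np.exp(-((t - tau) ** 2) / width_param)


def simulate_wave(config: WaveConfig) -> PopulationPETH:
    """Simulate a population whose peak responses form a temporal sequence.

    Neuron ``i`` (1-based) in a condition of a group with onset ``o`` peaks at
    ``tau = o + (i - 1) * per_neuron_lag``; its amplitude is drawn once per
    (neuron, condition) from ``amplitude_interval``. Two runs with the same
    seed are bit-identical; the seed affects amplitudes only.
    """
    rng = np.random.default_rng(config.seed)
    low, high = config.amplitude_interval
    amplitudes = low + (high - low) * rng.random((config.n_neurons, config.n_conditions))
    tau = config.peak_times()  # (n_neurons, n_conditions)
    t = config.grid.times
    kernel = np.exp(-((t[None, None, :] - tau[:, :, None]) ** 2) / config.kernel_width_param)
    rates = amplitudes[:, :, None] * kernel
    peak_rate = rates.max(axis=2)
    n_silent = int(np.sum(peak_rate.max(axis=1) < low * 1e-6))
    if n_silent:
        warnings.warn(
            f"{n_silent} neuron(s) have essentially no response mass inside the grid "
            f"[{t[0]}, {t[-1]}] ms; their rates are near zero",
            stacklevel=2,
        )
    return PopulationPETH(rates, config.grid)


def simulate_synchronous(config: WaveConfig) -> PopulationPETH:
    """Simulate a population with no temporal spread of peaks.

    Equivalent to :func:`simulate_wave` with ``per_neuron_lag = 0``: within
    each condition every neuron peaks at the same time, though condition
    groups may still differ in onset.
    """
    return simulate_wave(dataclasses.replace(config, per_neuron_lag=0.0))
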