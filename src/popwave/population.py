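"""Core containers: uniform time grids and condition-structured PETH arrays.

The universal currency of the pipeline is a :class:`PopulationPETH`, a dense
``(neurons, conditions, time)`` array of firing rates on a uniform time grid,
one smoothed peri-event time histogram (PETH) per neuron per condition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["TimeGrid", "PopulationPETH", "DEFAULT_GRID"]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid in milliseconds.

    Parameters
    ----------
    start, stop : float
        First and last sample times (ms). Both are included in the grid.
    step : float
        Bin width (ms), strictly positive.
    """

    start: float = -50.0
    stop: float = 550.0
    step: float = 10.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(f"grid stop must exceed start ({self.start}..{self.stop})")

    @property
    def n_samples(self) -> int:
        return int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms, length ``n_samples``."""
        return self.start + self.step * np.arange(self.n_samples)

    @property
    def duration(self) -> float:
        """Window length ``stop - start`` in ms."""
        return self.times[-1] - self.start

    def index_of(self, t: float) -> int:
        """Index of the grid sample at time ``t`` (must lie on the grid)."""
        idx = (t - self.start) / self.step
        if abs(idx - round(idx)) > 1e-6:
            raise ValueError(f"time {t} ms is not on the grid {self}")
        i = int(round(idx))
        if not 0 <= i < self.n_samples:
            raise ValueError(f"time {t} ms is outside the grid {self}")
        return i


DEFAULT_GRID = TimeGrid(-50.0, 550.0, 10.0)
"""The analysis window used throughout: -50 to 550 ms in 10-ms bins (61 samples)."""


@dataclass
class PopulationPETH:
    """Population of condition-structured PETHs.

    Attributes
    ----------
    rates : ndarray, shape (n_neurons, n_conditions, n_times)
        Firing rates (spikes/s or arbitrary units). Simulator output is
        nonnegative; preprocessing steps (standardization, mean subtraction)
        legitimately produce signed values in the same container.
    grid : TimeGrid
        The common time axis.
    neuron_ids, condition_ids : ndarray
        Labels, 1-based by default to match the field's figure conventions
        ("conditions 1-54", "neurons 1-73").
    """

    rates: np.ndarray
    grid: TimeGrid = field(default_factory=lambda: DEFAULT_GRID)
    neuron_ids: np.ndarray | None = None
    condition_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if self.rates.ndim != 3:
            raise ValueError(f"rates must be 3-D (neurons, conditions, time), got {self.rates.shape}")
        if self.rates.shape[2] != self.grid.n_samples:
            raise ValueError(
                f"time axis length {self.rates.shape[2]} does not match grid ({self.grid.n_samples} samples)"
            )
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates contain non-finite values")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(1, self.n_neurons + 1)
        if self.condition_ids is None:
            self.condition_ids = np.arange(1, self.n_conditions + 1)
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.condition_ids = np.asarray(self.condition_ids)
        if len(self.neuron_ids) != self.n_neurons or len(self.condition_ids) != self.n_conditions:
            raise ValueError("label lengths do not match rates shape")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.rates.shape[1]

    @property
    def n_times(self) -> int:
        return self.rates.shape[2]

    def with_rates(self, rates: np.ndarray) -> "PopulationPETH":
        """Copy of this container with a new rate array on the same grid/labels."""
        return dataclasses.replace(self, rates=np.array(rates, dtype=np.float64))

    def window(self, t_start: float, t_stop: float) -> "PopulationPETH":
        """Restrict to grid samples with ``t_start <= t <= t_stop``."""
        times = self.grid.times
        if t_start < times[0] - 1e-9 or t_stop > times[-1] + 1e-9:
            raise ValueError(
                f"window [{t_start}, {t_stop}] ms exceeds the data grid [{times[0]}, {times[-1]}]"
            )
        mask = (times >= t_start - 1e-9) & (times <= t_stop + 1e-9)
        sub = times[mask]
        grid = TimeGrid(float(sub[0]), float(sub[-1]), self.grid.step)
        return PopulationPETH(self.rates[:, :, mask], grid, self.neuron_ids, self.condition_ids)

    # ------------------------------------------------------------------ I/O

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns (neuron, condition, time_ms, rate)."""
        n, c, t = self.rates.shape
        neuron = np.repeat(self.neuron_ids, c * t)
        condition = np.tile(np.repeat(self.condition_ids, t), n)
        time_ms = np.tile(self.grid.times, n * c)
        return pd.DataFrame(
            {"neuron": neuron, "condition": condition, "time_ms": time_ms, "rate": self.rates.ravel()}
        )

    def save_npz(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            rates=self.rates,
            times=self.grid.times,
            neuron_ids=self.neuron_ids,
            condition_ids=self.condition_ids,
        )

    @classmethod
    def load_npz(cls, path: str | Path) -> "PopulationPETH":
        with np.load(path, allow_pickle=False) as z:
            return cls._from_arrays(z["rates"], z["times"], z["neuron_ids"], z["condition_ids"])

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("rates", data=self.rates)
            f.create_dataset("times", data=self.grid.times)
            f.create_dataset("neuron_ids", data=np.asarray(self.neuron_ids))
            f.create_dataset("condition_ids", data=np.asarray(self.condition_ids))

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "PopulationPETH":
        with h5py.File(path, "r") as f:
            return cls._from_arrays(f["rates"][()], f["times"][()], f["neuron_ids"][()], f["condition_ids"][()])

    @classmethod
    def load(cls, path: str | Path) -> "PopulationPETH":
        """Load from ``.npz`` or HDF5 (``.h5``/``.hdf5``), dispatched on suffix."""
        path = Path(path)
        if path.suffix == ".npz":
            return cls.load_npz(path)
        return cls.load_hdf5(path)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".npz":
            self.save_npz(path)
        else:
            self.save_hdf5(path)

    @classmethod
    def load_mat_conditions(cls, path: str | Path, variable: str = "Data") -> "PopulationPETH":
        """Read a MAT-style container of per-condition rate matrices.

        Expects a struct array (one element per condition) whose elements
        carry a field ``A`` — a (time, neurons) rate matrix — plus a shared
        ``times`` vector either as a field of the first element or as a
        top-level variable. Convenience plumbing for externally provided
        data; not exercised by the test suite.
        """
        from scipy.io import loadmat

        mat = loadmat(path, squeeze_me=True)
        data = mat[variable]
        entries = np.atleast_1d(data)

        def _field(entry, name):
            value = np.asarray(entry[name])
            while value.dtype == object:  # loadmat wraps struct fields
                value = np.asarray(value.item())
            return value

        mats = [np.atleast_2d(_field(e, "A").astype(float)) for e in entries]
        shapes = {m.shape for m in mats}
        if len(shapes) != 1:
            raise ValueError(f"per-condition matrices disagree in shape: {sorted(shapes)}")
        if "times" in mat:
            times = np.asarray(mat["times"], dtype=float).ravel()
        else:
            times = _field(entries[0], "times").astype(float).ravel()
        rates = np.stack(mats).transpose(2, 0, 1)  # (neurons, conditions, time)
        return cls._from_arrays(rates, times, np.arange(1, rates.shape[0] + 1),
                                np.arange(1, rates.shape[1] + 1))

    @classmethod
    def _from_arrays(cls, rates, times, neuron_ids, condition_ids) -> "PopulationPETH":
        times = np.asarray(times, dtype=float)
        if len(times) < 2:
            raise ValueError("time grid must have at least 2 samples")
        step = float(times[1] - times[0])
        if not np.allclose(np.diff(times), step):
            raise ValueError("stored time grid is not uniform")
        grid = TimeGrid(float(times[0]), float(times[-1]), step)
        return cls(np.asarray(rates), grid, np.asarray(neuron_ids), np.asarray(condition_ids))
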