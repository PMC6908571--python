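"""End-to-end experiment runners on synthetic populations.

Each experiment chains the library modules the way the corresponding
analysis is described: simulate a population, perturb it if called for,
run the ordering / PCA / skew-dynamics / regression analyses, and write
CSV/JSON outputs plus a manifest. All randomness flows from the single
seed in the config; reruns with the same config are byte-identical.

The module also hosts the canonical simulation configurations used by the
experiments and the acceptance checks (single-, two- and three-onset
waves, the synchronous population, the window-tiling wave used for the
regression experiments, and the coarse-lag wave used for order recovery).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .jpca import jpca_pipeline
from .lissajous import fit_lissajous, make_targets, predict
from .perturb import shuffle_conditions
from .peth_analysis import (
    average_across_conditions,
    build_peak_table,
    pairwise_correlation,
    split_subpopulations,
)
from .population import PopulationPETH
from .simulate import WaveConfig, simulate_synchronous, simulate_wave
from .statespace import pca_reduce, standardize

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "EXPERIMENTS",
    "wave_single_onset",
    "wave_two_onsets",
    "wave_three_onsets",
    "synchronous_three_onsets",
    "window_tiling_wave",
    "ordering_wave",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- canonical configs


def wave_single_onset(seed: int = 0, per_neuron_lag: float = 1.0) -> WaveConfig:
    """Single onset group at 50 ms: all conditions statistically identical."""
    return WaveConfig(per_neuron_lag=per_neuron_lag, group_onsets=(((1, 108), 50.0),), seed=seed)


def wave_two_onsets(seed: int = 0, per_neuron_lag: float = 1.0) -> WaveConfig:
    """Two onset groups: conditions 1-54 start at 50 ms, 55-108 at 200 ms."""
    return WaveConfig(
        per_neuron_lag=per_neuron_lag,
        group_onsets=(((1, 54), 50.0), ((55, 108), 200.0)),
        seed=seed,
    )


def wave_three_onsets(seed: int = 0, per_neuron_lag: float = 1.0) -> WaveConfig:
    """Three onset groups (conditions 1-36, 37-72, 73-108) at 50/150/200 ms."""
    return WaveConfig(
        per_neuron_lag=per_neuron_lag,
        group_onsets=(((1, 36), 50.0), ((37, 72), 150.0), ((73, 108), 200.0)),
        seed=seed,
    )


def synchronous_three_onsets(seed: int = 0) -> WaveConfig:
    """No per-neuron lag; three onset groups at 50/150/200 ms."""
    return dataclasses.replace(wave_three_onsets(seed), per_neuron_lag=0.0)


def window_tiling_wave(seed: int = 0) -> WaveConfig:
    """Wave whose peak sequence tiles the full analysis window.

    Onset near the window start with lag 600/218 ms, so the 218 peaks span
    the 600-ms window the way the real data's peak latencies spread over
    the trial. Three condition groups with onsets one grid bin apart
    (-50/-40/-30 ms) emulate modest condition-to-condition variability in
    movement-initiation timing: conditions stay similar enough for one
    linear readout to serve them all, yet per-neuron condition shuffling
    genuinely scrambles cross-neuron timing coherence. Used by the
    regression (Lissajous) experiments.
    """
    return WaveConfig(
        per_neuron_lag=600.0 / 218.0,
        group_onsets=(((1, 36), -50.0), ((37, 72), -40.0), ((73, 108), -30.0)),
        seed=seed,
    )


def ordering_wave(seed: int = 0) -> WaveConfig:
    """Coarse 10-ms-lag wave for peak-order recovery on the 10-ms grid.

    One grid bin of lag per neuron; 50 neurons so every peak (0..490 ms)
    lies inside the -50..550 ms window (218 neurons at 10 ms would overrun
    it).
    """
    return WaveConfig(
        n_neurons=50, per_neuron_lag=10.0, group_onsets=(((1, 108), 0.0),), seed=seed
    )


# ---------------------------------------------------------------- runner plumbing


@dataclass
class ExperimentConfig:
    """One experiment run: id, output directory, seed, optional overrides."""

    experiment: str
    outdir: Path
    seed: int = 0
    wave: WaveConfig | None = None  # override the experiment's canonical config
    num_pcs: int = 6
    options: dict = field(default_factory=dict)


def _summary_dict(fit, summary, report) -> dict:
    return {
        "omega_rad_per_ms": summary.omega,
        "r2_skew": fit.r2_skew,
        "r2_best": fit.r2_best,
        "direction_consistency": summary.direction_consistency,
        "degenerate": bool(report.degenerate),
        "residual_fraction": report.residual_fraction,
        "rescaling_residual_fraction": report.rescaling_residual_fraction,
        "mean_subtraction_applied": bool(report.applied),
    }


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _projection_frame(pop: PopulationPETH, summary) -> pd.DataFrame:
    c, t, _ = summary.projections.shape
    return pd.DataFrame(
        {
            "condition": np.repeat(pop.condition_ids[:c], t),
            "time_ms": np.tile(pop.grid.times[:t], c),
            "proj1": summary.projections[..., 0].ravel(),
            "proj2": summary.projections[..., 1].ravel(),
        }
    )


def _jpca_to_dir(pop: PopulationPETH, outdir: Path, tag: str, subtract_mean: bool, num_pcs: int) -> dict:
    fit, summary, report = jpca_pipeline(pop, subtract_mean=subtract_mean, num_pcs=num_pcs)
    d = _summary_dict(fit, summary, report)
    _write_json(outdir / f"{tag}_summary.json", d)
    pd.DataFrame(fit.M_skew).to_csv(outdir / f"{tag}_m_skew.csv", index=False)
    _projection_frame(pop, summary).to_csv(outdir / f"{tag}_projections.csv", index=False)
    log.info(
        "%s: consistency=%.3f r2_skew=%.3f r2_best=%.3f degenerate=%s",
        tag, d["direction_consistency"], d["r2_skew"], d["r2_best"], d["degenerate"],
    )
    return d


# ---------------------------------------------------------------- experiments


def _run_peth_order(cfg: ExperimentConfig, outdir: Path) -> dict:
    pop = simulate_wave(cfg.wave or ordering_wave(cfg.seed))
    table = build_peak_table(pop)
    avg = average_across_conditions(pop)
    pd.DataFrame(
        {
            "neuron": pop.neuron_ids,
            "avg_peak_ms": table.peak_ms,
            "rank": np.argsort(table.order) + 1,
        }
    ).to_csv(outdir / "peak_table.csv", index=False)
    scatter = pd.DataFrame(
        {
            "neuron": np.repeat(pop.neuron_ids, pop.n_conditions),
            "condition": np.tile(pop.condition_ids, pop.n_neurons),
            "peak_ms": table.condition_peak_ms.ravel(),
        }
    )
    scatter.to_csv(outdir / "peak_scatter.csv", index=False)
    pd.DataFrame(pairwise_correlation(avg)).to_csv(outdir / "correlation_matrix.csv", index=False)
    identity = bool(np.array_equal(table.order, np.arange(pop.n_neurons)))
    return {"order_is_identity": identity, "n_neurons": pop.n_neurons}


def _run_subpop3d(cfg: ExperimentConfig, outdir: Path) -> dict:
    pop = simulate_wave(cfg.wave or wave_two_onsets(cfg.seed))
    table = build_peak_table(pop)
    split = split_subpopulations(table, 3, pop)
    g, c, t = split.group_condition_avg.shape
    frame = pd.DataFrame(
        {
            "group": np.repeat(np.arange(1, g + 1), c * t),
            "condition": np.tile(np.repeat(pop.condition_ids, t), g),
            "time_ms": np.tile(pop.grid.times, g * c),
            "rate": split.group_condition_avg.ravel(),
        }
    )
    frame.to_csv(outdir / "group_condition_avg.csv", index=False)
    # the 3D trace: one (time x 3) table per condition, groups as axes
    traces = split.group_condition_avg.transpose(1, 2, 0).reshape(c * t, g)
    pd.DataFrame(
        {
            "condition": np.repeat(pop.condition_ids, t),
            "time_ms": np.tile(pop.grid.times, c),
            "early": traces[:, 0],
            "intermediate": traces[:, 1],
            "late": traces[:, 2],
        }
    ).to_csv(outdir / "trace3d.csv", index=False)
    return {"group_sizes": list(split.sizes)}


def _run_pca_traj(cfg: ExperimentConfig, outdir: Path) -> dict:
    pop = simulate_wave(cfg.wave or wave_two_onsets(cfg.seed))
    traj = pca_reduce(standardize(pop), 3)
    c, t, k = traj.scores.shape
    frame = pd.DataFrame(
        np.column_stack(
            [np.repeat(pop.condition_ids, t), np.tile(pop.grid.times, c), traj.scores.reshape(-1, k)]
        ),
        columns=["condition", "time_ms"] + [f"pc{i + 1}" for i in range(k)],
    )
    frame.to_csv(outdir / "pca_trajectories.csv", index=False)
    _write_json(
        outdir / "pca_summary.json",
        {"explained_variance_ratio": traj.explained_variance_ratio.tolist()},
    )
    return {"explained_variance_ratio": traj.explained_variance_ratio.tolist()}


def _run_jpca_variants(cfg: ExperimentConfig, outdir: Path) -> dict:
    pop = simulate_wave(cfg.wave or wave_single_onset(cfg.seed))
    return {
        "subtract_on": _jpca_to_dir(pop, outdir, "subtract_on", True, cfg.num_pcs),
        "subtract_off": _jpca_to_dir(pop, outdir, "subtract_off", False, cfg.num_pcs),
    }


def _run_wave_groups(cfg: ExperimentConfig, outdir: Path) -> dict:
    out = {}
    for tag, config in (
        ("two_groups", wave_two_onsets(cfg.seed)),
        ("three_groups", wave_three_onsets(cfg.seed)),
    ):
        pop = simulate_wave(cfg.wave or config)
        out[tag] = _jpca_to_dir(pop, outdir, tag, True, cfg.num_pcs)
    return out


def _run_synchronous(cfg: ExperimentConfig, outdir: Path) -> dict:
    pop = simulate_synchronous(cfg.wave or synchronous_three_onsets(cfg.seed))
    return {
        "subtract_on": _jpca_to_dir(pop, outdir, "subtract_on", True, cfg.num_pcs),
        "subtract_off": _jpca_to_dir(pop, outdir, "subtract_off", False, cfg.num_pcs),
    }


def _run_mean_subtraction_off(cfg: ExperimentConfig, outdir: Path) -> dict:
    wave2 = simulate_wave(wave_two_onsets(cfg.seed))
    datasets = {
        "wave_single": simulate_wave(wave_single_onset(cfg.seed)),
        "wave_two_groups": wave2,
        "wave_two_groups_shuffled": shuffle_conditions(wave2, seed=cfg.seed + 1),
        "synchronous": simulate_synchronous(synchronous_three_onsets(cfg.seed)),
    }
    return {tag: _jpca_to_dir(pop, outdir, tag, False, cfg.num_pcs) for tag, pop in datasets.items()}


def _run_lissajous(cfg: ExperimentConfig, outdir: Path) -> dict:
    pop = simulate_wave(cfg.wave or window_tiling_wave(cfg.seed))
    even = np.arange(0, pop.n_conditions, 2)
    odd = np.arange(1, pop.n_conditions, 2)
    results: dict = {}
    for shape in ("circle", "infinity"):
        target = make_targets(pop.grid, shape)
        full = fit_lissajous(pop, target)
        half = fit_lissajous(pop, target, train_conditions=even)
        curves, r2_test = predict(half, pop, odd)
        t = pop.n_times
        pd.DataFrame(
            {
                "condition": np.repeat(pop.condition_ids[odd], t),
                "time_ms": np.tile(pop.grid.times, len(odd)),
                "x_hat": curves[..., 0].ravel(),
                "y_hat": curves[..., 1].ravel(),
            }
        ).to_csv(outdir / f"{shape}_predicted_curves.csv", index=False)
        coef_cols = [f"n{i}" for i in range(1, pop.n_neurons + 1)] + (["intercept"] if full.intercept else [])
        pd.DataFrame(full.coef.T, columns=coef_cols, index=["x", "y"]).to_csv(outdir / f"{shape}_coefficients.csv")
        results[shape] = {
            "r2_train_full": full.r2_train,
            "r2_train_half": half.r2_train,
            "r2_test": r2_test,
        }
    # shuffled control: per-neuron condition shuffling before fitting the figure eight
    shuffled = shuffle_conditions(pop, seed=cfg.seed + 1)
    target = make_targets(pop.grid, "infinity")
    half_sh = fit_lissajous(shuffled, target, train_conditions=even)
    _, r2_test_sh = predict(half_sh, shuffled, odd)
    results["infinity_shuffled"] = {"r2_train_half": half_sh.r2_train, "r2_test": r2_test_sh}
    _write_json(outdir / "lissajous_summary.json", results)
    return results


EXPERIMENTS = {
    "peth_order": _run_peth_order,
    "subpop3d": _run_subpop3d,
    "pca_traj": _run_pca_traj,
    "jpca_variants": _run_jpca_variants,
    "wave_groups": _run_wave_groups,
    "synchronous": _run_synchronous,
    "mean_subtraction_off": _run_mean_subtraction_off,
    "lissajous": _run_lissajous,
}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one experiment, write its output bundle, and return its results.

    Writes ``manifest.json`` (config, seed, version) and ``results.json``
    alongside the experiment's CSV outputs. Deterministic given the config.
    """
    if cfg.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; valid ids: {sorted(EXPERIMENTS)}"
        )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = EXPERIMENTS[cfg.experiment](cfg, outdir)
    manifest = {
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "num_pcs": cfg.num_pcs,
        "wave": None if cfg.wave is None else dataclasses.asdict(cfg.wave),
        "options": cfg.options,
        "version": __version__,
    }
    _write_json(outdir / "manifest.json", manifest)
    _write_json(outdir / "results.json", results)
    return results
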