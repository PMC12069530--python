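"""End-to-end orchestration: synthetic session -> behavior -> decoding ->
geometry -> encoding models, driven by one TOML config.

Every stage reads its inputs from the run directory through the serialized
interfaces (CSV trial table, HDF5 spike store) and writes its outputs there,
so stages can run in separate processes.  Each stochastic stage carries an
explicit seed in the config; given the same config the run directory's CSV
outputs are byte-identical.  Defaults mirror the full study conditions (160
neurons, 60 trials per condition, 63 bins, 50 resamples, 20 shuffles); scale
them down in the config for quick runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .behavior_stats import behavior_report, compare_reaction_times
from .core_data import REWARD_SIZES, bin_spike_counts, load_session, write_session
from .decoding import (
    DecoderSpec,
    assess_significance,
    balanced_decode,
    build_null,
    decode_timecourse,
    significance_stars,
    sliding_window_decode,
)
from .encoding_models import feedback_property_anova, variance_partition
from .errors import OiprError
from .geometry import run_projection_analysis
from .pseudopopulation import population_from_binned, select_eligible_neurons
from .synthetic_data import AgentParams, TaskDesignParams, TuningSpec, generate_session

log = logging.getLogger("oipr")


class SimulateConfig(BaseModel):
    n_blocks: int = 20
    n_neurons: int = 160
    seed: int = 1
    task: dict = Field(default_factory=dict)
    agent: dict = Field(default_factory=dict)
    tuning: dict = Field(default_factory=dict)


class BinningConfig(BaseModel):
    bin_width: float = 250.0
    bin_step: float = 25.0
    delay_span: tuple[float, float] = (-500.0, 1300.0)
    feedback_span: tuple[float, float] = (-500.0, 1300.0)


class DecodeConfig(BaseModel):
    n_per_condition: int = 60
    n_per_condition_action: int = 25  # stay/switch trials are scarcer
    k_folds: int = 10
    n_resamples: int = 50
    n_shuffles: int = 20
    null_resamples: int | None = None
    min_consecutive: int = 5
    C: float = 1.0
    multiclass: str = "ovr"
    seed: int = 2


class WindowsConfig(BaseModel):
    window: int = 10
    step: int = 1
    min_trials_per_condition: int = 20
    n_resamples: int = 50
    n_shuffles: int = 20
    null_resamples: int | None = None
    k_folds: int = 5
    seed: int = 3


class BalancedConfig(BaseModel):
    window_ms: tuple[float, float] = (800.0, 1000.0)  # re scene onset
    min_per_cell: int = 10
    n_shuffles: int = 25
    n_resamples: int = 10
    seed: int = 4


class GeometryConfig(BaseModel):
    n_per_condition: int = 60
    n_resamples: int = 100
    overlap_threshold: float = 0.05
    min_consecutive: int = 5
    seed: int = 5


class EncodeConfig(BaseModel):
    delay_window_ms: tuple[float, float] = (0.0, 800.0)  # re scene onset
    feedback_window_ms: tuple[float, float] = (0.0, 400.0)  # re feedback onset
    n_property_levels: int = 3
    seed: int = 6


class StagesConfig(BaseModel):
    simulate: bool = True
    behavior: bool = True
    decode: bool = True
    windows: bool = True
    balanced: bool = True
    geometry: bool = True
    encode: bool = True


class PipelineConfig(BaseModel):
    out_dir: str = "runs/oipr"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    binning: BinningConfig = Field(default_factory=BinningConfig)
    decode: DecodeConfig = Field(default_factory=DecodeConfig)
    windows: WindowsConfig = Field(default_factory=WindowsConfig)
    balanced: BalancedConfig = Field(default_factory=BalancedConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    encode: EncodeConfig = Field(default_factory=EncodeConfig)
    stages: StagesConfig = Field(default_factory=StagesConfig)


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_bytes()
    return PipelineConfig.model_validate(tomllib.loads(text.decode()))


def _session_paths(run_dir: Path) -> tuple[Path, Path]:
    return run_dir / "trials.csv", run_dir / "spikes.h5"


def _load(run_dir: Path):
    return load_session(*_session_paths(run_dir))


def _epoch_binned(trials, spikes, cfg: PipelineConfig, epoch: str):
    b = cfg.binning
    event = "scene_onset" if epoch == "delay" else "feedback_onset"
    span = b.delay_span if epoch == "delay" else b.feedback_span
    return bin_spike_counts(spikes, trials, event, span, b.bin_width, b.bin_step)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> None:
    s = cfg.simulate
    trials, spikes = generate_session(
        task=TaskDesignParams(n_blocks=s.n_blocks, **s.task),
        agent=AgentParams(**s.agent),
        tuning=TuningSpec(**s.tuning),
        n_neurons=s.n_neurons,
        seed=s.seed,
    )
    write_session(trials, spikes, *_session_paths(run_dir))
    log.info("simulated %d trials, %d neurons", len(trials), len(spikes))


def stage_behavior(cfg: PipelineConfig, run_dir: Path) -> None:
    trials, _ = _load(run_dir)
    behavior_report(trials).to_csv(run_dir / "behavior_report.csv", index=False)
    compare_reaction_times(trials).to_csv(run_dir / "behavior_rt_ks.csv", index=False)


def _decode_epoch(cfg: PipelineConfig, run_dir: Path, epoch: str, labels, name: str,
                  conditions: list) -> None:
    trials, spikes = _load(run_dir)
    binned = _epoch_binned(trials, spikes, cfg, epoch)
    keep = ~pd.isna(labels)
    binned.counts = binned.counts[:, np.asarray(keep), :]
    labels = np.asarray(labels)[np.asarray(keep)]
    d = cfg.decode
    n_per = d.n_per_condition_action if name == "action" else d.n_per_condition
    pop = select_eligible_neurons(
        population_from_binned(binned, labels), n_per, conditions
    )
    spec = DecoderSpec(
        C=d.C, k_folds=d.k_folds, n_resamples=d.n_resamples,
        n_per_condition=n_per, multiclass=d.multiclass,
    )
    res = decode_timecourse(
        pop, spec, seed=d.seed, conditions=conditions, bin_centers=binned.bin_centers
    )
    null = build_null(
        pop, spec, n_shuffles=d.n_shuffles, seed=d.seed + 1,
        conditions=conditions, n_resamples=d.null_resamples,
    )
    sig = assess_significance(res, null, min_consecutive=d.min_consecutive)
    pd.DataFrame(
        {"bin_center_ms": res.bin_centers, "mean_accuracy": res.mean_accuracy,
         "resample_sd": res.resample_sd, "z_score": sig.z_scores,
         "p_normal": sig.p_normal, "p_empirical": sig.p_empirical,
         "significant": sig.mask}
    ).to_csv(run_dir / f"decode_{name}_{epoch}.csv", index=False)
    with open(run_dir / f"decode_{name}_{epoch}_null.json", "w") as f:
        json.dump(
            {"null_mean": float(null.values.mean()),
             "null_sd": float(null.values.std(ddof=1)),
             "null_size": int(null.size),
             "corrected_alpha": null.corrected_alpha,
             "chance": res.chance, "n_neurons": len(pop), "seed": d.seed},
            f, indent=2,
        )


def stage_decode(cfg: PipelineConfig, run_dir: Path) -> None:
    trials, _ = _load(run_dir)
    reward = trials["reward_size"].to_numpy()
    for epoch in ("delay", "feedback"):
        _decode_epoch(cfg, run_dir, epoch, reward, "reward", list(REWARD_SIZES))
    action = trials["stay_switch"].replace({"undefined": None}).to_numpy()
    _decode_epoch(cfg, run_dir, "delay", action, "action", ["stay", "switch"])


def stage_windows(cfg: PipelineConfig, run_dir: Path) -> None:
    trials, spikes = _load(run_dir)
    w = cfg.windows
    for epoch in ("delay", "feedback"):
        binned = _epoch_binned(trials, spikes, cfg, epoch)
        spec = DecoderSpec(
            k_folds=w.k_folds, n_resamples=w.n_resamples,
            n_per_condition=w.min_trials_per_condition,
        )
        res = sliding_window_decode(
            binned, trials, trials["reward_size"].to_numpy(), spec,
            window=w.window, step=w.step,
            min_trials_per_condition=w.min_trials_per_condition,
            n_shuffles=w.n_shuffles, null_resamples=w.null_resamples, seed=w.seed,
        )
        acc = pd.DataFrame(res.accuracy, index=res.window_starts,
                           columns=res.bin_centers)
        acc.index.name = "window_start_trial"
        acc.to_csv(run_dir / f"windows_{epoch}_accuracy.csv")
        sig = pd.DataFrame(res.significant, index=res.window_starts,
                           columns=res.bin_centers)
        sig.index.name = "window_start_trial"
        sig.to_csv(run_dir / f"windows_{epoch}_significant.csv")


def stage_balanced(cfg: PipelineConfig, run_dir: Path) -> None:
    trials, spikes = _load(run_dir)
    b = cfg.balanced
    keep = trials["stay_switch"].isin(["stay", "switch"]).to_numpy()
    sub = trials[keep].reset_index(drop=True)
    width = b.window_ms[1] - b.window_ms[0]
    binned = bin_spike_counts(
        spikes, sub, "scene_onset", span=b.window_ms, bin_width=width, bin_step=width
    )
    counts = binned.counts[:, :, 0].astype(float)
    labels_a = np.where(sub["reward_size"] == "small", "small", "medlarge")
    labels_b = sub["stay_switch"].to_numpy()
    res = balanced_decode(
        counts, labels_a, labels_b, min_per_cell=b.min_per_cell,
        n_shuffles=b.n_shuffles, n_resamples=b.n_resamples, seed=b.seed,
    )
    with open(run_dir / "balanced.json", "w") as f:
        json.dump(
            {"variable_a": "reward (small vs medium+large)",
             "variable_b": "action (stay vs switch)",
             "accuracy_a": res.accuracy_a, "accuracy_b": res.accuracy_b,
             "p_a": res.p_a, "p_b": res.p_b,
             "stars_a": significance_stars(res.p_a),
             "stars_b": significance_stars(res.p_b),
             "null_mean_a": float(res.null_a.mean()),
             "null_mean_b": float(res.null_b.mean()),
             "n_neurons": res.n_neurons, "n_per_cell": res.n_per_cell,
             "chance": res.chance, "window_ms": list(b.window_ms), "seed": b.seed},
            f, indent=2,
        )


def stage_geometry(cfg: PipelineConfig, run_dir: Path) -> None:
    trials, spikes = _load(run_dir)
    g = cfg.geometry
    reward = trials["reward_size"].to_numpy()
    summary = {}
    for epoch in ("delay", "feedback"):
        binned = _epoch_binned(trials, spikes, cfg, epoch)
        pop = select_eligible_neurons(
            population_from_binned(binned, reward), g.n_per_condition,
            list(REWARD_SIZES),
        )
        res = run_projection_analysis(
            pop, n_per_condition=g.n_per_condition, n_resamples=g.n_resamples,
            seed=g.seed, conditions=list(REWARD_SIZES),
            bin_centers=binned.bin_centers, overlap_threshold=g.overlap_threshold,
            min_consecutive=g.min_consecutive,
        )
        rows = []
        for ci, cond in enumerate(res.conditions):
            for b in range(len(res.bin_centers)):
                rows.append(
                    {"bin_center_ms": res.bin_centers[b], "condition": cond,
                     "projection_mean": res.projections[:, b, ci].mean(),
                     "projection_sd": res.projections[:, b, ci].std(ddof=1)}
                )
        pd.DataFrame(rows).to_csv(run_dir / f"geometry_{epoch}_projections.csv",
                                  index=False)
        ov_rows = []
        for (ca, cb), ov in res.overlap.items():
            for b in range(len(res.bin_centers)):
                ov_rows.append(
                    {"bin_center_ms": res.bin_centers[b], "pair": f"{ca}-{cb}",
                     "overlap": ov[b], "different": bool(res.different[(ca, cb)][b])}
                )
        pd.DataFrame(ov_rows).to_csv(run_dir / f"geometry_{epoch}_overlap.csv",
                                     index=False)
        summary[epoch] = {
            f"{ca}-{cb}": int(res.different[(ca, cb)].sum())
            for (ca, cb) in res.overlap
        }
    with open(run_dir / "geometry_summary.json", "w") as f:
        json.dump({"significant_bins_per_pair": summary, "seed": g.seed}, f, indent=2)


def stage_encode(cfg: PipelineConfig, run_dir: Path) -> None:
    trials, spikes = _load(run_dir)
    e = cfg.encode
    rt_mov = (trials["reaction_time"] + trials["movement_time"]).to_numpy()
    reward = trials["reward_size"].to_numpy()
    epochs = {
        "delay": ("scene_onset", e.delay_window_ms),
        "feedback": ("feedback_onset", e.feedback_window_ms),
    }
    rows = []
    for epoch, (event, win) in epochs.items():
        width = win[1] - win[0]
        binned = bin_spike_counts(spikes, trials, event, span=win,
                                  bin_width=width, bin_step=width)
        rates = binned.counts[:, :, 0].astype(float) / (width / 1000.0)
        for i in range(rates.shape[0]):
            vp = variance_partition(
                rates[i], rt_mov, reward, neuron_id=binned.neuron_ids[i],
                epoch=epoch,
            )
            rows.append(vp.__dict__)
    pd.DataFrame(rows).to_csv(run_dir / "variance_partition.csv", index=False)

    width = e.feedback_window_ms[1] - e.feedback_window_ms[0]
    binned = bin_spike_counts(
        spikes, trials, "feedback_onset", span=e.feedback_window_ms,
        bin_width=width, bin_step=width,
    )
    rates = binned.counts[:, :, 0].astype(float) / (width / 1000.0)

    # property-blind control: synthetic shape labels independent of activity
    rng = np.random.default_rng(e.seed)
    prop = rng.integers(e.n_property_levels, size=len(trials))
    feedback_property_anova(
        rates, prop, trials["correct"].to_numpy()
    ).to_csv(run_dir / "feedback_property_anova.csv", index=False)


STAGES = {
    "simulate": stage_simulate,
    "behavior": stage_behavior,
    "decode": stage_decode,
    "windows": stage_windows,
    "balanced": stage_balanced,
    "geometry": stage_geometry,
    "encode": stage_encode,
}


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    config_text: str | None = None,
) -> Path:
    """Run every enabled stage into one run directory and write a manifest
    (package version, config hash, per-stage wall time)."""
    run_dir = Path(out_dir or config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if config_text is None:
        config_text = json.dumps(config.model_dump(), sort_keys=True, default=str)
    (run_dir / "config_echo.txt").write_text(config_text)
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "stages": {},
    }
    for name, fn in STAGES.items():
        if not getattr(config.stages, name):
            log.info("stage %s disabled", name)
            continue
        t0 = time.perf_counter()
        try:
            fn(config, run_dir)
        except OiprError as err:
            raise OiprError(f"stage {name!r} failed: {err}") from err
        manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.1fs", name, manifest["stages"][name]["wall_time_s"])
    with open(run_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return run_dir
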