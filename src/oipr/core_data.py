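"""Domain containers and I/O for the object-in-place reward (OIPR) task.

A session is described by two objects:

* a *trial table* — a :class:`pandas.DataFrame` with one row per completed
  trial (columns in :data:`TRIAL_COLUMNS`), carrying the block design, the
  behavior and the event timestamps on a single session clock (ms);
* a list of :class:`SpikeData` — per-neuron spike times on the same clock.

Event-aligned binning produces a :class:`BinnedActivity` (neuron x trial x
time-bin spike counts) that every downstream analysis consumes.

Conventions fixed here and relied on everywhere else:

* all times are milliseconds; event times live on one session clock, bin
  centers are relative to the alignment event;
* bins are half-open ``[start, start + width)`` — a spike exactly on a
  boundary belongs to the later bin;
* the number of sliding bins for a span ``(a, b)`` is
  ``floor((b - a - width) / step) + 1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError, ValidationError

REWARD_SIZES = ("small", "medium", "large")
STAY_SWITCH = ("stay", "switch", "undefined")
ALIGNMENT_EVENTS = ("scene_onset", "feedback_onset")

N_SCENES = 5
N_RUNS = 6
TRIALS_PER_BLOCK = N_SCENES * N_RUNS

#: Trial-table columns, in canonical order. ``stay_switch`` is written to CSV
#: as the empty string when undefined (run 1).
TRIAL_COLUMNS = [
    "session_id",
    "block_index",
    "run_index",
    "scene_index",
    "trial_index_in_block",
    "reward_size",
    "correct",
    "chosen_object",
    "chosen_position",
    "stay_switch",
    "reaction_time",
    "movement_time",
    "scene_onset",
    "go_signal",
    "feedback_onset",
]


@dataclass
class SpikeData:
    """Spike times (ms, session clock) of one neuron in one session."""

    neuron_id: str
    session_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_times.ndim != 1:
            raise ValidationError(f"{self.neuron_id}: spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(
                f"{self.neuron_id}: spike times must be non-decreasing"
            )


@dataclass
class BinnedActivity:
    """Event-aligned spike counts: ``counts[neuron, trial, bin]``."""

    counts: np.ndarray
    bin_centers: np.ndarray  # ms relative to the alignment event
    bin_width: float
    bin_step: float
    alignment_event: str
    span: tuple[float, float]
    neuron_ids: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


def n_sliding_bins(span: tuple[float, float], bin_width: float, bin_step: float) -> int:
    """Number of sliding bins of ``bin_width`` advancing by ``bin_step``
    that fit in ``span`` (last bin must end within the span)."""
    length = span[1] - span[0]
    if length < bin_width:
        raise ParameterError(
            f"span length {length} ms shorter than bin width {bin_width} ms"
        )
    return int(np.floor((length - bin_width) / bin_step)) + 1


def validate_trial_table(
    trials: pd.DataFrame, require_complete_blocks: bool = False
) -> None:
    """Check the trial-table invariants, raising a row-addressed report.

    Checks: required columns, category values, run-1 rows have undefined
    stay/switch, reward size constant within (session, block, scene), and —
    when ``require_complete_blocks`` — exactly 30 trials per block.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")

    problems: list[str] = []
    for idx, row in enumerate(trials.itertuples(index=False)):
        if row.reward_size not in REWARD_SIZES:
            problems.append(f"row {idx}: reward_size {row.reward_size!r} unknown")
        if row.stay_switch not in STAY_SWITCH:
            problems.append(f"row {idx}: stay_switch {row.stay_switch!r} unknown")
        elif row.run_index == 1 and row.stay_switch != "undefined":
            problems.append(
                f"row {idx}: run 1 trial has stay_switch={row.stay_switch!r}"
            )
        if not 1 <= row.run_index <= N_RUNS:
            problems.append(f"row {idx}: run_index {row.run_index} outside 1..6")
        if not 1 <= row.scene_index <= N_SCENES:
            problems.append(f"row {idx}: scene_index {row.scene_index} outside 1..5")

    for (sid, blk, scene), grp in trials.groupby(
        ["session_id", "block_index", "scene_index"]
    ):
        if grp["reward_size"].nunique() > 1:
            problems.append(
                f"session {sid} block {blk} scene {scene}: reward size not "
                f"constant across runs ({sorted(grp['reward_size'].unique())})"
            )

    if require_complete_blocks:
        sizes = trials.groupby(["session_id", "block_index"]).size()
        for (sid, blk), n in sizes.items():
            if n != TRIALS_PER_BLOCK:
                problems.append(
                    f"session {sid} block {blk}: {n} trials, expected "
                    f"{TRIALS_PER_BLOCK}"
                )

    if problems:
        raise ValidationError(
            f"trial table failed validation ({len(problems)} problems)", problems
        )


def complete_blocks(trials: pd.DataFrame) -> pd.DataFrame:
    """Rows belonging to blocks with the full 30 trials (block-level
    analyses exclude a session's trailing incomplete block)."""
    sizes = trials.groupby(["session_id", "block_index"]).size()
    ok = sizes[sizes == TRIALS_PER_BLOCK].index
    key = pd.MultiIndex.from_frame(trials[["session_id", "block_index"]])
    return trials[key.isin(ok)].reset_index(drop=True)


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

def bin_spike_counts(
    spikes: SpikeData | list[SpikeData],
    trials: pd.DataFrame,
    alignment_event: str,
    span: tuple[float, float] = (-500.0, 1300.0),
    bin_width: float = 250.0,
    bin_step: float = 25.0,
) -> BinnedActivity:
    """Count spikes in sliding bins around ``alignment_event`` of each trial.

    ``counts[i, t, b]`` is the number of spikes of neuron ``i`` in the
    half-open window ``[e_t + span[0] + b*step, e_t + span[0] + b*step +
    width)`` where ``e_t`` is the event time of trial ``t``.
    """
    if alignment_event not in trials.columns:
        raise SchemaError(f"trials have no column {alignment_event!r}")
    if trials[alignment_event].isna().any():
        raise ValidationError(f"{alignment_event} missing for some trials")
    if isinstance(spikes, SpikeData):
        spikes = [spikes]

    nb = n_sliding_bins(span, bin_width, bin_step)
    starts = span[0] + bin_step * np.arange(nb)
    centers = starts + bin_width / 2.0
    events = trials[alignment_event].to_numpy(dtype=np.float64)

    # absolute bin edges for every (trial, bin): lo/hi arrays [n_trials, nb]
    lo = events[:, None] + starts[None, :]
    hi = lo + bin_width
    counts = np.empty((len(spikes), len(events), nb), dtype=np.int64)
    for i, sd in enumerate(spikes):
        st = sd.spike_times
        counts[i] = np.searchsorted(st, hi, side="left") - np.searchsorted(
            st, lo, side="left"
        )
    return BinnedActivity(
        counts=counts,
        bin_centers=centers,
        bin_width=bin_width,
        bin_step=bin_step,
        alignment_event=alignment_event,
        span=(float(span[0]), float(span[1])),
        neuron_ids=[sd.neuron_id for sd in spikes],
    )


# --------------------------------------------------------------------------
# session I/O: CSV trial table + HDF5 spike store
# --------------------------------------------------------------------------

def write_session(
    trials: pd.DataFrame,
    spikes: list[SpikeData],
    trial_table_path: str | os.PathLike,
    spike_store_path: str | os.PathLike,
) -> None:
    """Write a session to disk (CSV trial table, HDF5 spike store).

    Undefined stay/switch is encoded as the empty string in CSV.
    """
    out = trials[TRIAL_COLUMNS].copy()
    out["stay_switch"] = out["stay_switch"].replace({"undefined": ""})
    out.to_csv(trial_table_path, index=False)

    with h5py.File(spike_store_path, "w") as f:
        grp = f.create_group("neurons")
        for sd in spikes:
            g = grp.create_group(sd.neuron_id)
            g.create_dataset("spike_times", data=sd.spike_times, dtype="float64")
            g.attrs["neuron_id"] = sd.neuron_id
            g.attrs["session_id"] = sd.session_id


def load_session(
    trial_table_path: str | os.PathLike,
    spike_store_path: str | os.PathLike,
    require_complete_blocks: bool = False,
) -> tuple[pd.DataFrame, list[SpikeData]]:
    """Load and validate one session (inverse of :func:`write_session`)."""
    trials = pd.read_csv(
        trial_table_path,
        dtype={"session_id": str, "chosen_object": str},
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing required columns: {missing}")
    trials["stay_switch"] = trials["stay_switch"].replace({"": "undefined"})
    for col in ("block_index", "run_index", "scene_index", "trial_index_in_block",
                "chosen_position"):
        trials[col] = trials[col].astype(int)
    for col in ("reaction_time", "movement_time", "scene_onset", "go_signal",
                "feedback_onset"):
        trials[col] = trials[col].astype(float)
    trials["correct"] = trials["correct"].map(
        {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
    )
    if trials["correct"].isna().any():
        raise SchemaError("column 'correct' contains non-boolean values")
    trials["correct"] = trials["correct"].astype(bool)
    validate_trial_table(trials, require_complete_blocks=require_complete_blocks)

    spikes: list[SpikeData] = []
    with h5py.File(spike_store_path, "r") as f:
        for name in f["neurons"]:
            g = f["neurons"][name]
            spikes.append(
                SpikeData(
                    neuron_id=str(g.attrs["neuron_id"]),
                    session_id=str(g.attrs["session_id"]),
                    spike_times=g["spike_times"][...],
                )
            )
    return trials, spikes


def save_binned(binned: BinnedActivity, path: str | os.PathLike) -> None:
    """Cache a BinnedActivity in HDF5 (3-D dataset plus attributes)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=binned.counts)
        d.attrs["bin_width"] = binned.bin_width
        d.attrs["bin_step"] = binned.bin_step
        d.attrs["alignment_event"] = binned.alignment_event
        d.attrs["span"] = list(binned.span)
        f.create_dataset("bin_centers", data=binned.bin_centers)
        f.create_dataset(
            "neuron_ids", data=np.array(binned.neuron_ids, dtype=h5py.string_dtype())
        )


def load_binned(path: str | os.PathLike) -> BinnedActivity:
    with h5py.File(path, "r") as f:
        d = f["counts"]
        return BinnedActivity(
            counts=d[...],
            bin_centers=f["bin_centers"][...],
            bin_width=float(d.attrs["bin_width"]),
            bin_step=float(d.attrs["bin_step"]),
            alignment_event=str(d.attrs["alignment_event"]),
            span=tuple(float(x) for x in d.attrs["span"]),
            neuron_ids=[s.decode() for s in f["neuron_ids"][...]],
        )
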