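"""Synthetic OIPR sessions: task design, agent behavior, Poisson spiking.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline can be exercised and validated without any
recorded data:

* **design** — blocks of 30 trials (5 scenes x 6 runs); within a block the
  scene order is fixed across runs and each scene is bound to one of three
  reward sizes, with all three sizes present and no size used for three
  scenes (the composition over scenes is always 2+2+1);
* **behavior** — a phenomenological stay/switch agent: run-1 choices are a
  coin flip, afterwards the agent repeats its previous choice for the same
  scene with a probability that depends on the reward size and on whether
  that previous choice was correct.  Defaults make learning fast for medium
  and large reward, slower (more exploratory) for small reward, and give
  small-reward trials longer reaction times;
* **spiking** — per-neuron Poisson spike trains: a constant baseline plus
  additive rate gains in event-locked windows.  Feedback gains separate the
  three reward sizes from the first trial of a block; delay gains separate
  small from a *merged* medium/large representation, switch on only late in
  the scene (onset latency) and only once the within-block trial index
  reaches a learning gate; an action gain separates stay from switch trials
  in a late-delay window.

With a fixed seed the output is reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    N_RUNS,
    N_SCENES,
    REWARD_SIZES,
    TRIAL_COLUMNS,
    SpikeData,
)
from .errors import ParameterError

__all__ = [
    "TaskDesignParams",
    "AgentParams",
    "TuningSpec",
    "generate_block_design",
    "simulate_behavior",
    "simulate_spikes",
    "generate_session",
]


@dataclass
class TaskDesignParams:
    """Block structure of the task. Reward volumes are metadata only."""

    n_scenes: int = N_SCENES
    n_runs: int = N_RUNS
    n_blocks: int = 10
    reward_volumes_ml: dict = field(
        default_factory=lambda: {"small": 0.15, "medium": 0.3, "large": 0.6}
    )
    # fixed-duration task events (ms); the delay (scene on screen before the
    # go-signal) and the feedback display each take one of two durations
    delay_durations_ms: tuple[float, float] = (800.0, 1200.0)
    feedback_durations_ms: tuple[float, float] = (400.0, 600.0)
    inter_trial_interval_ms: float = 2000.0

    def validate(self) -> None:
        if self.n_scenes != N_SCENES or self.n_runs != N_RUNS:
            raise ParameterError("task structure is fixed at 5 scenes x 6 runs")
        if self.n_blocks < 0:
            raise ParameterError("n_blocks must be >= 0")


@dataclass
class AgentParams:
    """Outcome-conditional stay/switch agent.

    ``p_stay_after_correct`` / ``p_stay_after_incorrect`` map reward size to
    the probability of repeating the previous choice for the same scene.
    Defaults reproduce the behavioral pattern of interest: near-perfect
    exploitation of medium/large reward once the correct object is found,
    persistent exploration (elevated switch rate, regardless of outcome) for
    small reward, and slower reaction times for small reward.
    """

    p_correct_run1: float = 0.5
    p_stay_after_correct: dict = field(
        default_factory=lambda: {"small": 0.70, "medium": 0.95, "large": 0.95}
    )
    p_stay_after_incorrect: dict = field(
        default_factory=lambda: {"small": 0.15, "medium": 0.25, "large": 0.25}
    )
    # reaction time ~ lognormal, parameterized by median (ms) and sigma
    rt_median_ms: dict = field(
        default_factory=lambda: {"small": 400.0, "medium": 320.0, "large": 300.0}
    )
    rt_sigma: float = 0.20
    movement_median_ms: float = 250.0
    movement_sigma: float = 0.15

    def validate(self) -> None:
        probs = [self.p_correct_run1]
        for d in (self.p_stay_after_correct, self.p_stay_after_incorrect):
            for size in REWARD_SIZES:
                if size not in d:
                    raise ParameterError(f"missing stay probability for {size!r}")
                probs.append(d[size])
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("all probabilities must lie in [0, 1]")


@dataclass
class TuningSpec:
    """Population tuning for the Poisson spike generator.

    Gains are additive firing-rate offsets (Hz) applied within event-locked
    windows; with every gain at zero the generator is condition-blind.  Each
    neuron is independently a coder of each feature with the given
    probability, and coders scale the population-level gains by a per-neuron
    multiplier drawn uniformly from ``gain_jitter``.
    """

    baseline_hz: float = 10.0
    # feedback epoch: three distinct levels from block start
    feedback_gains_hz: dict = field(
        default_factory=lambda: {"small": 0.0, "medium": 4.0, "large": 8.0}
    )
    feedback_window_ms: tuple[float, float] = (0.0, 400.0)  # re feedback onset
    # delay epoch: small vs merged medium/large, late onset, learning-gated
    delay_gains_hz: dict = field(
        default_factory=lambda: {"small": 0.0, "medium": 4.0, "large": 4.0}
    )
    delay_onset_ms: float = 400.0  # re scene onset; window extends to the go-signal
    learning_gate_trial: int = 15  # delay gain active for trial_index_in_block >= gate
    # stay/switch action coding in a fixed late-delay window
    action_gains_hz: dict = field(default_factory=lambda: {"stay": 0.0, "switch": 4.0})
    action_window_ms: tuple[float, float] = (800.0, 1000.0)  # re scene onset
    p_feedback_coder: float = 0.6
    p_delay_coder: float = 0.5
    p_action_coder: float = 0.4
    gain_jitter: tuple[float, float] = (0.5, 1.5)

    def validate(self) -> None:
        if self.baseline_hz < 0:
            raise ParameterError("baseline rate must be >= 0")
        for p in (self.p_feedback_coder, self.p_delay_coder, self.p_action_coder):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("coder probabilities must lie in [0, 1]")


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def _sample_reward_map(rng: np.random.Generator) -> list[str]:
    """Reward size per scene: all three sizes present, none three times,
    hence multiplicities 2+2+1 in some order."""
    single = rng.integers(3)  # which size appears once
    sizes = []
    for i, s in enumerate(REWARD_SIZES):
        sizes.extend([s] * (1 if i == single else 2))
    rng.shuffle(sizes)
    return sizes


def generate_block_design(
    params: TaskDesignParams | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Trial-table skeleton: design and event times, behavior unfilled.

    Within a block the scene order is drawn once and repeated across the six
    runs; scene identities (object sets) are fresh every block, which the
    skeleton expresses by giving every block its own scene->reward and
    scene->correct-object maps.
    """
    params = params or TaskDesignParams()
    params.validate()
    rng = np.random.default_rng(seed)

    rows = []
    clock = 1000.0  # leave headroom for pre-event baseline bins
    for blk in range(1, params.n_blocks + 1):
        scene_order = rng.permutation(N_SCENES) + 1
        reward_of_scene = dict(zip(range(1, N_SCENES + 1), _sample_reward_map(rng)))
        correct_obj = {s: rng.choice(["A", "B"]) for s in range(1, N_SCENES + 1)}
        positions = {s: rng.integers(1, 11) for s in range(1, N_SCENES + 1)}
        t = 0
        for run in range(1, N_RUNS + 1):
            for scene in scene_order:
                t += 1
                delay = rng.choice(params.delay_durations_ms)
                fb_dur = rng.choice(params.feedback_durations_ms)
                rows.append(
                    {
                        "session_id": "synthetic",
                        "block_index": blk,
                        "run_index": run,
                        "scene_index": int(scene),
                        "trial_index_in_block": t,
                        "reward_size": reward_of_scene[int(scene)],
                        "correct": False,
                        "chosen_object": "",
                        "chosen_position": int(positions[int(scene)]),
                        "stay_switch": "undefined",
                        "reaction_time": np.nan,
                        "movement_time": np.nan,
                        "scene_onset": clock,
                        "go_signal": clock + delay,
                        "feedback_onset": np.nan,  # set once RT/MT are simulated
                        "aux_correct_object": correct_obj[int(scene)],
                        "aux_delay_ms": delay,
                        "aux_feedback_dur_ms": fb_dur,
                    }
                )
                # budget per trial: delay + generous choice time + feedback +
                # inter-trial interval; refined after behavior simulation
                clock += delay + 1500.0 + fb_dur + params.inter_trial_interval_ms
    cols = TRIAL_COLUMNS + ["aux_correct_object", "aux_delay_ms", "aux_feedback_dur_ms"]
    return pd.DataFrame(rows, columns=cols)


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def simulate_behavior(
    design: pd.DataFrame, agent: AgentParams | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Fill choices, correctness, stay/switch labels and reaction/movement
    times into a design skeleton.

    Run-1 choices hit the correct object with probability
    ``p_correct_run1``; from run 2 the agent repeats its previous choice for
    the same scene with the size- and outcome-conditional stay probability,
    otherwise it picks the alternative object.
    """
    agent = agent or AgentParams()
    agent.validate()
    rng = np.random.default_rng(seed)

    trials = design.copy().reset_index(drop=True)
    prev_choice: dict[tuple, str] = {}
    prev_correct: dict[tuple, bool] = {}
    choices, corrects, staysw, rts, mts, fb_on = [], [], [], [], [], []
    for row in trials.itertuples(index=False):
        key = (row.session_id, row.block_index, row.scene_index)
        good = row.aux_correct_object
        alt = "B" if good == "A" else "A"
        if row.run_index == 1:
            choice = good if rng.random() < agent.p_correct_run1 else alt
            label = "undefined"
        else:
            p_stay = (
                agent.p_stay_after_correct[row.reward_size]
                if prev_correct[key]
                else agent.p_stay_after_incorrect[row.reward_size]
            )
            stay = rng.random() < p_stay
            choice = prev_choice[key] if stay else (
                alt if prev_choice[key] == good else good
            )
            label = "stay" if choice == prev_choice[key] else "switch"
        correct = choice == good
        prev_choice[key] = choice
        prev_correct[key] = correct

        rt = float(
            rng.lognormal(np.log(agent.rt_median_ms[row.reward_size]), agent.rt_sigma)
        )
        mt = float(rng.lognormal(np.log(agent.movement_median_ms), agent.movement_sigma))
        choices.append(choice)
        corrects.append(correct)
        staysw.append(label)
        rts.append(rt)
        mts.append(mt)
        fb_on.append(row.go_signal + rt + mt)

    trials["chosen_object"] = choices
    trials["correct"] = corrects
    trials["stay_switch"] = staysw
    trials["reaction_time"] = rts
    trials["movement_time"] = mts
    trials["feedback_onset"] = fb_on
    return trials


# --------------------------------------------------------------------------
# spiking
# --------------------------------------------------------------------------

def _add_window_spikes(
    rng: np.random.Generator, gain_hz: float, start_ms: float, end_ms: float
) -> np.ndarray:
    """Extra Poisson spikes for a positive rate gain in a window
    (superposition property of Poisson processes)."""
    dur_s = (end_ms - start_ms) / 1000.0
    n = rng.poisson(gain_hz * dur_s)
    return rng.uniform(start_ms, end_ms, size=n)


def _thin_spikes(
    rng: np.random.Generator,
    spikes: np.ndarray,
    deficit_hz: float,
    baseline_hz: float,
    start_ms: float,
    end_ms: float,
) -> np.ndarray:
    """Remove baseline spikes in a window to realize a negative gain
    (thinning); rates are clipped at zero."""
    if deficit_hz >= baseline_hz:
        warnings.warn("negative gain exceeds baseline; rate clipped at 0 Hz")
        deficit_hz = baseline_hz
    p_drop = deficit_hz / baseline_hz if baseline_hz > 0 else 0.0
    inside = (spikes >= start_ms) & (spikes < end_ms)
    drop = inside & (rng.random(spikes.size) < p_drop)
    return spikes[~drop]


def simulate_spikes(
    trials: pd.DataFrame,
    tuning: TuningSpec | None = None,
    n_neurons: int = 160,
    seed: int | None = None,
) -> list[SpikeData]:
    """Poisson spike trains with the tuning structure of :class:`TuningSpec`.

    The rate of each neuron is a constant baseline plus additive gains in
    event-locked windows (feedback reward gain; learning-gated late-delay
    reward gain; late-delay stay/switch gain).  Positive gains are realized
    by superposing extra Poisson spikes, negative ones by thinning the
    baseline train, which together implement the piecewise-constant
    inhomogeneous Poisson process exactly.
    """
    tuning = tuning or TuningSpec()
    tuning.validate()
    rng = np.random.default_rng(seed)

    t_end = float(trials["feedback_onset"].max()) + 3000.0
    session_id = str(trials["session_id"].iloc[0])

    # per-neuron effective gains: coder mask x jitter multiplier
    lo, hi = tuning.gain_jitter
    fb_mult = rng.uniform(lo, hi, n_neurons) * (
        rng.random(n_neurons) < tuning.p_feedback_coder
    )
    dl_mult = rng.uniform(lo, hi, n_neurons) * (
        rng.random(n_neurons) < tuning.p_delay_coder
    )
    ac_mult = rng.uniform(lo, hi, n_neurons) * (
        rng.random(n_neurons) < tuning.p_action_coder
    )

    scene_on = trials["scene_onset"].to_numpy()
    go = trials["go_signal"].to_numpy()
    fb_on = trials["feedback_onset"].to_numpy()
    reward = trials["reward_size"].to_numpy()
    action = trials["stay_switch"].to_numpy()
    tidx = trials["trial_index_in_block"].to_numpy()

    spikes: list[SpikeData] = []
    for i in range(n_neurons):
        n_base = rng.poisson(tuning.baseline_hz * t_end / 1000.0)
        train = rng.uniform(0.0, t_end, size=n_base)
        extras = [train]
        for t in range(len(trials)):
            # feedback reward gain, from block start
            g = tuning.feedback_gains_hz[reward[t]] * fb_mult[i]
            if g > 0:
                extras.append(
                    _add_window_spikes(
                        rng,
                        g,
                        fb_on[t] + tuning.feedback_window_ms[0],
                        fb_on[t] + tuning.feedback_window_ms[1],
                    )
                )
            elif g < 0:
                extras[0] = _thin_spikes(
                    rng, extras[0], -g, tuning.baseline_hz,
                    fb_on[t] + tuning.feedback_window_ms[0],
                    fb_on[t] + tuning.feedback_window_ms[1],
                )
            # learning-gated delay reward gain, scene+onset .. go-signal
            if tidx[t] >= tuning.learning_gate_trial:
                g = tuning.delay_gains_hz[reward[t]] * dl_mult[i]
                a, b = scene_on[t] + tuning.delay_onset_ms, go[t]
                if b > a:
                    if g > 0:
                        extras.append(_add_window_spikes(rng, g, a, b))
                    elif g < 0:
                        extras[0] = _thin_spikes(
                            rng, extras[0], -g, tuning.baseline_hz, a, b
                        )
            # stay/switch action gain in the late-delay window
            if action[t] in ("stay", "switch"):
                g = tuning.action_gains_hz[action[t]] * ac_mult[i]
                a = scene_on[t] + tuning.action_window_ms[0]
                b = scene_on[t] + tuning.action_window_ms[1]
                if g > 0:
                    extras.append(_add_window_spikes(rng, g, a, b))
                elif g < 0:
                    extras[0] = _thin_spikes(
                        rng, extras[0], -g, tuning.baseline_hz, a, b
                    )
        all_spikes = np.sort(np.concatenate(extras))
        spikes.append(
            SpikeData(
                neuron_id=f"syn{i:04d}", session_id=session_id, spike_times=all_spikes
            )
        )
    return spikes


def generate_session(
    task: TaskDesignParams | None = None,
    agent: AgentParams | None = None,
    tuning: TuningSpec | None = None,
    n_neurons: int = 160,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[SpikeData]]:
    """One full synthetic session (design + behavior + spikes).

    The three stages consume independent streams spawned from ``seed`` so
    that, e.g., changing the tuning does not perturb the behavior.
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_behav, s_spk = (s.generate_state(1)[0] % (2**31) for s in ss.spawn(3))
    design = generate_block_design(task, seed=int(s_design))
    trials = simulate_behavior(design, agent, seed=int(s_behav))
    spikes = simulate_spikes(trials, tuning, n_neurons=n_neurons, seed=int(s_spk))
    return trials.drop(columns=["aux_correct_object", "aux_delay_ms", "aux_feedback_dur_ms"]), spikes
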