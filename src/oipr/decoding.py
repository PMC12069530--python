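"""Time-resolved pseudo-population decoding with shuffle-null significance.

The decoder is a linear support-vector machine (C = 1) trained per time bin
on z-scored pseudo-population activity with condition-balanced k-fold
cross-validation.  The per-bin accuracy is the average over ``n_resamples``
pseudo-population redraws.  Significance comes from a label-shuffle null:
the whole procedure is repeated ``n_shuffles`` times with permuted condition
labels, the per-(shuffle, bin) resample-averages are pooled into one null
distribution (e.g. 20 shuffles x 63 bins = 1260 values), the observed
accuracy is z-scored against it, and bins pass when their one-sided p-value
clears a Bonferroni-corrected alpha of ``0.05 / (n_bins * n_shuffles)`` in
at least ``min_consecutive`` consecutive bins.

Two further variants live here: a sliding 10-trial-window decoder that
tracks how decodability develops across the 30 trials of a block, and a
two-variable balanced-sampling decoder that removes the correlation between
two binary labelings (reward small vs medium+large, action stay vs switch)
by forcing equal counts in every cell of their cross-table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC, LinearSVC

from .core_data import BinnedActivity, TRIALS_PER_BLOCK
from .errors import EligibilityError, ParameterError
from .pseudopopulation import (
    NeuronTrials,
    assemble_sample,
    population_from_binned,
    stratified_folds,
    zscore_by_train,
)

__all__ = [
    "DecoderSpec",
    "NullModel",
    "DecodingResult",
    "SignificanceResult",
    "SlidingWindowResult",
    "BalancedDecodingResult",
    "decode_timecourse",
    "build_null",
    "assess_significance",
    "sliding_window_decode",
    "balanced_decode",
    "significance_stars",
]


@dataclass
class DecoderSpec:
    """Classifier and cross-validation settings for population decoding."""

    C: float = 1.0
    k_folds: int = 10
    n_resamples: int = 50
    n_per_condition: int = 60
    multiclass: str = "ovr"  # 'ovr' (one-vs-rest) or 'ovo' (one-vs-one)

    def validate(self) -> None:
        if self.C <= 0:
            raise ParameterError("C must be > 0")
        if self.k_folds < 2:
            raise ParameterError("k_folds must be >= 2")
        if self.multiclass not in ("ovr", "ovo"):
            raise ParameterError("multiclass must be 'ovr' or 'ovo'")

    def make_classifier(self):
        if self.multiclass == "ovr":
            return LinearSVC(C=self.C, max_iter=5000, random_state=0)
        return SVC(kernel="linear", C=self.C)


@dataclass
class NullModel:
    """Pooled label-shuffle null of resample-averaged accuracies."""

    values: np.ndarray  # flat, n_shuffles * n_bins
    n_shuffles: int
    n_bins: int

    @property
    def corrected_alpha(self) -> float:
        return 0.05 / (self.n_bins * self.n_shuffles)

    @property
    def size(self) -> int:
        return self.values.size


@dataclass
class DecodingResult:
    """Per-bin accuracy (mean over resamples) with the resample spread."""

    bin_centers: np.ndarray
    accuracies: np.ndarray  # [n_resamples, n_bins]
    conditions: list
    chance: float

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracies.mean(axis=0)

    @property
    def resample_sd(self) -> np.ndarray:
        return self.accuracies.std(axis=0, ddof=1)


@dataclass
class SignificanceResult:
    z_scores: np.ndarray
    p_normal: np.ndarray
    p_empirical: np.ndarray
    corrected_alpha: float
    mask: np.ndarray  # after the consecutive-bin rule


def _decode_sample(activity, labels, fold_ids, spec: DecoderSpec) -> np.ndarray:
    """Fold-averaged accuracy per bin for one assembled pseudo-population."""
    n_bins = activity.shape[2]
    k = fold_ids.max() + 1
    acc = np.zeros(n_bins)
    for b in range(n_bins):
        X = activity[:, :, b]
        fold_acc = np.zeros(k)
        for f in range(k):
            Xtr, Xte, train_mask, _ = zscore_by_train(X, fold_ids, f)
            ytr, yte = labels[train_mask], labels[~train_mask]
            clf = spec.make_classifier()
            clf.fit(Xtr.T, ytr)
            fold_acc[f] = np.mean(clf.predict(Xte.T) == yte)
        acc[b] = fold_acc.mean()
    return acc


def decode_timecourse(
    population: list[NeuronTrials],
    spec: DecoderSpec | None = None,
    seed: int | None = None,
    conditions: list | None = None,
    bin_centers: np.ndarray | None = None,
    permute_labels: bool = False,
) -> DecodingResult:
    """Cross-validated decoding accuracy per time bin, averaged over
    pseudo-population resamples.

    ``permute_labels`` shuffles the condition labels of every assembled
    sample (used internally to build the null model).
    """
    spec = spec or DecoderSpec()
    spec.validate()
    if not population:
        raise EligibilityError("empty population")
    if conditions is None:
        conditions = sorted(np.unique(population[0].labels).tolist())
    if len(conditions) < 2:
        raise ParameterError("need at least 2 conditions to decode")
    rng = np.random.default_rng(seed)
    n_bins = population[0].counts.shape[1]
    accs = np.zeros((spec.n_resamples, n_bins))
    for r in range(spec.n_resamples):
        sample = assemble_sample(population, spec.n_per_condition, rng, conditions)
        labels = sample.labels.copy()
        if permute_labels:
            labels = rng.permutation(labels)
        fold_ids = stratified_folds(labels, spec.k_folds, rng)
        accs[r] = _decode_sample(sample.activity, labels, fold_ids, spec)
    if bin_centers is None:
        bin_centers = np.arange(n_bins, dtype=float)
    return DecodingResult(
        bin_centers=np.asarray(bin_centers),
        accuracies=accs,
        conditions=list(conditions),
        chance=1.0 / len(conditions),
    )


def build_null(
    population: list[NeuronTrials],
    spec: DecoderSpec | None = None,
    n_shuffles: int = 20,
    seed: int | None = None,
    conditions: list | None = None,
    n_resamples: int | None = None,
) -> NullModel:
    """Label-shuffle null: the full decoding procedure repeated with permuted
    labels; the per-bin resample averages of all shuffles are pooled into one
    distribution of ``n_shuffles * n_bins`` values.

    ``n_resamples`` optionally overrides the spec's resample count for the
    null (the observed statistic is itself a resample average, so a smaller
    per-shuffle resample count only widens the null)."""
    if n_shuffles < 2:
        raise ParameterError("n_shuffles must be >= 2")
    spec = spec or DecoderSpec()
    if n_resamples is not None:
        spec = DecoderSpec(
            C=spec.C, k_folds=spec.k_folds, n_resamples=n_resamples,
            n_per_condition=spec.n_per_condition, multiclass=spec.multiclass,
        )
    ss = np.random.SeedSequence(seed)
    vals = []
    n_bins = population[0].counts.shape[1]
    for child in ss.spawn(n_shuffles):
        res = decode_timecourse(
            population, spec, seed=int(child.generate_state(1)[0] % 2**31),
            conditions=conditions, permute_labels=True,
        )
        vals.append(res.mean_accuracy)
    return NullModel(
        values=np.concatenate(vals), n_shuffles=n_shuffles, n_bins=n_bins
    )


def _consecutive_mask(passing: np.ndarray, min_consecutive: int) -> np.ndarray:
    """Keep only runs of at least ``min_consecutive`` consecutive True bins."""
    mask = np.zeros_like(passing, dtype=bool)
    run = 0
    for i, ok in enumerate(list(passing) + [False]):
        if ok:
            run += 1
        else:
            if run >= min_consecutive:
                mask[i - run : i] = True
            run = 0
    return mask


def assess_significance(
    result: DecodingResult,
    null: NullModel,
    min_consecutive: int = 5,
    p_method: str = "normal",
) -> SignificanceResult:
    """Per-bin significance of observed accuracy against the pooled null.

    Each observed bin accuracy is z-scored against the null distribution.
    Two one-sided p-values are reported: ``p_normal``, the upper normal tail
    of the z-score, and ``p_empirical``, the exceedance proportion
    ``(1 + #{null >= observed}) / (1 + N_null)``.  Significance uses
    ``p_method`` (default the normal tail, since the Bonferroni-corrected
    alpha ``0.05 / (n_bins * n_shuffles)`` lies below the resolution
    ``1 / (1 + N_null)`` of the empirical p-value) and keeps only runs of at
    least ``min_consecutive`` passing bins.
    """
    if null.values.size == 0:
        raise ParameterError("empty null distribution")
    obs = result.mean_accuracy
    mu, sd = null.values.mean(), null.values.std(ddof=1)
    z = (obs - mu) / (sd if sd > 0 else np.inf)
    p_norm = sps.norm.sf(z)
    p_emp = (1.0 + (null.values[None, :] >= obs[:, None]).sum(axis=1)) / (
        1.0 + null.size
    )
    p = p_norm if p_method == "normal" else p_emp
    passing = p <= null.corrected_alpha
    return SignificanceResult(
        z_scores=z,
        p_normal=p_norm,
        p_empirical=p_emp,
        corrected_alpha=null.corrected_alpha,
        mask=_consecutive_mask(passing, min_consecutive),
    )


# --------------------------------------------------------------------------
# sliding trial-window decoding (within-block learning)
# --------------------------------------------------------------------------

@dataclass
class SlidingWindowResult:
    """Accuracy and significance per (trial window, time bin)."""

    window_starts: np.ndarray  # first trial index (1-based) of each window
    bin_centers: np.ndarray
    accuracy: np.ndarray  # [n_windows, n_bins]
    significant: np.ndarray  # [n_windows, n_bins] bool
    chance: float
    n_neurons: int


def sliding_window_decode(
    binned: BinnedActivity,
    trials: pd.DataFrame,
    labels: np.ndarray,
    spec: DecoderSpec | None = None,
    window: int = 10,
    step: int = 1,
    min_trials_per_condition: int = 20,
    n_shuffles: int = 20,
    null_resamples: int | None = None,
    min_consecutive: int = 5,
    seed: int | None = None,
) -> SlidingWindowResult:
    """Decode within a sliding window of within-block trial positions.

    Window ``w`` pools trials with ``trial_index_in_block`` in
    ``[w, w + window - 1]`` across blocks (30-trial blocks give 21 windows of
    10 trials).  Neurons must retain ``min_trials_per_condition`` trials per
    condition in *every* window; decoding and the shuffle null then run per
    window exactly as in :func:`decode_timecourse`, with the per-window
    Bonferroni alpha ``0.05 / (n_bins * n_shuffles)`` and the
    consecutive-bin rule applied along the time axis of each window.
    """
    spec = spec or DecoderSpec(n_per_condition=min_trials_per_condition)
    labels = np.asarray(labels)
    tidx = trials["trial_index_in_block"].to_numpy()
    if tidx.max() != TRIALS_PER_BLOCK:
        raise ParameterError("sliding-window decoding expects complete 30-trial blocks")
    starts = np.arange(1, TRIALS_PER_BLOCK - window + 2, step)
    conditions = sorted(np.unique(labels).tolist())

    # eligibility: every window must keep >= min trials per condition
    window_masks = [(tidx >= w) & (tidx <= w + window - 1) for w in starts]
    for w, m in zip(starts, window_masks):
        cnt = {c: int(np.sum(labels[m] == c)) for c in conditions}
        if min(cnt.values()) < min_trials_per_condition:
            raise EligibilityError(
                f"window starting at trial {w}: per-condition counts {cnt} "
                f"below {min_trials_per_condition}"
            )

    ss = np.random.SeedSequence(seed)
    acc = np.zeros((len(starts), binned.n_bins))
    sig = np.zeros((len(starts), binned.n_bins), dtype=bool)
    for wi, (m, child) in enumerate(zip(window_masks, ss.spawn(len(starts)))):
        sub = BinnedActivity(
            counts=binned.counts[:, m, :],
            bin_centers=binned.bin_centers,
            bin_width=binned.bin_width,
            bin_step=binned.bin_step,
            alignment_event=binned.alignment_event,
            span=binned.span,
            neuron_ids=binned.neuron_ids,
        )
        pop = population_from_binned(sub, labels[m])
        s_obs, s_null = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2))
        res = decode_timecourse(
            pop, spec, seed=s_obs, conditions=conditions,
            bin_centers=binned.bin_centers,
        )
        null = build_null(
            pop, spec, n_shuffles=n_shuffles, seed=s_null,
            conditions=conditions, n_resamples=null_resamples,
        )
        acc[wi] = res.mean_accuracy
        sig[wi] = assess_significance(res, null, min_consecutive=min_consecutive).mask
    return SlidingWindowResult(
        window_starts=starts,
        bin_centers=binned.bin_centers,
        accuracy=acc,
        significant=sig,
        chance=1.0 / len(conditions),
        n_neurons=binned.n_neurons,
    )


# --------------------------------------------------------------------------
# two-variable balanced decoding (decorrelation)
# --------------------------------------------------------------------------

@dataclass
class BalancedDecodingResult:
    accuracy_a: float
    accuracy_b: float
    null_a: np.ndarray
    null_b: np.ndarray
    p_a: float
    p_b: float
    n_neurons: int
    n_per_cell: int
    chance: float = 0.5


def significance_stars(p: float) -> str:
    """Encode a p-value as the conventional star string."""
    for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p <= thr:
            return s
    return "ns"


def _balanced_accuracy(
    cells: list[np.ndarray],  # per neuron: [4 cells, n_per_cell] counts
    var_labels: np.ndarray,  # label per cell (length 4), for the decoded variable
    n_per_cell: int,
    split: float,
    n_splits: int,
    C: float,
    rng: np.random.Generator,
    permute: bool = False,
) -> float:
    X = np.stack(cells)  # [n_neurons, 4, n_per_cell]
    n_neurons = X.shape[0]
    cols = X.reshape(n_neurons, 4 * n_per_cell)
    col_labels = np.repeat(var_labels, n_per_cell)
    if permute:
        col_labels = rng.permutation(col_labels)
    n_train = int(round(split * n_per_cell))
    if not 0 < n_train < n_per_cell:
        raise ParameterError("split leaves an empty train or test set")
    accs = []
    for _ in range(n_splits):
        train = np.zeros(4 * n_per_cell, dtype=bool)
        for c in range(4):  # per-cell split keeps both variables balanced
            pick = rng.choice(n_per_cell, size=n_train, replace=False)
            train[c * n_per_cell + pick] = True
        mu = cols[:, train].mean(axis=1, keepdims=True)
        sd = cols[:, train].std(axis=1, keepdims=True)
        Z = (cols - mu) / np.where(sd > 0, sd, np.inf)
        clf = LinearSVC(C=C, max_iter=5000, random_state=0)
        clf.fit(Z[:, train].T, col_labels[train])
        accs.append(np.mean(clf.predict(Z[:, ~train].T) == col_labels[~train]))
    return float(np.mean(accs))


def balanced_decode(
    counts: np.ndarray | list[np.ndarray],
    labels_a: np.ndarray | list[np.ndarray],
    labels_b: np.ndarray | list[np.ndarray],
    split: float = 0.7,
    n_splits: int = 10,
    min_per_cell: int = 10,
    n_shuffles: int = 25,
    n_resamples: int = 10,
    C: float = 1.0,
    seed: int | None = None,
) -> BalancedDecodingResult:
    """Decode two correlated binary variables after balanced sampling.

    ``counts`` holds one scalar activity value per trial per neuron (a 2-D
    array ``[n_neurons, n_trials]`` for shared trials, or one 1-D array per
    neuron with matching per-neuron label arrays).  For every neuron the same
    number of trials is drawn from each cell of the A x B cross-table, so
    within each class of either variable the other variable is exactly
    balanced — the correlation between the labels cannot carry information.
    Each variable is then decoded with ``n_splits`` stratified 70/30
    train/test splits per resample; significance is the exceedance p against
    ``n_shuffles`` label permutations, ``p = (1 + #{null >= obs}) /
    (1 + n_shuffles)``.
    """
    if isinstance(counts, np.ndarray) and counts.ndim == 2:
        neurons = [(counts[i], np.asarray(labels_a), np.asarray(labels_b))
                   for i in range(counts.shape[0])]
    else:
        neurons = [(np.asarray(c), np.asarray(a), np.asarray(b))
                   for c, a, b in zip(counts, labels_a, labels_b)]
    a_levels = sorted(np.unique(np.concatenate([n[1] for n in neurons])).tolist())
    b_levels = sorted(np.unique(np.concatenate([n[2] for n in neurons])).tolist())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ParameterError("both variables must be binary")
    cells_def = [(a, b) for a in a_levels for b in b_levels]

    # eligibility: >= min_per_cell trials in every (A, B) cell
    eligible = []
    for c, a, b in neurons:
        cnt = [int(np.sum((a == ca) & (b == cb))) for ca, cb in cells_def]
        if min(cnt) >= min_per_cell:
            eligible.append((c, a, b, cnt))
    if not eligible:
        raise EligibilityError(
            f"no neuron has {min_per_cell} trials in every label cell"
        )
    n_per_cell = min(min(e[3]) for e in eligible)

    rng = np.random.default_rng(seed)
    lab_a = np.array([ca for ca, _ in cells_def])
    lab_b = np.array([cb for _, cb in cells_def])

    def sample_cells(r: np.random.Generator) -> list[np.ndarray]:
        out = []
        for c, a, b, _ in eligible:
            mat = np.empty((4, n_per_cell))
            for ci, (ca, cb) in enumerate(cells_def):
                idx = np.flatnonzero((a == ca) & (b == cb))
                mat[ci] = c[r.choice(idx, size=n_per_cell, replace=False)]
            out.append(mat)
        return out

    obs_a, obs_b = [], []
    for _ in range(n_resamples):
        cells = sample_cells(rng)
        obs_a.append(_balanced_accuracy(cells, lab_a, n_per_cell, split, n_splits, C, rng))
        obs_b.append(_balanced_accuracy(cells, lab_b, n_per_cell, split, n_splits, C, rng))
    acc_a, acc_b = float(np.mean(obs_a)), float(np.mean(obs_b))

    null_a, null_b = [], []
    for _ in range(n_shuffles):
        cells = sample_cells(rng)
        null_a.append(
            _balanced_accuracy(cells, lab_a, n_per_cell, split, n_splits, C, rng, True)
        )
        null_b.append(
            _balanced_accuracy(cells, lab_b, n_per_cell, split, n_splits, C, rng, True)
        )
    null_a, null_b = np.array(null_a), np.array(null_b)
    p_a = float((1 + np.sum(null_a >= acc_a)) / (1 + n_shuffles))
    p_b = float((1 + np.sum(null_b >= acc_b)) / (1 + n_shuffles))
    return BalancedDecodingResult(
        accuracy_a=acc_a, accuracy_b=acc_b, null_a=null_a, null_b=null_b,
        p_a=p_a, p_b=p_b, n_neurons=len(eligible), n_per_cell=n_per_cell,
    )
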