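"""Pseudo-population assembly with leakage-free normalization.

Neurons recorded in different sessions never share trials, so population
analyses operate on *pseudo-populations*: for every neuron, the same number
of trials per condition is drawn independently (without replacement) and the
draws are stacked column-wise as if they had been simultaneous.  Each
resample redraws the trials, producing a new pseudo-population.

Cross-validation folds are stratified by condition label so every fold
carries equal label counts, and z-scoring statistics are always computed
from training columns only (optionally from a subset of conditions, as the
projection-geometry analysis requires).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import BinnedActivity
from .errors import EligibilityError, ParameterError

__all__ = [
    "NeuronTrials",
    "PseudoPopulationSample",
    "population_from_binned",
    "select_eligible_neurons",
    "assemble_sample",
    "stratified_folds",
    "zscore_by_train",
]


@dataclass
class NeuronTrials:
    """All trials of one neuron: counts ``[n_trials, n_bins]`` plus one
    condition label per trial. The unit from which pseudo-populations draw."""

    neuron_id: str
    counts: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.counts.shape[0]:
            raise ParameterError(
                f"{self.neuron_id}: {self.counts.shape[0]} trials but "
                f"{len(self.labels)} labels"
            )


@dataclass
class PseudoPopulationSample:
    """One resample: ``activity[neuron, column, bin]`` with a condition label
    per column and ``n_per_condition`` columns per label."""

    activity: np.ndarray
    labels: np.ndarray  # [n_columns]
    neuron_ids: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_columns(self) -> int:
        return self.activity.shape[1]

    @property
    def n_bins(self) -> int:
        return self.activity.shape[2]


def population_from_binned(
    binned: BinnedActivity, labels: np.ndarray | list
) -> list[NeuronTrials]:
    """Split a simultaneous recording into per-neuron trial sets (after which
    neurons are treated as if they came from different sessions)."""
    labels = np.asarray(labels)
    if len(labels) != binned.n_trials:
        raise ParameterError("one label per trial required")
    ids = binned.neuron_ids or [f"n{i}" for i in range(binned.n_neurons)]
    return [
        NeuronTrials(ids[i], binned.counts[i], labels) for i in range(binned.n_neurons)
    ]


def select_eligible_neurons(
    population: list[NeuronTrials],
    min_trials_per_condition: int,
    conditions: list | None = None,
) -> list[NeuronTrials]:
    """Neurons with at least ``min_trials_per_condition`` trials for every
    condition (all labels seen across the population unless given)."""
    if conditions is None:
        conditions = sorted({l for nt in population for l in np.unique(nt.labels)})
    keep = []
    for nt in population:
        counts = {c: int(np.sum(nt.labels == c)) for c in conditions}
        if all(v >= min_trials_per_condition for v in counts.values()):
            keep.append(nt)
    return keep


def assemble_sample(
    population: list[NeuronTrials],
    n_per_condition: int,
    rng: np.random.Generator,
    conditions: list | None = None,
) -> PseudoPopulationSample:
    """Draw one pseudo-population: for each neuron and condition,
    ``n_per_condition`` trials uniformly without replacement, independently
    across neurons. Columns are grouped by condition."""
    if not population:
        raise EligibilityError("empty population")
    if conditions is None:
        conditions = sorted(np.unique(population[0].labels).tolist())
    n_bins = population[0].counts.shape[1]
    n_cols = n_per_condition * len(conditions)
    activity = np.empty((len(population), n_cols, n_bins), dtype=float)
    labels = np.repeat(conditions, n_per_condition)
    for i, nt in enumerate(population):
        col = 0
        for c in conditions:
            idx = np.flatnonzero(nt.labels == c)
            if len(idx) < n_per_condition:
                raise EligibilityError(
                    f"neuron {nt.neuron_id}: {len(idx)} trials for condition "
                    f"{c!r}, need {n_per_condition}"
                )
            take = rng.choice(idx, size=n_per_condition, replace=False)
            activity[i, col : col + n_per_condition] = nt.counts[take]
            col += n_per_condition
    return PseudoPopulationSample(
        activity=activity, labels=labels, neuron_ids=[nt.neuron_id for nt in population]
    )


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per column, stratified so every label is spread evenly over
    the k folds (fold sizes within a label differ by at most 1)."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    labels = np.asarray(labels)
    folds = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ParameterError(f"condition {c!r} has fewer trials than folds")
        assign = np.resize(np.arange(k), len(idx))
        rng.shuffle(idx)
        folds[idx] = assign
    return folds


def zscore_by_train(
    X: np.ndarray,
    fold_ids: np.ndarray,
    fold: int,
    labels: np.ndarray | None = None,
    stat_labels: list | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron z-scoring of one bin's matrix ``X [n_neurons, n_columns]``
    using training-column statistics only.

    Returns ``(X_train_z, X_test_z, train_mask, mu)`` where the test split is
    fold ``fold``.  With ``stat_labels`` the mean/sd come only from training
    columns of those conditions (the geometry analysis normalizes with
    small+large training statistics); otherwise from all training columns.
    Neurons with zero training variance are mapped to 0 rather than dropped,
    keeping the population size fixed.
    """
    train = fold_ids != fold
    stat_cols = train.copy()
    if stat_labels is not None:
        if labels is None:
            raise ParameterError("stat_labels requires labels")
        stat_cols &= np.isin(labels, stat_labels)
    mu = X[:, stat_cols].mean(axis=1, keepdims=True)
    sd = X[:, stat_cols].std(axis=1, keepdims=True)
    safe = np.where(sd > 0, sd, np.inf)  # constant neuron -> all zeros
    Xz = (X - mu) / safe
    return Xz[:, train], Xz[:, ~train], train, mu.ravel()
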