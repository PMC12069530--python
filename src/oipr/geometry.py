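"""State-space geometry: projections onto the small-large reward
discriminant and the overlap-index significance criterion.

The coding direction is the difference between the mean (z-scored)
population activity of the large- and small-reward training trials.  Test
activity of *all three* reward conditions is projected onto this direction;
whether the medium condition clusters with the large one (as in the delay
epoch) or sits between small and large (as at feedback) is read off the
per-condition projection distributions collected over pseudo-population
resamples.  Two conditions count as different in a bin when the overlap
index — the shared area of the two kernel-density estimates — is below 5%,
sustained over at least five consecutive bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import gaussian_kde

from .errors import EligibilityError, ParameterError
from .pseudopopulation import NeuronTrials, assemble_sample

__all__ = [
    "ProjectionResult",
    "compute_discriminant",
    "project_conditions",
    "overlap_index",
    "run_projection_analysis",
]


@dataclass
class ProjectionResult:
    """Projection distributions per (bin, condition) and pairwise overlaps."""

    bin_centers: np.ndarray
    conditions: list
    projections: np.ndarray  # [n_resamples, n_bins, n_conditions]
    overlap: dict  # (cond_a, cond_b) -> [n_bins]
    different: dict  # (cond_a, cond_b) -> bool mask [n_bins], consec. rule
    overlap_threshold: float = 0.05


def compute_discriminant(
    train_means: np.ndarray, conditions: list, low: str = "small", high: str = "large"
) -> np.ndarray:
    """Coding direction: mean(high) - mean(low) per neuron, unnormalized.

    ``train_means`` is ``[n_neurons, n_conditions]`` of per-condition mean
    training activity (z-scored upstream)."""
    train_means = np.asarray(train_means)
    for c in (low, high):
        if c not in conditions:
            raise ParameterError(f"condition {c!r} missing from {conditions}")
    return train_means[:, conditions.index(high)] - train_means[:, conditions.index(low)]


def project_conditions(direction: np.ndarray, test_matrix: np.ndarray) -> np.ndarray:
    """Dot product of the discriminant with each condition's test population
    vector (``test_matrix`` is ``[n_neurons, n_conditions]``)."""
    direction = np.asarray(direction)
    test_matrix = np.asarray(test_matrix)
    if test_matrix.shape[0] != direction.shape[0]:
        raise ParameterError(
            f"dimension mismatch: direction {direction.shape[0]} vs "
            f"test matrix {test_matrix.shape[0]} neurons"
        )
    return direction @ test_matrix


def overlap_index(
    samples_a: np.ndarray, samples_b: np.ndarray, grid_points: int = 512
) -> float:
    """Shared area of two kernel-density estimates, in [0, 1].

    Gaussian kernels with Silverman bandwidth on one grid spanning both
    samples (3 bandwidths of margin).  Zero-variance samples degenerate to
    point masses: overlap 1 if the two points coincide, else 0.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ParameterError("need at least 10 samples per distribution")
    sd_a, sd_b = a.std(), b.std()
    if sd_a == 0 or sd_b == 0:
        warnings.warn("zero-variance sample; point-mass overlap rule applied")
        if sd_a == 0 and sd_b == 0:
            return 1.0 if a[0] == b[0] else 0.0
        return 0.0
    kde_a = gaussian_kde(a, bw_method="silverman")
    kde_b = gaussian_kde(b, bw_method="silverman")
    bw = max(np.sqrt(kde_a.covariance[0, 0]), np.sqrt(kde_b.covariance[0, 0]))
    lo = min(a.min(), b.min()) - 3 * bw
    hi = max(a.max(), b.max()) + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    return float(np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid))


def _loo_projections(activity: np.ndarray, conditions: list) -> np.ndarray:
    """Leave-one-out cross-validated projections for one (resample, bin).

    ``activity`` is ``[n_neurons, n_conditions, m]`` with m trials per
    condition; fold i holds out trial i of every condition.  Training means,
    the small+large normalization statistics, the discriminant and the test
    projections are computed for all m folds at once, then averaged.
    Returns one projection per condition.
    """
    n, c, m = activity.shape
    i_small, i_large = conditions.index("small"), conditions.index("large")
    S = activity.sum(axis=2)  # [n, c]
    # per-fold training means: (S - x_i) / (m - 1)  -> [n, c, m]
    train_means = (S[:, :, None] - activity) / (m - 1)
    # z-stats from small+large training columns of each fold
    sl = activity[:, (i_small, i_large), :]  # [n, 2, m]
    tot = sl.sum(axis=(1, 2))  # [n]
    tot2 = (sl**2).sum(axis=(1, 2))
    n_tr = 2 * (m - 1)
    mu = (tot[:, None] - sl[:, 0, :] - sl[:, 1, :]) / n_tr  # [n, m]
    ex2 = (tot2[:, None] - sl[:, 0, :] ** 2 - sl[:, 1, :] ** 2) / n_tr
    var = np.maximum(ex2 - mu**2, 0.0)
    sd = np.sqrt(var)
    safe = np.where(sd > 0, sd, np.inf)
    # discriminant per fold: (mean_large - mean_small) / sd   [n, m]
    direction = (train_means[:, i_large, :] - train_means[:, i_small, :]) / safe
    # z-scored test vectors per condition/fold, projected
    proj = np.empty((c, m))
    for ci in range(c):
        z_test = (activity[:, ci, :] - mu) / safe
        proj[ci] = (direction * z_test).sum(axis=0)
    return proj.mean(axis=1)


def run_projection_analysis(
    population: list[NeuronTrials],
    n_per_condition: int = 60,
    n_resamples: int = 100,
    seed: int | None = None,
    conditions: list | None = None,
    bin_centers: np.ndarray | None = None,
    overlap_threshold: float = 0.05,
    min_consecutive: int = 5,
) -> ProjectionResult:
    """Cross-validated discriminant projections of all conditions per bin.

    Per resample and bin: sample ``n_per_condition`` trials per condition per
    neuron, run leave-one-out folds in which the held-out trial of each
    condition is projected onto the small-large discriminant built (and
    z-scored) from the remaining training trials, and average over folds.
    Over ``n_resamples`` redraws this yields a projection distribution per
    condition; condition pairs whose kernel-density overlap stays below
    ``overlap_threshold`` for at least ``min_consecutive`` consecutive bins
    are flagged as different.
    """
    from .decoding import _consecutive_mask  # shared run-length rule

    if not population:
        raise EligibilityError("empty population")
    if conditions is None:
        conditions = sorted(np.unique(population[0].labels).tolist())
    for c in ("small", "large"):
        if c not in conditions:
            raise ParameterError(f"projection analysis needs condition {c!r}")
    rng = np.random.default_rng(seed)
    n_bins = population[0].counts.shape[1]
    n_cond = len(conditions)
    projections = np.empty((n_resamples, n_bins, n_cond))
    for r in range(n_resamples):
        sample = assemble_sample(population, n_per_condition, rng, conditions)
        # columns are grouped by condition: reshape to [n, c, m]
        act = sample.activity.reshape(
            sample.n_neurons, n_cond, n_per_condition, n_bins
        )
        for b in range(n_bins):
            projections[r, b] = _loo_projections(act[:, :, :, b], conditions)

    overlap: dict = {}
    different: dict = {}
    for ca, cb in combinations(conditions, 2):
        ia, ib = conditions.index(ca), conditions.index(cb)
        ov = np.array(
            [overlap_index(projections[:, b, ia], projections[:, b, ib])
             for b in range(n_bins)]
        )
        overlap[(ca, cb)] = ov
        different[(ca, cb)] = _consecutive_mask(ov < overlap_threshold, min_consecutive)
    if bin_centers is None:
        bin_centers = np.arange(n_bins, dtype=float)
    return ProjectionResult(
        bin_centers=np.asarray(bin_centers),
        conditions=list(conditions),
        projections=projections,
        overlap=overlap,
        different=different,
        overlap_threshold=overlap_threshold,
    )
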