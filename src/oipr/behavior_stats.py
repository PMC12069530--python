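"""Behavioral statistics: learning curves, switch rates, reaction times.

All functions take a trial table (see :mod:`oipr.core_data`) and return tidy
results.  The tests used mirror standard practice for this kind of choice
behavior: one-sided exact binomial tests of per-run accuracy against the 0.5
chance level, chi-square tests (2x2, no continuity correction by default)
between proportions, and two-sample Kolmogorov-Smirnov tests between
reaction-time distributions.  A per-day aggregation variant evaluates any
statistic separately per session and averages the per-session values
unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import N_RUNS, REWARD_SIZES
from .errors import ParameterError

__all__ = [
    "ProportionResult",
    "performance_by_run_and_size",
    "compare_proportions",
    "switch_proportions",
    "compare_reaction_times",
    "aggregate_by_day",
    "behavior_report",
]


@dataclass
class ProportionResult:
    """A success proportion in one stratum, with its test against chance."""

    run_index: int | None
    reward_size: str
    outcome_filter: str  # 'all' | 'after_correct' | 'after_incorrect'
    k: int
    n: int
    p_value: float  # NaN when the stratum is empty
    test: str

    @property
    def proportion(self) -> float:
        return self.k / self.n if self.n else float("nan")


def performance_by_run_and_size(
    trials: pd.DataFrame, chance: float = 0.5
) -> list[ProportionResult]:
    """Proportion correct per (run, reward size), one-sided exact binomial
    test against ``chance``. Empty strata are returned with ``n=0`` and an
    undefined p-value."""
    out = []
    for run in range(1, N_RUNS + 1):
        for size in REWARD_SIZES:
            grp = trials[(trials.run_index == run) & (trials.reward_size == size)]
            k, n = int(grp["correct"].sum()), len(grp)
            if n == 0:
                p = float("nan")
            else:
                p = stats.binomtest(k, n, chance, alternative="greater").pvalue
            out.append(
                ProportionResult(run, size, "all", k, n, p, "binomial_one_sided")
            )
    return out


def compare_proportions(
    table_a: tuple[int, int],
    table_b: tuple[int, int],
    yates: bool = False,
) -> tuple[float, float]:
    """Chi-square test between two success proportions ``(k, n)``.

    Returns ``(statistic, p)``; no continuity correction unless ``yates``.
    A zero expected cell yields ``(0, 1)`` with a warning rather than NaN.
    """
    (ka, na), (kb, nb) = table_a, table_b
    if na <= 0 or nb <= 0:
        raise ParameterError("both groups need n > 0")
    obs = np.array([[ka, na - ka], [kb, nb - kb]], dtype=float)
    if (obs.sum(axis=0) == 0).any():
        warnings.warn("zero expected cell in 2x2 table; statistic set to 0")
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(obs, correction=yates)
    return float(stat), float(p)


def _previous_outcome(trials: pd.DataFrame) -> pd.Series:
    """Correctness of the same scene's trial in the previous run (aligned to
    the input index; NaN for run-1 rows)."""
    key = ["session_id", "block_index", "scene_index"]
    prev = trials.sort_values(key + ["run_index"]).groupby(key)["correct"].shift(1)
    return prev.reindex(trials.index)


def switch_proportions(
    trials: pd.DataFrame, outcome_filter: str = "all"
) -> tuple[list[ProportionResult], pd.DataFrame]:
    """Switch-trial proportions per (run 2-6, reward size) plus the pairwise
    chi-square comparisons between sizes within each run.

    A switch trial is a scene in which the chosen object differs from the
    choice made for the same scene in the previous run; ``outcome_filter``
    conditions on whether that previous choice was correct.
    """
    if outcome_filter not in ("all", "after_correct", "after_incorrect"):
        raise ParameterError(f"unknown outcome filter {outcome_filter!r}")
    sub = trials[trials.stay_switch.isin(["stay", "switch"])].copy()
    if outcome_filter != "all":
        prev = _previous_outcome(trials).loc[sub.index]
        sub = sub[prev == (outcome_filter == "after_correct")]

    results = []
    for run in range(2, N_RUNS + 1):
        for size in REWARD_SIZES:
            grp = sub[(sub.run_index == run) & (sub.reward_size == size)]
            k = int((grp.stay_switch == "switch").sum())
            n = len(grp)
            results.append(
                ProportionResult(run, size, outcome_filter, k, n, float("nan"), "none")
            )
    by_stratum = {(r.run_index, r.reward_size): r for r in results}
    rows = []
    for run in range(2, N_RUNS + 1):
        for sa, sb in combinations(REWARD_SIZES, 2):
            a, b = by_stratum[(run, sa)], by_stratum[(run, sb)]
            if a.n == 0 or b.n == 0:
                stat, p = float("nan"), float("nan")
            else:
                stat, p = compare_proportions((a.k, a.n), (b.k, b.n))
            rows.append(
                {"run_index": run, "size_a": sa, "size_b": sb,
                 "chi2": stat, "p_value": p}
            )
    return results, pd.DataFrame(rows)


def compare_reaction_times(
    trials: pd.DataFrame, grouping: str = "reward_size", exact_below: int = 50
) -> pd.DataFrame:
    """Pairwise two-sided two-sample Kolmogorov-Smirnov tests between
    reaction-time distributions across the levels of ``grouping``.

    Asymptotic p-values; exact when both samples are smaller than
    ``exact_below``.  Groups with fewer than 2 observations are skipped with
    a warning.
    """
    groups = {
        lvl: grp["reaction_time"].to_numpy()
        for lvl, grp in trials.groupby(grouping, observed=True)
    }
    rows = []
    for (la, xa), (lb, xb) in combinations(groups.items(), 2):
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"group {la if len(xa) < 2 else lb} has < 2 RTs; skipped")
            continue
        method = "exact" if max(len(xa), len(xb)) < exact_below else "asymp"
        res = stats.ks_2samp(xa, xb, alternative="two-sided", method=method)
        rows.append(
            {"group_a": la, "group_b": lb, "n_a": len(xa), "n_b": len(xb),
             "ks_statistic": float(res.statistic), "p_value": float(res.pvalue)}
        )
    return pd.DataFrame(rows)


def aggregate_by_day(
    trials: pd.DataFrame, statistic: Callable[[pd.DataFrame], float]
) -> tuple[pd.Series, float]:
    """Evaluate ``statistic`` separately per recording session and return the
    per-day values and their unweighted mean (the per-day averaging control
    for pooled proportions)."""
    per_day = trials.groupby("session_id").apply(statistic, include_groups=False)
    return per_day, float(per_day.mean())


def behavior_report(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy one-table summary of the behavioral statistics: per-(run, size)
    accuracy with its binomial test, and switch proportions under each
    outcome filter. A ``stars`` column encodes significance."""

    def stars(p: float) -> str:
        if not np.isfinite(p):
            return ""
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if p <= thr:
                return s
        return "ns"

    rows = []
    for r in performance_by_run_and_size(trials):
        rows.append(
            {"measure": "p_correct", "outcome_filter": "all",
             "run_index": r.run_index, "reward_size": r.reward_size, "k": r.k,
             "n": r.n, "proportion": r.proportion, "p_value": r.p_value,
             "test": r.test, "stars": stars(r.p_value)}
        )
    for filt in ("all", "after_correct", "after_incorrect"):
        props, _ = switch_proportions(trials, outcome_filter=filt)
        for r in props:
            rows.append(
                {"measure": "p_switch", "outcome_filter": filt,
                 "run_index": r.run_index, "reward_size": r.reward_size, "k": r.k,
                 "n": r.n, "proportion": r.proportion, "p_value": r.p_value,
                 "test": r.test, "stars": stars(r.p_value)}
            )
    return pd.DataFrame(rows)
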