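"""Per-neuron confound controls.

Two single-neuron analyses guard the population results against trivial
explanations:

* **variance partitioning** — an ordinary-least-squares model of the
  epoch firing rate on the reaction-movement time (go-signal to target
  touch, a continuous motor covariate), the categorical reward size and
  their interaction.  An ANOVA on the fitted model converts each term's sum
  of squares into percent of total variance, so motor and reward
  contributions can be compared neuron by neuron;
* **feedback-property selectivity** — a one-way ANOVA of feedback-window
  rates across levels of a visual property of the feedback stimulus (shape
  or color), run separately in correct and incorrect trials; the fraction of
  selective neurons should sit at the nominal false-positive rate if the
  population is property-blind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ParameterError

__all__ = ["VariancePartition", "variance_partition", "feedback_property_anova"]


@dataclass
class VariancePartition:
    """Percent of a neuron's rate variance attributed to each regressor."""

    neuron_id: str
    epoch: str
    n_trials: int
    full_model_p: float
    full_model_significant: bool
    pct_rt_movement: float
    pct_reward_size: float
    pct_interaction: float
    p_rt_movement: float
    p_reward_size: float
    p_interaction: float
    rank_deficient: bool = False


def variance_partition(
    rates: np.ndarray,
    rt_movement: np.ndarray,
    reward_size: np.ndarray,
    neuron_id: str = "",
    epoch: str = "",
    alpha: float = 0.05,
    ss_type: int = 1,
) -> VariancePartition:
    """OLS fit of ``rate ~ rt_movement * reward_size`` with an ANOVA-based
    variance partition.

    Sequential (Type I) sums of squares by default, with the motor covariate
    entered first so reward size is only credited variance it explains beyond
    the motor term; Type II available via ``ss_type``.  Percentages are sums
    of squares over the total sum of squares.  The full-vs-null comparison is
    the model F-test.
    """
    rates = np.asarray(rates, dtype=float)
    rt_movement = np.asarray(rt_movement, dtype=float)
    reward_size = np.asarray(reward_size)
    if not len(rates) == len(rt_movement) == len(reward_size):
        raise ParameterError("rates, rt_movement, reward_size must align")
    if len(rates) < 10:
        raise ParameterError("need at least 10 trials")
    if len(np.unique(reward_size)) < 3:
        raise ParameterError("all three reward sizes must be present")

    df = pd.DataFrame(
        {"rate": rates, "rt_mov": rt_movement, "size": reward_size}
    )
    model = smf.ols("rate ~ rt_mov * C(size)", data=df).fit()
    ss_total = float(np.sum((rates - rates.mean()) ** 2))
    if ss_total == 0 or model.df_resid <= 0:
        return VariancePartition(
            neuron_id, epoch, len(rates), float("nan"), False,
            float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), float("nan"), rank_deficient=True,
        )
    if ss_type == 1:
        # sequential SS with the motor covariate entered first (formula-level
        # term ordering always puts the categorical first, so nest explicitly)
        nested = [
            smf.ols(f, data=df).fit().ssr
            for f in ("rate ~ 1", "rate ~ rt_mov", "rate ~ rt_mov + C(size)")
        ] + [model.ssr]
        ss_terms = -np.diff(nested)  # rt_mov, C(size), interaction
        df_terms = np.array([1.0, 2.0, 2.0])
        ms_resid = model.ssr / model.df_resid
        f_stats = (ss_terms / df_terms) / ms_resid
        p_terms = stats.f.sf(f_stats, df_terms, model.df_resid)
        (pct_rt, pct_size, pct_int) = 100.0 * ss_terms / ss_total
        p_rt, p_size, p_int = (float(p) for p in p_terms)
    else:
        table = sm.stats.anova_lm(model, typ=ss_type)

        def row(name: str) -> tuple[float, float]:
            ss = float(table.loc[name, "sum_sq"])
            p = float(table.loc[name, "PR(>F)"])
            return 100.0 * ss / ss_total, p

        pct_rt, p_rt = row("rt_mov")
        pct_size, p_size = row("C(size)")
        pct_int, p_int = row("rt_mov:C(size)")
    full_p = float(model.f_pvalue)
    return VariancePartition(
        neuron_id=neuron_id,
        epoch=epoch,
        n_trials=len(rates),
        full_model_p=full_p,
        full_model_significant=bool(full_p < alpha),
        pct_rt_movement=pct_rt,
        pct_reward_size=pct_size,
        pct_interaction=pct_int,
        p_rt_movement=p_rt,
        p_reward_size=p_size,
        p_interaction=p_int,
    )


def feedback_property_anova(
    rates: np.ndarray,
    property_labels: np.ndarray,
    correct: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of neurons selective for a feedback stimulus property.

    One-way ANOVA of each neuron's feedback-window rate (``rates`` is
    ``[n_neurons, n_trials]``) across the property levels, separately in
    correct and incorrect trials.  Neurons with a level holding fewer than 2
    trials in a split are skipped in that split.  Returns one row per split
    with the selective count and fraction at ``alpha``.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    property_labels = np.asarray(property_labels)
    correct = np.asarray(correct, dtype=bool)
    rows = []
    for split, mask in (("correct", correct), ("incorrect", ~correct)):
        labels = property_labels[mask]
        levels = np.unique(labels)
        n_sel, n_tested, pvals = 0, 0, []
        for i in range(rates.shape[0]):
            groups = [rates[i, mask][labels == lv] for lv in levels]
            if len(groups) < 2 or any(len(g) < 2 for g in groups):
                pvals.append(float("nan"))
                continue
            if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
                p = 1.0  # identical rates everywhere: no effect by definition
            else:
                _, p = stats.f_oneway(*groups)
            n_tested += 1
            pvals.append(float(p))
            if p < alpha:
                n_sel += 1
        rows.append(
            {"split": split, "n_tested": n_tested, "n_selective": n_sel,
             "selective_fraction": n_sel / n_tested if n_tested else float("nan"),
             "alpha": alpha}
        )
    return pd.DataFrame(rows)
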