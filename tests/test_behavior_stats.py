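"""Behavioral statistics against hand-computed and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import lognorm

from oipr.behavior_stats import (
    aggregate_by_day,
    behavior_report,
    compare_proportions,
    compare_reaction_times,
    performance_by_run_and_size,
    switch_proportions,
)
from oipr.synthetic_data import (
    AgentParams,
    TaskDesignParams,
    generate_block_design,
    simulate_behavior,
)


def binomial_upper_tail(k, n, p=0.5):
    """Oracle: exact one-sided tail sum over the binomial pmf."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def chi2_by_hand(ka, na, kb, nb):
    """Oracle: 2x2 chi-square from explicitly computed expected counts."""
    obs = np.array([[ka, na - ka], [kb, nb - kb]], dtype=float)
    total = obs.sum()
    exp = np.outer(obs.sum(1), obs.sum(0)) / total
    return float(((obs - exp) ** 2 / exp).sum())


def toy_trials(rows):
    """Minimal trial table for proportion tests."""
    df = pd.DataFrame(
        rows,
        columns=["session_id", "block_index", "run_index", "scene_index",
                 "reward_size", "correct", "stay_switch", "reaction_time"],
    )
    df["movement_time"] = 250.0
    return df


class TestBinomial:
    def test_tail_sum_oracle_18_of_20(self):
        d = generate_block_design(TaskDesignParams(n_blocks=1), seed=0)
        t = simulate_behavior(d, seed=1)
        # take the package's p-value machinery on a crafted stratum
        rows = [("s", 1, 2, i % 5 + 1, "small", i < 18, "stay", 300.0)
                for i in range(20)]
        res = performance_by_run_and_size(toy_trials(rows))
        r = next(x for x in res if x.run_index == 2 and x.reward_size == "small")
        assert r.k == 18 and r.n == 20
        assert r.p_value == pytest.approx(binomial_upper_tail(18, 20), rel=1e-12)
        assert t is not None

    def test_all_correct_of_30_has_p_two_to_minus_30(self):
        rows = [("s", 1, 3, i % 5 + 1, "large", True, "stay", 300.0)
                for i in range(30)]
        res = performance_by_run_and_size(toy_trials(rows))
        r = next(x for x in res if x.run_index == 3 and x.reward_size == "large")
        assert r.p_value == pytest.approx(2.0**-30, rel=1e-9)

    def test_exactly_chance_never_significant(self):
        for n in (10, 40, 200):
            rows = [("s", 1, 2, i % 5 + 1, "medium", i < n // 2, "stay", 300.0)
                    for i in range(n)]
            res = performance_by_run_and_size(toy_trials(rows))
            r = next(x for x in res if x.run_index == 2 and x.reward_size == "medium")
            assert r.p_value > 0.05

    def test_p_monotone_decreasing_in_k(self):
        ps = []
        for k in range(10, 21):
            rows = [("s", 1, 2, i % 5 + 1, "small", i < k, "stay", 300.0)
                    for i in range(20)]
            res = performance_by_run_and_size(toy_trials(rows))
            ps.append(next(x for x in res
                           if x.run_index == 2 and x.reward_size == "small").p_value)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_empty_stratum_flagged_with_nan(self):
        rows = [("s", 1, 1, 1, "small", True, "undefined", 300.0)]
        res = performance_by_run_and_size(toy_trials(rows))
        r = next(x for x in res if x.run_index == 6 and x.reward_size == "large")
        assert r.n == 0 and np.isnan(r.p_value)


class TestChiSquare:
    def test_statistic_matches_hand_computed_expected_counts(self):
        stat, _ = compare_proportions((30, 40), (15, 40))
        assert stat == pytest.approx(chi2_by_hand(30, 40, 15, 40), rel=1e-12)

    def test_identical_proportions_give_zero_statistic(self):
        stat, p = compare_proportions((10, 20), (10, 20))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        s1, p1 = compare_proportions((30, 40), (15, 40))
        s2, p2 = compare_proportions((15, 40), (30, 40))
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_expected_cell_flagged(self):
        with pytest.warns(UserWarning, match="zero expected cell"):
            stat, p = compare_proportions((0, 5), (0, 7))
        assert stat == 0.0


class TestSwitch:
    def test_always_stay_agent_has_zero_switch_proportion(self):
        d = generate_block_design(TaskDesignParams(n_blocks=10), seed=2)
        agent = AgentParams(
            p_stay_after_correct={s: 1.0 for s in ("small", "medium", "large")},
            p_stay_after_incorrect={s: 1.0 for s in ("small", "medium", "large")},
        )
        t = simulate_behavior(d, agent, seed=3)
        props, _ = switch_proportions(t)
        assert all(r.k == 0 for r in props if r.n > 0)

    def test_outcome_filters_partition_all_trials(self, synthetic_session):
        trials, _ = synthetic_session
        allp, _ = switch_proportions(trials, "all")
        cor, _ = switch_proportions(trials, "after_correct")
        inc, _ = switch_proportions(trials, "after_incorrect")
        for a, c, i in zip(allp, cor, inc):
            assert a.n == c.n + i.n
            assert a.k == c.k + i.k

    def test_small_reward_switches_more_in_every_run(self):
        d = generate_block_design(TaskDesignParams(n_blocks=200), seed=4)
        t = simulate_behavior(d, seed=5)
        props, _ = switch_proportions(t)
        by = {(r.run_index, r.reward_size): r.proportion for r in props}
        for run in range(2, 7):
            assert by[(run, "small")] > by[(run, "medium")]
            assert by[(run, "small")] > by[(run, "large")]


class TestReactionTimes:
    def test_identical_samples_have_zero_ks(self):
        rows = [("s", 1, 1, i % 5 + 1, s, True, "undefined", 300.0 + i)
                for s in ("small", "medium") for i in range(10)]
        res = compare_reaction_times(toy_trials(rows))
        row = res[(res.group_a == "medium") & (res.group_b == "small")].iloc[0]
        assert row.ks_statistic == 0.0

    def test_disjoint_supports_have_ks_one(self):
        rows = [("s", 1, 1, i + 1, "small", True, "undefined", float(i + 1))
                for i in range(3)]
        rows += [("s", 1, 1, i + 1, "large", True, "undefined", float(i + 4))
                 for i in range(3)]
        res = compare_reaction_times(toy_trials(rows))
        assert res.iloc[0].ks_statistic == 1.0

    def test_shifted_lognormals_match_analytic_sup_difference(self, rng):
        # oracle: sup |F_A - F_B| for two log-normals by dense numeric search
        med_a, med_b, sig = 300.0, 400.0, 0.2
        grid = np.linspace(100, 900, 20001)
        fa = lognorm.cdf(grid, sig, scale=med_a)
        fb = lognorm.cdf(grid, sig, scale=med_b)
        target = np.max(np.abs(fa - fb))
        n = 500
        rows = [("s", 1, 1, i % 5 + 1, "small",
                 True, "undefined", float(rng.lognormal(np.log(med_b), sig)))
                for i in range(n)]
        rows += [("s", 1, 1, i % 5 + 1, "medium",
                  True, "undefined", float(rng.lognormal(np.log(med_a), sig)))
                 for i in range(n)]
        res = compare_reaction_times(toy_trials(rows))
        stat = res.iloc[0].ks_statistic
        se = np.sqrt(target * (1 - target) * 2 / n)
        assert abs(stat - target) < 2.5 * se


class TestAggregation:
    @staticmethod
    def _prop(df):
        return df["correct"].mean()

    def test_single_session_day_mean_equals_pooled(self, synthetic_session):
        trials, _ = synthetic_session
        per_day, mean = aggregate_by_day(trials, self._prop)
        assert mean == pytest.approx(trials.correct.mean())
        assert len(per_day) == 1

    def test_unbalanced_sessions_day_mean_differs_from_pooled(self):
        rows = [("a", 1, 1, i % 5 + 1, "small", i < 4, "undefined", 300.0)
                for i in range(10)]
        rows += [("b", 1, 1, i % 5 + 1, "small", i < 54, "undefined", 300.0)
                 for i in range(90)]
        t = toy_trials(rows)
        _, day_mean = aggregate_by_day(t, self._prop)
        pooled = t.correct.mean()
        assert day_mean == pytest.approx(0.5)
        assert pooled == pytest.approx(0.58)
        assert abs(day_mean - pooled) > 0.05


def test_behavior_report_is_tidy(synthetic_session):
    trials, _ = synthetic_session
    rep = behavior_report(trials)
    assert {"measure", "proportion", "stars"} <= set(rep.columns)
    assert (rep[rep.measure == "p_correct"].groupby("run_index").size() == 3).all()
    assert rep.proportion.dropna().between(0, 1).all()
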