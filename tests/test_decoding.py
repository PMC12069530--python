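"""Decoding correctness: separability, chance under shuffling, the null
model's shape, the consecutive-bin rule, sliding windows and balanced
two-variable decoding."""

import numpy as np
import pytest

from oipr.core_data import bin_spike_counts
from oipr.decoding import (
    DecoderSpec,
    NullModel,
    _consecutive_mask,
    _decode_sample,
    assess_significance,
    balanced_decode,
    build_null,
    decode_timecourse,
    significance_stars,
    sliding_window_decode,
)
from oipr.errors import EligibilityError, ParameterError
from oipr.pseudopopulation import NeuronTrials
from oipr.synthetic_data import TaskDesignParams, generate_session


def gaussian_population(rng, n_neurons=2, n_per=20, sep=10.0, n_bins=3):
    """Two-label population with clusters ``sep`` SDs apart in every bin."""
    labels = np.repeat(["lo", "hi"], n_per)
    shift = np.where(labels == "hi", sep, 0.0)[:, None]
    return [
        NeuronTrials(f"n{i}", rng.normal(0, 1, size=(2 * n_per, n_bins)) + shift,
                     labels)
        for i in range(n_neurons)
    ]


class TestTimecourse:
    def test_widely_separated_clusters_decode_perfectly(self, rng):
        pop = gaussian_population(rng)
        spec = DecoderSpec(k_folds=4, n_resamples=3, n_per_condition=20)
        res = decode_timecourse(pop, spec, seed=0)
        np.testing.assert_array_equal(res.mean_accuracy, 1.0)
        assert res.chance == 0.5

    def test_shuffled_labels_sit_at_chance(self, rng):
        pop = gaussian_population(rng, n_per=30)
        spec = DecoderSpec(k_folds=5, n_resamples=8, n_per_condition=30)
        res = decode_timecourse(pop, spec, seed=1, permute_labels=True)
        null_sd = res.accuracies.mean(axis=0).std(ddof=1)
        assert abs(res.mean_accuracy.mean() - 0.5) < max(2 * null_sd, 0.1)

    def test_affine_rescaling_of_counts_is_absorbed_by_zscoring(self, rng):
        pop = gaussian_population(rng, n_per=12, sep=2.0)
        pop_scaled = [
            NeuronTrials(nt.neuron_id, nt.counts * 7.0 + 3.0, nt.labels)
            for nt in pop
        ]
        spec = DecoderSpec(k_folds=3, n_resamples=2, n_per_condition=12)
        a = decode_timecourse(pop, spec, seed=2)
        b = decode_timecourse(pop_scaled, spec, seed=2)
        np.testing.assert_allclose(a.mean_accuracy, b.mean_accuracy)

    def test_single_neuron_matches_threshold_oracle(self):
        # 1 neuron, 2 labels, 4 columns, fixed folds: the SVM must match an
        # exhaustive best-threshold classifier on separable data
        X = np.array([[0.0, 1.0, 10.0, 11.0]])[:, :, None]  # [1, 4, 1]
        labels = np.array(["a", "a", "b", "b"])
        fold_ids = np.array([0, 1, 0, 1])

        def threshold_oracle():
            correct = 0
            for f in (0, 1):
                tr, te = fold_ids != f, fold_ids == f
                best = None
                vals = np.unique(X[0, tr, 0])
                midpoints = (vals[:-1] + vals[1:]) / 2  # max-margin thresholds
                for thr in midpoints:
                    for sign in (1, -1):
                        pred = np.where(sign * X[0, tr, 0] > sign * thr, "b", "a")
                        acc = np.mean(pred == labels[tr])
                        cand = (acc, thr, sign)
                        best = cand if best is None or cand[0] > best[0] else best
                _, thr, sign = best
                pred = np.where(sign * X[0, te, 0] > sign * thr, "b", "a")
                correct += np.sum(pred == labels[te])
            return correct / len(labels)

        acc = _decode_sample(X, labels, fold_ids, DecoderSpec(k_folds=2))
        assert acc[0] == threshold_oracle() == 1.0

    def test_single_label_rejected(self, rng):
        pop = [NeuronTrials("n", rng.normal(size=(4, 1)), np.array(["a"] * 4))]
        with pytest.raises(ParameterError):
            decode_timecourse(pop, DecoderSpec(k_folds=2, n_per_condition=2))


class TestNullModel:
    def test_pool_size_is_shuffles_times_bins(self, rng):
        pop = gaussian_population(rng, n_per=8, n_bins=4)
        spec = DecoderSpec(k_folds=2, n_resamples=2, n_per_condition=8)
        null = build_null(pop, spec, n_shuffles=5, seed=3)
        assert null.size == 5 * 4
        assert null.corrected_alpha == pytest.approx(0.05 / 20)

    def test_pooled_mean_is_chance(self, rng):
        pop = gaussian_population(rng, n_per=20, n_bins=2)
        spec = DecoderSpec(k_folds=4, n_resamples=3, n_per_condition=20)
        null = build_null(pop, spec, n_shuffles=10, seed=4)
        se = null.values.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.values.mean() - 0.5) < max(2 * se, 0.05)

    def test_too_few_shuffles_rejected(self, rng):
        pop = gaussian_population(rng, n_per=6)
        with pytest.raises(ParameterError):
            build_null(pop, DecoderSpec(n_per_condition=6), n_shuffles=1)

    def test_full_scale_alpha_matches_printed_value(self):
        null = NullModel(values=np.zeros(1260), n_shuffles=20, n_bins=63)
        assert null.size == 1260
        assert null.corrected_alpha == pytest.approx(3.96e-5, rel=0.01)


class TestSignificance:
    def _result(self, acc):
        acc = np.asarray(acc, dtype=float)
        return type("R", (), {"mean_accuracy": acc})()

    def test_short_runs_are_masked_out(self):
        passing = np.array([0, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 0], dtype=bool)
        mask = _consecutive_mask(passing, 5)
        assert mask.tolist() == [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 0]

    def test_observed_below_null_max_never_significant(self, rng):
        null = NullModel(values=rng.normal(0.5, 0.02, 100), n_shuffles=10, n_bins=10)
        obs = np.full(10, null.values.max() - 0.01)
        res = decode_result = self._result(obs)
        sig = assess_significance(decode_result, null, min_consecutive=1,
                                  p_method="empirical")
        assert not sig.mask.any()
        assert res is decode_result

    def test_strong_signal_flagged_by_normal_p(self, rng):
        null = NullModel(values=rng.normal(0.33, 0.01, 200), n_shuffles=20,
                         n_bins=10)
        obs = np.full(10, 0.9)
        sig = assess_significance(self._result(obs), null, min_consecutive=5)
        assert sig.mask.all()
        assert (sig.z_scores > 10).all()

    def test_empirical_p_uses_plus_one_exceedance(self, rng):
        null = NullModel(values=np.linspace(0.2, 0.4, 99), n_shuffles=9, n_bins=11)
        sig = assess_significance(self._result(np.array([1.0])), null,
                                  min_consecutive=1)
        assert sig.p_empirical[0] == pytest.approx(1 / 100)


@pytest.fixture(scope="module")
def window_session():
    trials, spikes = generate_session(
        TaskDesignParams(n_blocks=12), n_neurons=25, seed=30
    )
    return trials, spikes


class TestSlidingWindows:
    def test_thirty_trial_blocks_give_21_windows_of_100_trials_at_10_blocks(self):
        # design arithmetic: window starts 1..21; 10 blocks x 10 trials each
        trials, _ = generate_session(TaskDesignParams(n_blocks=10), n_neurons=1,
                                     seed=31)
        starts = np.arange(1, 30 - 10 + 2)
        assert len(starts) == 21
        first = trials[(trials.trial_index_in_block >= 1)
                       & (trials.trial_index_in_block <= 10)]
        assert len(first) == 100

    def test_feedback_decoding_significant_in_every_window(self, window_session):
        trials, spikes = window_session
        binned = bin_spike_counts(spikes, trials, "feedback_onset",
                                  (-100, 650), 250, 50)
        spec = DecoderSpec(k_folds=4, n_resamples=4, n_per_condition=20)
        res = sliding_window_decode(
            binned, trials, trials.reward_size.to_numpy(), spec,
            n_shuffles=3, null_resamples=2, min_consecutive=3, seed=32,
        )
        assert res.accuracy.shape == (21, binned.n_bins)
        assert res.significant.any(axis=1).all()
        assert (res.accuracy >= 0).all() and (res.accuracy <= 1).all()

    def test_window_equal_to_block_length_gives_single_window(self, window_session):
        trials, spikes = window_session
        binned = bin_spike_counts(spikes, trials, "feedback_onset",
                                  (0, 500), 250, 250)
        spec = DecoderSpec(k_folds=3, n_resamples=2, n_per_condition=60)
        res = sliding_window_decode(
            binned, trials, trials.reward_size.to_numpy(), spec, window=30,
            min_trials_per_condition=60, n_shuffles=2, null_resamples=2,
            min_consecutive=1, seed=33,
        )
        assert res.accuracy.shape == (1, 2)
        assert res.window_starts.tolist() == [1]
        assert (res.accuracy > res.chance).all()  # whole-block feedback decode

    def test_window_eligibility_enforced(self, window_session):
        trials, spikes = window_session
        binned = bin_spike_counts(spikes, trials, "feedback_onset",
                                  (0, 250), 250, 250)
        with pytest.raises(EligibilityError):
            sliding_window_decode(
                binned, trials, trials.reward_size.to_numpy(),
                DecoderSpec(n_per_condition=60), min_trials_per_condition=60,
            )


class TestBalanced:
    def test_confounded_variable_falls_to_chance_after_balancing(self, rng):
        n = 400
        a = rng.integers(2, size=n)
        b = np.where(rng.random(n) < 0.9, a, 1 - a)  # ~80% label correlation
        counts = rng.poisson(2.0 + 1.5 * a, size=(30, n)).astype(float)
        res = balanced_decode(counts, a.astype(str), b.astype(str),
                              n_resamples=5, seed=6)
        assert res.chance == 0.5
        assert res.accuracy_a > 0.8 and res.p_a < 0.05
        null_sd = res.null_b.std(ddof=1)
        assert abs(res.accuracy_b - 0.5) < max(2 * null_sd, 0.06)
        assert res.p_b > 0.05

    def test_independently_coded_variables_both_recovered(self, rng):
        n = 400
        a = rng.integers(2, size=n)
        b = np.where(rng.random(n) < 0.9, a, 1 - a)
        counts = np.vstack([
            rng.poisson(2.0 + 1.5 * a, size=(15, n)),
            rng.poisson(2.0 + 1.5 * b, size=(15, n)),
        ]).astype(float)
        res = balanced_decode(counts, a.astype(str), b.astype(str),
                              n_resamples=5, seed=7)
        assert res.accuracy_a > 0.7 and res.p_a < 0.05
        assert res.accuracy_b > 0.7 and res.p_b < 0.05

    def test_minimum_cell_count_excludes_neurons(self, rng):
        a = np.array(["x"] * 30 + ["y"] * 30)
        b = np.array((["u"] * 15 + ["v"] * 15) * 2)
        good = (rng.poisson(3.0, 60), a, b)
        bad = (rng.poisson(3.0, 40), a[:40], b[:40])  # cell (y, u/v) too small
        res = balanced_decode([good[0], bad[0]], [good[1], bad[1]],
                              [good[2], bad[2]], min_per_cell=15, n_resamples=2,
                              n_shuffles=2, seed=8)
        assert res.n_neurons == 1

    def test_no_eligible_neuron_is_an_error(self, rng):
        a = np.array(["x", "y"] * 4)
        b = np.array(["u", "v"] * 4)
        with pytest.raises(EligibilityError):
            balanced_decode(rng.poisson(3.0, size=(2, 8)).astype(float), a, b)

    def test_stars_encoding(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"
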