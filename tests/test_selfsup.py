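import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kccafmri import Benchmark1DPipeline, KernelSpec, simulate_1d
from kccafmri.selfsup import (OptimizationTrace, ShuffleConfig,
                              apparent_partial_auc, label_top_fraction,
                              noise_injection_loss, optimize_kernel_params,
                              random_cluster_shuffle, reversal_shuffle,
                              shuffle_loss)


class TestLabelTopFraction:
    def test_simple_example(self):
        np.testing.assert_array_equal(
            label_top_fraction(np.array([3.0, 2.0, 1.0]), 1 / 3),
            [True, False, False])

    def test_exact_count_at_default_fraction(self, rng):
        labels = label_top_fraction(rng.standard_normal(10_000), 0.1)
        assert labels.sum() == 1000

    def test_all_equal_ties_resolved_by_index(self):
        labels = label_top_fraction(np.ones(10), 0.3)
        np.testing.assert_array_equal(np.flatnonzero(labels), [0, 1, 2])

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            label_top_fraction(np.ones(5), 1.0)


class TestReversalShuffle:
    def test_ten_voxel_method1_oracle(self, rng):
        # Q=10, top 10% => one activated voxel; method 1 reverses the other 9
        alpha = np.array([0.9, 0.1, 0.8, 0.3, 0.5, 0.2, 0.7, 0.4, 0.6, 0.05])
        labels = label_top_fraction(alpha, 0.1)
        assert labels.sum() == 1 and labels[0]
        data = rng.standard_normal((4, 10))
        config = ShuffleConfig.method1(labels)
        shuffled, perm = reversal_shuffle(data, alpha, config, labels=labels)

        inactive = np.flatnonzero(~labels)
        by_alpha = inactive[np.argsort(-alpha[inactive])]
        expected = np.arange(10)
        expected[by_alpha] = by_alpha[::-1]
        np.testing.assert_array_equal(perm, expected)
        assert perm[0] == 0  # the single activated voxel stays put
        np.testing.assert_array_equal(shuffled, data[:, perm])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_involution_and_multiset_preservation(self, seed):
        rng = np.random.default_rng(seed)
        alpha = rng.standard_normal(40)
        data = rng.standard_normal((6, 40))
        labels = label_top_fraction(alpha, 0.1)
        for config in (ShuffleConfig.method1(labels),
                       ShuffleConfig.method2(labels)):
            shuffled, perm = reversal_shuffle(data, alpha, config, labels=labels)
            np.testing.assert_array_equal(perm[perm], np.arange(40))
            # applying the permutation twice restores the data
            np.testing.assert_array_equal(shuffled[:, perm], data)
            np.testing.assert_array_equal(np.sort(shuffled, axis=1),
                                          np.sort(data, axis=1))

    def test_activated_location_set_unchanged(self, rng):
        alpha = rng.standard_normal(60)
        labels = label_top_fraction(alpha, 0.1)
        for config in (ShuffleConfig.method1(labels),
                       ShuffleConfig.method2(labels)):
            _, perm = reversal_shuffle(rng.standard_normal((3, 60)), alpha,
                                       config, labels=labels)
            np.testing.assert_array_equal(labels[perm], labels)

    def test_method2_cluster_sizes(self):
        labels = np.zeros(100, bool)
        labels[:10] = True
        config = ShuffleConfig.method2(labels)
        assert config.q1 == config.q2 == 5

    def test_cluster_too_large_raises(self, rng):
        alpha = rng.standard_normal(20)
        labels = label_top_fraction(alpha, 0.1)
        with pytest.raises(ValueError, match="cluster"):
            reversal_shuffle(rng.standard_normal((3, 20)), alpha,
                             ShuffleConfig(19, 5), labels=labels)

    def test_random_shuffle_stays_within_clusters(self, rng):
        alpha = rng.standard_normal(50)
        labels = label_top_fraction(alpha, 0.1)
        config = ShuffleConfig.method1(labels)
        _, perm = random_cluster_shuffle(rng.standard_normal((2, 50)), alpha,
                                         config, seed=4, labels=labels)
        np.testing.assert_array_equal(labels[perm], labels)
        np.testing.assert_array_equal(np.sort(perm), np.arange(50))


class TestApparentPartialAuc:
    def test_perfect_recovery_saturates(self, rng):
        alpha = rng.standard_normal(200)
        labels = label_top_fraction(alpha, 0.1)
        assert apparent_partial_auc(labels, alpha) == pytest.approx(0.1)

    def test_chance_level_expectation(self):
        rng = np.random.default_rng(0)
        labels = np.zeros(500, bool)
        labels[:50] = True
        values = [apparent_partial_auc(labels, rng.standard_normal(500))
                  for _ in range(300)]
        assert np.mean(values) == pytest.approx(0.005, abs=0.0015)

    def test_six_voxel_toy_against_threshold_enumeration(self):
        labels = np.array([1, 1, 0, 0, 0, 0], bool)
        scores = np.array([0.9, 0.2, 0.8, 0.1, 0.05, 0.01])
        got = apparent_partial_auc(labels, scores, fpr_max=1.0)
        # exhaustive thresholds: vertices of the empirical ROC
        thresholds = np.r_[np.inf, np.sort(scores)[::-1]]
        fpr = [np.mean(scores[~labels] >= th) for th in thresholds]
        tpr = [np.mean(scores[labels] >= th) for th in thresholds]
        expected = np.trapezoid(tpr, fpr)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            apparent_partial_auc(np.ones(5, bool), np.arange(5.0))


class _StubPipeline:
    """Activation independent of the data: shuffles recover labels exactly."""

    def __init__(self, alpha):
        self._alpha = alpha
        self.raw_data = np.zeros((3, alpha.size))

    def activation(self, spec):
        return self._alpha

    def activation_of(self, spec, data):
        return self._alpha


class TestShuffleLoss:
    def test_perfect_recovery_hits_lower_bound(self, rng):
        pipeline = _StubPipeline(rng.standard_normal(300))
        loss = shuffle_loss(pipeline, KernelSpec("linear"))
        assert loss == pytest.approx(-0.2)

    def test_loss_bounds_on_real_pipeline(self, tiny_dataset_1d):
        from kccafmri.pipelines import VolumePipeline  # noqa: F401
        pipeline = Benchmark1DPipeline(tiny_dataset_1d, n_repeats=1)
        loss = shuffle_loss(pipeline, KernelSpec("linear", gamma=100.0))
        assert -0.2 <= loss <= 0.0

    def test_baseline_without_parameters_scores_too(self, tiny_dataset_1d):
        # the GLM baseline has no kernel parameters but supports the loss
        class GlmPipeline:
            def __init__(self, pipeline):
                self.raw_data = pipeline.raw_data
                self._xeff = pipeline.xeff

            def activation(self, spec):
                from kccafmri.baseline import glm_gs
                return glm_gs(self.raw_data, self._xeff).alpha

            def activation_of(self, spec, data):
                from kccafmri.baseline import glm_gs
                return glm_gs(data, self._xeff).alpha

        pipeline = GlmPipeline(Benchmark1DPipeline(tiny_dataset_1d))
        loss = shuffle_loss(pipeline, None)
        assert -0.2 <= loss <= 0.0


class TestNoiseInjectionLoss:
    def test_zero_scale_gives_zero(self, tiny_dataset_1d):
        pipeline = Benchmark1DPipeline(tiny_dataset_1d)
        spec = KernelSpec("linear", gamma=10.0)
        assert noise_injection_loss(pipeline, spec, noise_scale=0.0) == 0.0

    def test_loss_nonnegative(self, tiny_dataset_1d):
        pipeline = Benchmark1DPipeline(tiny_dataset_1d, n_repeats=2)
        spec = KernelSpec("tanh", {"b": 0.3, "c": 0.1}, gamma=50.0)
        assert noise_injection_loss(pipeline, spec, n_repeats=2) >= 0.0

    def test_estimator_variance_shrinks_with_repeats(self):
        # Monte-Carlo averaging: std over seeds drops roughly like 1/sqrt(n)
        dataset = simulate_1d(T=30, Q=120, seed=3)
        spec = KernelSpec("tanh", {"b": 0.5, "c": 0.2}, gamma=10.0)

        def spread(n_repeats):
            values = []
            for seed in range(30):
                pipeline = Benchmark1DPipeline(dataset, n_repeats=n_repeats,
                                               seed=seed)
                values.append(noise_injection_loss(pipeline, spec,
                                                   n_repeats=n_repeats,
                                                   seed=seed))
            return np.std(values)

        ratio = spread(1) / spread(16)
        assert 1.8 < ratio < 9.0


class TestOptimizer:
    @staticmethod
    def _quadratic(spec):
        target = {"b": 0.2, "c": -0.1, "b1": 0.2, "b2": 0.1, "C": 5.0,
                  "sigma2": 2.0}
        loss = sum((v - target.get(k, 0.0)) ** 2 for k, v in spec.params.items())
        return loss + (np.log10(spec.gamma) - 1.0) ** 2

    @pytest.mark.parametrize("kernel,budget", [("linear", 15),
                                               ("mixed_tanh", 200)])
    def test_exact_budget(self, kernel, budget):
        trace = optimize_kernel_params(self._quadratic, kernel, seed=0)
        assert len(trace) == budget

    def test_same_seed_identical_trace(self):
        t1 = optimize_kernel_params(self._quadratic, "tanh", seed=42)
        t2 = optimize_kernel_params(self._quadratic, "tanh", seed=42)
        assert [(s.params, s.gamma, l) for s, l in t1.evaluations] == \
               [(s.params, s.gamma, l) for s, l in t2.evaluations]

    def test_linear_init_for_tanh_family(self):
        trace = optimize_kernel_params(self._quadratic, "mixed_tanh", seed=1,
                                       gamma_init=25.0)
        first = trace.evaluations[0][0]
        assert first.params["b1"] == pytest.approx(1e-3, rel=1e-6)
        assert first.params["b2"] == pytest.approx(0.0, abs=1e-9)
        assert first.params["c"] == pytest.approx(0.0, abs=1e-9)
        assert first.gamma == pytest.approx(25.0, rel=1e-6)

    def test_all_evaluations_in_bounds(self):
        trace = optimize_kernel_params(self._quadratic, "mixed_tanh", seed=3)
        for spec, _ in trace.evaluations:
            for key, value in spec.params.items():
                lo, hi = spec.info.param_bounds[key]
                assert lo < value < hi
            assert 0.1 <= spec.gamma <= 1e4

    def test_best_is_minimum_of_trace(self):
        trace = optimize_kernel_params(self._quadratic, "gaussian", seed=5)
        assert trace.best_loss == min(l for _, l in trace.evaluations)

    def test_budget_below_one_raises(self):
        with pytest.raises(ValueError):
            optimize_kernel_params(self._quadratic, "linear", seed=0, budget=0)

    def test_budget_extension_stability_on_benchmark(self):
        # 50% more steps changes the best loss by under 5%
        dataset = simulate_1d(T=100, Q=2000, seed=11)
        pipeline = Benchmark1DPipeline(dataset, n_repeats=3, seed=11)
        base = optimize_kernel_params(pipeline.loss, "linear", seed=11)
        extended = optimize_kernel_params(pipeline.loss, "linear", seed=11,
                                          budget=22)
        rel_change = abs(extended.best_loss - base.best_loss) / abs(base.best_loss)
        assert rel_change < 0.05
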