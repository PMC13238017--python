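import itertools

import numpy as np
import pytest

from kccafmri import ActivationMap, KernelWorkspace, VolumeGeometry, simulate_1d
from kccafmri.metrics import (NeighborHistogram, kl_divergence,
                              neighbor_joint_hist, param_grid, partial_auc,
                              r_corr, r_gray, r_roi, r_shuffling, r_truth,
                              roc_curve, sphere_mask)


class TestRocCurve:
    def test_perfect_separation(self):
        labels = np.array([1, 1, 0, 0], bool)
        curve = roc_curve(labels, np.array([0.9, 0.8, 0.2, 0.1]))
        assert curve.total_auc == pytest.approx(1.0)
        assert curve.partial_auc_01 == pytest.approx(0.1)

    def test_all_tied_scores_give_chance(self):
        labels = np.array([1, 0, 1, 0, 0, 1], bool)
        curve = roc_curve(labels, np.zeros(6))
        assert curve.total_auc == pytest.approx(0.5)
        assert curve.partial_auc_01 == pytest.approx(0.005)

    def test_eight_element_instance_against_enumeration(self):
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0], bool)
        scores = np.array([0.7, 0.7, 0.9, 0.2, 0.4, 0.1, 0.5, 0.3])
        curve = roc_curve(labels, scores)
        # brute force: evaluate (FPR, TPR) at every distinct threshold
        pts = [(0.0, 0.0)]
        for th in sorted(set(scores), reverse=True):
            fpr = np.mean(scores[~labels] >= th)
            tpr = np.mean(scores[labels] >= th)
            pts.append((fpr, tpr))
        fpr_e, tpr_e = np.array(sorted(pts)).T
        assert curve.total_auc == pytest.approx(np.trapezoid(tpr_e, fpr_e))
        np.testing.assert_allclose(sorted(curve.fpr), sorted(fpr_e))

    def test_endpoints(self):
        curve = roc_curve(np.array([1, 0, 1], bool), np.array([0.3, 0.2, 0.9]))
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve(np.ones(4, bool), np.arange(4.0))


class TestRatios:
    def test_r_truth_arithmetic(self):
        assert r_truth(0.05, 0.05) == 1.0
        assert r_truth(0.06, 0.05) == pytest.approx(1.2)
        with pytest.raises(ValueError):
            r_truth(0.05, 0.0)

    def test_r_shuffling_arithmetic(self):
        assert r_shuffling(-0.1, -0.1) == 1.0
        assert r_shuffling(-0.18, -0.09) == pytest.approx(2.0)
        assert r_shuffling(-0.15, -0.05) > 0
        with pytest.raises(ValueError):
            r_shuffling(-0.1, 0.0)

    def test_r_gray_identical_ranking_is_one(self, rng):
        gray = np.zeros(200, bool)
        gray[rng.permutation(200)[:80]] = True
        scores = rng.standard_normal(200)
        assert r_gray(scores, gray, scores.copy()) == pytest.approx(1.0)

    def test_r_gray_mask_as_activation_saturates_numerator(self, rng):
        gray = np.zeros(100, bool)
        gray[:40] = True
        baseline = rng.standard_normal(100)
        curve = roc_curve(gray, gray.astype(float))
        assert partial_auc(curve.fpr, curve.tpr, 0.1) == pytest.approx(0.1)
        denom_curve = roc_curve(gray, baseline)
        expected = 0.1 / partial_auc(denom_curve.fpr, denom_curve.tpr, 0.1)
        assert r_gray(gray.astype(float), gray, baseline) == pytest.approx(expected)

    def test_r_gray_composition_oracle(self, rng):
        gray = np.zeros(300, bool)
        gray[rng.permutation(300)[:100]] = True
        activation = rng.standard_normal(300)
        baseline = rng.standard_normal(300)
        a = roc_curve(gray, activation)
        b = roc_curve(gray, baseline)
        expected = (partial_auc(a.fpr, a.tpr, 0.1)
                    / partial_auc(b.fpr, b.tpr, 0.1))
        assert r_gray(activation, gray, baseline) == pytest.approx(expected)

    def test_r_gray_degenerate_mask_raises(self, rng):
        with pytest.raises(ValueError):
            r_gray(rng.standard_normal(5), np.ones(5, bool),
                   rng.standard_normal(5))


class TestRoi:
    def test_roi_values_at_std_sum_to_count(self):
        alpha = np.zeros(50)
        alpha[:25] = 2.0
        alpha[25:] = -2.0  # std = 2
        roi = np.zeros(50, bool)
        roi[:7] = True
        amap = ActivationMap(alpha, method="glm")
        # normalized values inside the ROI are exactly 1
        assert r_roi(amap, roi) == pytest.approx(7.0 * alpha[0] / alpha.std())

    def test_empty_roi_is_zero(self, rng):
        amap = ActivationMap(rng.standard_normal(30), method="glm")
        assert r_roi(amap, np.zeros(30, bool)) == 0.0

    def test_zero_variance_raises(self):
        amap = ActivationMap(np.ones(10), method="glm")
        with pytest.raises(ValueError):
            r_roi(amap, np.ones(10, bool))

    def test_sphere_mask_against_distance_enumeration(self):
        geo = VolumeGeometry.full_grid((10, 10, 10), (2.0, 2.0, 2.0))
        center = np.array([8.0, 10.0, 6.0])
        mask = sphere_mask(geo, center, radius_mm=6.0)
        expected = np.zeros(geo.n_voxels, bool)
        for flat, (i, j, k) in enumerate(itertools.product(range(10),
                                                           repeat=3)):
            d2 = ((2 * i - center[0]) ** 2 + (2 * j - center[1]) ** 2
                  + (2 * k - center[2]) ** 2)
            expected[flat] = d2 <= 36.0
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() > 0


class TestRCorr:
    def test_noiseless_rank_one_is_one(self):
        t = np.linspace(0, 2 * np.pi, 40)
        xeff = np.sin(t)
        weights = np.random.default_rng(0).standard_normal(60)
        data = np.outer(xeff, weights)  # every row proportional to xeff
        assert r_corr(data, xeff, "linear") == pytest.approx(1.0, abs=1e-10)
        assert r_corr(data, xeff, "reduced_tanh", grid_points=21) > 0.999

    def test_sign_invariance(self, rng):
        data = rng.standard_normal((20, 50))
        xeff = np.sin(np.linspace(0, 2 * np.pi, 20))
        a = r_corr(data, xeff, "reduced_tanh", grid_points=11)
        b = r_corr(data, -xeff, "reduced_tanh", grid_points=11)
        assert a == pytest.approx(b, abs=1e-12)

    def test_nesting_at_matched_odd_grids(self):
        # odd grid counts put 0 on the parameter grid, so the richer kernel
        # family contains the poorer one exactly
        dataset = simulate_1d(T=40, Q=500, seed=5)
        ws = KernelWorkspace(dataset.data)
        xeff = dataset.design
        reduced = r_corr(ws, xeff, "reduced_tanh", grid_points=7)
        tanh = r_corr(ws, xeff, "tanh", grid_points=7)
        mixed = r_corr(ws, xeff, "mixed_tanh", grid_points=7)
        assert reduced <= tanh + 1e-12
        assert tanh <= mixed + 1e-12

    def test_monotone_under_grid_refinement(self):
        dataset = simulate_1d(T=30, Q=300, seed=6)
        ws = KernelWorkspace(dataset.data)
        coarse = r_corr(ws, dataset.design, "reduced_tanh", grid_points=5)
        fine = r_corr(ws, dataset.design, "reduced_tanh", grid_points=11)
        assert fine >= coarse - 1e-12

    def test_param_grid_excludes_endpoints_and_zero_on_even(self):
        grid = param_grid("reduced_tanh", 200)
        values = np.array([g["b"] for g in grid])
        assert len(values) == 200
        assert values.min() > -1.0 and values.max() < 1.0
        assert not np.any(values == 0.0)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            r_corr(rng.standard_normal((10, 20)), np.ones(8), "linear")


class TestNeighborHistogramAndKl:
    def test_constant_alpha_single_bin(self, small_geometry):
        hist = neighbor_joint_hist(np.ones(small_geometry.n_voxels),
                                   small_geometry, n_pairs=500, seed=0)
        assert hist.counts.sum() == 500
        assert (hist.counts > 0).sum() == 1

    def test_counts_sum_to_n_pairs(self, rng, small_geometry):
        hist = neighbor_joint_hist(rng.standard_normal(small_geometry.n_voxels),
                                   small_geometry, n_pairs=1000, seed=1)
        assert hist.counts.sum() == 1000

    def test_smooth_field_concentrates_on_diagonal(self):
        geo = VolumeGeometry.full_grid((10, 10, 10))
        grid = np.indices(geo.shape).sum(axis=0).astype(float)
        alpha = grid[geo.mask]  # perfectly smooth ramp
        hist = neighbor_joint_hist(alpha, geo, n_pairs=5000, seed=2, bins=16)
        diag = sum(hist.counts[i, j] for i in range(16) for j in range(16)
                   if abs(i - j) <= 1)
        assert diag > 0.9 * hist.counts.sum()

    def test_identical_histograms_near_zero(self, rng, small_geometry):
        alpha = rng.standard_normal(small_geometry.n_voxels)
        hist = neighbor_joint_hist(alpha, small_geometry, n_pairs=2000, seed=3)
        assert abs(kl_divergence(hist, hist)) < 1e-3

    def test_two_bin_toy_value(self):
        edges = (np.array([0.0, 0.5, 1.0]),) * 2
        p = NeighborHistogram(np.array([[10.0, 0.0], [0.0, 0.0]]), edges, 10)
        q = NeighborHistogram(np.array([[5.0, 0.0], [5.0, 0.0]]), edges, 10)
        expected = np.log(1.0 / (0.5 + 1e-6))
        assert kl_divergence(p, q) == pytest.approx(expected, abs=1e-12)

    def test_epsilon_bounded_below(self, rng, small_geometry):
        a = rng.standard_normal(small_geometry.n_voxels)
        edges = np.linspace(-4, 4, 17)
        h1 = neighbor_joint_hist(a, small_geometry, n_pairs=3000, seed=4,
                                 edges=edges)
        h2 = neighbor_joint_hist(a, small_geometry, n_pairs=3000, seed=5,
                                 edges=edges)
        assert kl_divergence(h1, h2) >= -1e-3

    def test_binning_mismatch_raises(self, rng, small_geometry):
        a = rng.standard_normal(small_geometry.n_voxels)
        h1 = neighbor_joint_hist(a, small_geometry, n_pairs=100, seed=0,
                                 edges=np.linspace(-3, 3, 9))
        h2 = neighbor_joint_hist(a, small_geometry, n_pairs=100, seed=0,
                                 edges=np.linspace(-4, 4, 9))
        with pytest.raises(ValueError, match="binning"):
            kl_divergence(h1, h2)
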