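"""Validation metrics for activation maps.

Five scalar metrics, each normalized per subject so cross-subject averages
are meaningful:

* ``r_truth``  — ratio of partial AUCs (FPR < 0.1) against known ground
  truth, kernel method over the GLM baseline;
* ``r_gray``   — the same ratio with gray-matter membership as the positive
  class (for real data without ground truth);
* ``r_shuffling`` — ratio of the shuffle-robustness losses;
* ``r_roi``    — summed std-normalized activation inside a small region of
  interest;
* ``r_corr``   — the eigendecomposition relevance: the largest absolute
  correlation between any eigenvector of the kernel Gram matrix and the
  effective design, maximized over a kernel-parameter grid (the
  regularization gamma plays no role in the Gram and is excluded).

Also here: the neighbor joint histogram of alpha values at face-adjacent
voxel pairs and the Kullback-Leibler divergence comparing it before and
after shuffling — the diagnostic showing that order-reversal shuffling
preserves spatial correlation while random shuffling destroys it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .geometry import VolumeGeometry
from .kcca import ActivationMap
from .kernels import KERNEL_TABLE, KernelSpec, KernelWorkspace

__all__ = [
    "RocCurve",
    "NeighborHistogram",
    "roc_curve",
    "partial_auc",
    "r_truth",
    "r_gray",
    "r_shuffling",
    "r_roi",
    "r_corr",
    "kl_divergence",
    "neighbor_joint_hist",
    "sphere_mask",
    "param_grid",
]

KL_EPSILON = 1e-6


# --------------------------------------------------------------------------
# ROC machinery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def partial_auc_01(self) -> float:
        return partial_auc(self.fpr, self.tpr, 0.1)

    @property
    def total_auc(self) -> float:
        return float(_skm.auc(self.fpr, self.tpr))


def roc_curve(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """Empirical ROC with tied scores grouped at a single threshold."""
    labels = np.asarray(labels, dtype=bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, _ = _skm.roc_curve(labels, scores, drop_intermediate=False)
    if fpr[0] != 0 or tpr[0] != 0:  # pragma: no cover - sklearn guarantees
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return RocCurve(fpr=fpr, tpr=tpr)


def partial_auc(fpr: np.ndarray, tpr: np.ndarray, fpr_max: float = 0.1) -> float:
    """Trapezoidal area under the curve restricted to FPR < ``fpr_max``."""
    if not 0 < fpr_max <= 1:
        raise ValueError("fpr_max must lie in (0, 1]")
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    cut = np.searchsorted(fpr, fpr_max, side="right")
    f = np.concatenate([fpr[:cut], [fpr_max]])
    t = np.concatenate([tpr[:cut], [np.interp(fpr_max, fpr, tpr)]])
    return float(np.trapezoid(t, f))


def _scores(activation: ActivationMap | np.ndarray) -> np.ndarray:
    return (activation.alpha if isinstance(activation, ActivationMap)
            else np.asarray(activation, dtype=float))


# --------------------------------------------------------------------------
# the five ratios
# --------------------------------------------------------------------------

def r_truth(auc_kernel: float, auc_baseline: float) -> float:
    """Ratio of ground-truth partial AUCs, kernel over baseline."""
    if auc_baseline <= 0:
        raise ValueError("baseline partial AUC must be positive")
    return float(auc_kernel) / float(auc_baseline)


def r_gray(activation: ActivationMap | np.ndarray, gray_mask: np.ndarray,
           baseline: ActivationMap | np.ndarray, fpr_max: float = 0.1) -> float:
    """Gray-matter overlap ratio: partial AUCs with in-gray as positives."""
    gray = np.asarray(gray_mask, dtype=bool).ravel()
    if gray.all() or not gray.any():
        raise ValueError("gray mask must contain both classes")
    num_curve = roc_curve(gray, _scores(activation))
    den_curve = roc_curve(gray, _scores(baseline))
    denominator = partial_auc(den_curve.fpr, den_curve.tpr, fpr_max)
    if denominator <= 0:
        raise ValueError("baseline gray-matter partial AUC must be positive")
    return partial_auc(num_curve.fpr, num_curve.tpr, fpr_max) / denominator


def r_shuffling(loss_kernel: float, loss_baseline: float) -> float:
    """Ratio of shuffle-robustness losses; > 1 means more robust than GLM."""
    if loss_baseline == 0:
        raise ValueError("baseline shuffling loss must be nonzero")
    return float(loss_kernel) / float(loss_baseline)


def r_roi(activation: ActivationMap, roi_mask: np.ndarray) -> float:
    """Sum of std-normalized activation over the region of interest."""
    roi = np.asarray(roi_mask, dtype=bool).ravel()
    alpha_std = activation.alpha_std  # raises on zero variance
    if roi.shape[0] != alpha_std.shape[0]:
        raise ValueError("ROI mask length does not match the activation map")
    return float(alpha_std[roi].sum())


def sphere_mask(geometry: VolumeGeometry, center_mm: np.ndarray,
                radius_mm: float = 6.0) -> np.ndarray:
    """Flat in-mask boolean vector for a sphere given in mm coordinates.

    ``center_mm`` is interpreted through the geometry's affine if present,
    else as mm offsets from the grid origin along each axis.
    """
    coords_vox = np.indices(geometry.shape).reshape(3, -1).T.astype(float)
    if geometry.affine is not None:
        homog = np.c_[coords_vox, np.ones(len(coords_vox))]
        coords_mm = (geometry.affine @ homog.T).T[:, :3]
    else:
        coords_mm = coords_vox * np.asarray(geometry.voxel_size_mm)
    d2 = ((coords_mm - np.asarray(center_mm, dtype=float)) ** 2).sum(axis=1)
    return (d2 <= radius_mm ** 2)[geometry.flat_indices]


# --------------------------------------------------------------------------
# eigendecomposition relevance
# --------------------------------------------------------------------------

def param_grid(kernel_name: str, grid_points: int) -> list[dict[str, float]]:
    """Uniform grid over the kernel's parameter box, endpoints excluded."""
    info = KERNEL_TABLE[kernel_name]
    axes = []
    for name, (lo, hi) in info.param_bounds.items():
        axes.append([(name, v) for v in
                     np.linspace(lo, hi, grid_points + 2)[1:-1]])
    if not axes:
        return [{}]
    return [dict(combo) for combo in itertools.product(*axes)]


def _max_abs_corr(eigvecs: np.ndarray, x_centered: np.ndarray) -> float:
    """Largest |Pearson correlation| between any eigenvector column and x."""
    t = eigvecs.shape[-2]
    num = np.abs(np.swapaxes(eigvecs, -1, -2) @ x_centered)
    means = eigvecs.mean(axis=-2)
    denom = np.sqrt(np.maximum((eigvecs ** 2).sum(axis=-2) - t * means ** 2,
                               1e-300))
    return float((num / denom).max())


def r_corr(data, xeff, kernel_name: str, grid_points: int = 200,
           batch: int = 256) -> float:
    """Maximum |corr(eigenvector, x_eff)| over a kernel-parameter grid.

    The full eigendecomposition of each Gram matrix is used (all
    eigenvectors, not only the leading ones).  For the odd-symmetric tanh
    family, negating every parameter flips the Gram's sign without changing
    its eigenvectors, so only one representative of each ±pair of grid
    points is evaluated — an exact halving, not an approximation.
    ``gamma`` is excluded from the grid.
    """
    workspace = data if isinstance(data, KernelWorkspace) else KernelWorkspace(
        getattr(data, "values", data))
    x = np.asarray(getattr(xeff, "values", xeff), dtype=float).ravel()
    if x.shape[0] != workspace.n_timepoints:
        raise ValueError("design length does not match the data's time axis")
    xc = x - x.mean()
    norm = np.linalg.norm(xc)
    if norm == 0:
        raise ValueError("effective design is constant")
    xc = xc / norm

    info = KERNEL_TABLE[kernel_name]
    grid = param_grid(kernel_name, grid_points)
    if info.odd:
        kept = []
        for params in grid:
            values = np.array(list(params.values()))
            first = values[values != 0]
            if first.size == 0 or first[0] > 0:
                kept.append(params)
        grid = kept

    best = 0.0
    for start in range(0, len(grid), batch):
        chunk = grid[start:start + batch]
        grams = np.stack([
            workspace.raw_gram(KernelSpec(kernel_name, params)) for params in chunk])
        _, eigvecs = np.linalg.eigh(grams)
        best = max(best, _max_abs_corr(eigvecs, xc))
    return best


# --------------------------------------------------------------------------
# neighbor distribution diagnostic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeighborHistogram:
    """2D histogram of (alpha_center, alpha_neighbor) pairs."""

    counts: np.ndarray
    edges: tuple[np.ndarray, np.ndarray]
    n_pairs: int

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _robust_edges(alpha: np.ndarray, bins: int, half_width: float = 4.0
                  ) -> np.ndarray:
    med = np.median(alpha)
    mad = np.median(np.abs(alpha - med))
    scale = 1.4826 * mad if mad > 0 else (alpha.std() or 1.0)
    return np.linspace(med - half_width * scale, med + half_width * scale,
                       bins + 1)


_FACE_NEIGHBORS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                            [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def neighbor_joint_hist(alpha: np.ndarray, geometry: VolumeGeometry,
                        n_pairs: int = 1_000_000, seed: int = 0,
                        bins: int = 64,
                        edges: np.ndarray | None = None) -> NeighborHistogram:
    """Sample face-neighbor pairs of in-mask voxels and bin their alphas.

    Each pair draws a uniformly random in-mask voxel with at least one
    in-mask face neighbor, then a uniformly random such neighbor.  Pass the
    same ``edges`` to histograms that will be compared.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.shape[0] != geometry.n_voxels:
        raise ValueError("alpha length does not match the brain mask")
    vol = np.full(geometry.shape, np.nan)
    vol[geometry.mask] = alpha

    centers = np.argwhere(geometry.mask)
    neighbor_ok = []
    for voxel in centers:
        options = voxel + _FACE_NEIGHBORS
        valid = ((options >= 0).all(axis=1)
                 & (options < np.array(geometry.shape)).all(axis=1))
        options = options[valid]
        inside = options[geometry.mask[tuple(options.T)]]
        neighbor_ok.append(inside)
    has_nb = np.array([len(n) > 0 for n in neighbor_ok])
    if not has_nb.any():
        raise ValueError("no in-mask voxel has an in-mask face neighbor")
    eligible = np.flatnonzero(has_nb)

    rng = np.random.default_rng(seed)
    picks = rng.integers(0, eligible.size, size=n_pairs)
    a1 = np.empty(n_pairs)
    a2 = np.empty(n_pairs)
    for k, pick in enumerate(picks):
        idx = eligible[pick]
        nbs = neighbor_ok[idx]
        nb = nbs[rng.integers(0, len(nbs))]
        a1[k] = vol[tuple(centers[idx])]
        a2[k] = vol[tuple(nb)]

    if edges is None:
        edges = _robust_edges(alpha, bins)
    a1 = np.clip(a1, edges[0], edges[-1])
    a2 = np.clip(a2, edges[0], edges[-1])
    counts, _, _ = np.histogram2d(a1, a2, bins=(edges, edges))
    return NeighborHistogram(counts=counts, edges=(edges, edges),
                             n_pairs=n_pairs)


def kl_divergence(p_shuffled: NeighborHistogram,
                  p_original: NeighborHistogram) -> float:
    """KL divergence of the shuffled from the original neighbor histogram.

    ``sum P_shuffle * log(P_shuffle / (P_ori + 1e-6))`` over normalized
    bins; empty shuffled bins contribute zero.  The epsilon guards against
    overflow on bins the original distribution never visits and introduces
    a small negative bias, so values slightly below zero are possible for
    near-identical histograms.
    """
    if (p_shuffled.edges[0].shape != p_original.edges[0].shape
            or not np.allclose(p_shuffled.edges[0], p_original.edges[0])
            or not np.allclose(p_shuffled.edges[1], p_original.edges[1])):
        raise ValueError("histograms use different binnings")
    ps = p_shuffled.probabilities
    po = p_original.probabilities
    mask = ps > 0
    return float(np.sum(ps[mask] * np.log(ps[mask] / (po[mask] + KL_EPSILON))))
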