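"""Benchmark data generation for activation-detection experiments.

The simulated datasets share one additive model: standardized noise plus a
task-locked signal of strength ``rho`` added to a known set of active
locations,

    Y = Y_noise + rho * Y_signal,   (Y_signal)_q = x_add if q in M else 0.

Three ingredients vary between benchmarks:

* the **effective design signal** ``x_eff`` — a single contrast-specific
  regressor combining the design matrix ``X`` and a contrast ``C``,
  ``x_eff = X (XᵀX)⁻¹ C [Cᵀ (XᵀX)⁻¹ C]⁻¹``;
* the **added signal** ``x_add`` — either a perturbed-contrast variant of
  ``x_eff`` (the "real signal differs from the hypothesis" assumption), a
  plain sinusoid (1D benchmark), or a data-driven resample of strongly
  task-correlated voxel series;
* the **noise** — i.i.d. Gaussian white noise for the 1D benchmark, or a
  synthetic spatio-temporally correlated volume (AR(1) in time, Gaussian
  spatial correlation) standing in for resampled resting-state fMRI.

``calibrate_rho`` implements the closed-loop signal-strength calibration that
adjusts ``rho`` until the GLM baseline's partial AUC (FPR < 0.1) falls in
[0.035, 0.05], so every simulated subject presents a comparable detection
difficulty to the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .geometry import VolumeGeometry

__all__ = [
    "DesignMatrix",
    "Contrast",
    "EffectiveDesign",
    "SimulatedDataset",
    "effective_design",
    "perturb_contrast",
    "canonical_hrf",
    "block_design",
    "simulate_1d",
    "synthetic_noise_volume",
    "simulate_volume",
    "blob_mask",
    "data_driven_xadd",
    "calibrate_rho",
    "CalibrationError",
    "standardize_columns",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """T x E matrix of HRF-convolved task regressors."""

    values: np.ndarray
    event_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(values)):
            raise ValueError("design matrix contains non-finite entries")
        t, e = values.shape
        if not (t > e >= 1):
            raise ValueError(f"need T > E >= 1, got T={t}, E={e}")
        if np.any(np.all(values == 0, axis=0)):
            raise ValueError("design matrix has an all-zero column")
        names = self.event_names or tuple(f"event{i}" for i in range(e))
        if len(names) != e:
            raise ValueError("event_names length does not match column count")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "event_names", tuple(names))

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_events(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Contrast:
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if not np.any(w != 0):
            raise ValueError("contrast must have at least one nonzero entry")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class EffectiveDesign:
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("effective design contains non-finite entries")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated time-by-location data with known ground truth."""

    data: np.ndarray
    mask: np.ndarray
    design: EffectiveDesign
    added_signal: np.ndarray
    rho: float
    noise_kind: str
    seed: int | None = None
    geometry: VolumeGeometry | None = None

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        mask = np.asarray(self.mask, dtype=bool).ravel()
        if mask.shape[0] != self.data.shape[1]:
            raise ValueError("mask length does not match voxel count")
        object.__setattr__(self, "mask", mask)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------

def standardize_columns(values: np.ndarray) -> np.ndarray:
    """Standardize each column to temporal mean 0, variance 1 (ddof=0)."""
    values = np.asarray(values, dtype=float)
    centered = values - values.mean(axis=0)
    sd = centered.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a zero-variance column")
    return centered / sd


def effective_design(design: DesignMatrix, contrast: Contrast) -> EffectiveDesign:
    """Combine a design matrix and a contrast into one regressor.

    Returns ``X (XᵀX)⁻¹ C [Cᵀ (XᵀX)⁻¹ C]⁻¹`` as a length-T vector.

    Raises
    ------
    ValueError
        If ``XᵀX`` is (numerically) singular, if the contrast length does
        not match the number of regressors, or if the scalar bracket
        ``Cᵀ(XᵀX)⁻¹C`` vanishes.
    """
    x = design.values
    c = contrast.weights
    if c.shape[0] != design.n_events:
        raise ValueError(
            f"contrast length {c.shape[0]} != number of regressors {design.n_events}")
    xtx = x.T @ x
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("XᵀX is singular or numerically rank deficient")
    xtx_inv_c = np.linalg.solve(xtx, c)
    bracket = float(c @ xtx_inv_c)
    if abs(bracket) < 1e-12:
        raise ValueError("contrast is orthogonal to the estimable space "
                         "(singular bracket Cᵀ(XᵀX)⁻¹C)")
    return EffectiveDesign(x @ xtx_inv_c / bracket)


def perturb_contrast(contrast: Contrast, scale: float, seed: int) -> Contrast:
    """Return ``C' = C + scale * z`` with ``z ~ N(0, I)``; seeded."""
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(contrast.weights.shape[0])
    return Contrast(contrast.weights + scale * z)


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``tr_s``.

    Peak at 6 s, undershoot at 16 s, undershoot ratio 1/6; peak normalized
    to 1.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, duration_s, tr_s)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    hrf = peak - undershoot / 6.0
    return hrf / hrf.max()


def block_design(n_timepoints: int, tr_s: float, onsets_s: dict[str, list[float]],
                 block_s: float) -> DesignMatrix:
    """HRF-convolved boxcar design: one column per event type."""
    hrf = canonical_hrf(tr_s)
    cols, names = [], []
    for name, onsets in onsets_s.items():
        box = np.zeros(n_timepoints)
        for onset in onsets:
            i0 = int(round(onset / tr_s))
            i1 = min(n_timepoints, i0 + max(1, int(round(block_s / tr_s))))
            box[i0:i1] = 1.0
        cols.append(np.convolve(box, hrf)[:n_timepoints])
        names.append(name)
    return DesignMatrix(np.column_stack(cols), tuple(names))


# --------------------------------------------------------------------------
# 1D benchmark
# --------------------------------------------------------------------------

def simulate_1d(T: int = 100, Q: int = 10_000, rho: float = 0.3,
                active_fraction: float = 0.1, seed: int = 0) -> SimulatedDataset:
    """The fully specified 1D benchmark.

    Gaussian white noise (columns standardized), a uniformly random 10% of
    locations active, effective design ``sin(t + phi)`` with ``t`` spanning
    [0, 2*pi] and a single phase draw ``phi ~ U(-pi/4, pi/4)`` per dataset,
    added signal ``sin(t)`` (unit amplitude, as defined — not re-standardized),
    no smoothing.
    """
    if not 0 < active_fraction < 1:
        raise ValueError("active_fraction must lie in (0, 1)")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2.0 * np.pi, T)
    phi = rng.uniform(-np.pi / 4, np.pi / 4)
    xeff = EffectiveDesign(np.sin(t + phi))
    x_add = np.sin(t)

    noise = standardize_columns(rng.standard_normal((T, Q)))
    n_active = int(math.floor(active_fraction * Q))
    mask = np.zeros(Q, dtype=bool)
    mask[rng.permutation(Q)[:n_active]] = True

    data = noise
    data[:, mask] += rho * x_add[:, None]
    return SimulatedDataset(data=data, mask=mask, design=xeff,
                            added_signal=x_add, rho=float(rho),
                            noise_kind="gaussian-white", seed=seed)


# --------------------------------------------------------------------------
# volumetric benchmark
# --------------------------------------------------------------------------

def synthetic_noise_volume(grid_shape, T: int, spatial_fwhm_mm: float = 6.0,
                           ar1_coeff: float = 0.3, seed: int = 0,
                           voxel_size_mm=(2.0, 2.0, 2.0)) -> np.ndarray:
    """Spatio-temporally correlated Gaussian noise on a 3D grid.

    Temporal AR(1) with coefficient ``ar1_coeff`` (stationary
    initialization), then per-frame Gaussian spatial smoothing with the given
    FWHM, then per-voxel standardization to temporal mean 0, variance 1.
    Returns a T x Q matrix over the full grid (C-order flattening).
    """
    if not 0 <= ar1_coeff < 1:
        raise ValueError("ar1_coeff must lie in [0, 1)")
    if spatial_fwhm_mm < 0:
        raise ValueError("spatial_fwhm_mm must be nonnegative")
    rng = np.random.default_rng(seed)
    shape = tuple(grid_shape)
    q = int(np.prod(shape))
    innovations = rng.standard_normal((T, q))
    series = np.empty((T, q))
    series[0] = innovations[0]
    scale = np.sqrt(1.0 - ar1_coeff ** 2)
    for i in range(1, T):
        series[i] = ar1_coeff * series[i - 1] + scale * innovations[i]
    if spatial_fwhm_mm > 0:
        sigma_vox = np.array([spatial_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
                              for v in voxel_size_mm])
        frames = series.reshape((T,) + shape)
        for i in range(T):
            frames[i] = ndimage.gaussian_filter(frames[i], sigma=sigma_vox)
        series = frames.reshape(T, q)
    return standardize_columns(series)


def simulate_volume(noise: np.ndarray, mask: np.ndarray, x_add: np.ndarray,
                    rho: float, design: EffectiveDesign | None = None,
                    geometry: VolumeGeometry | None = None,
                    seed: int | None = None) -> SimulatedDataset:
    """Assemble the additive model from explicit noise, mask and signal.

    ``x_add`` must be standardized (temporal mean 0, variance 1); columns of
    ``noise`` are assumed standardized already.
    """
    noise = np.asarray(noise, dtype=float)
    mask = np.asarray(mask, dtype=bool).ravel()
    x_add = np.asarray(x_add, dtype=float).ravel()
    if mask.shape[0] != noise.shape[1]:
        raise ValueError("mask length must equal the number of noise columns")
    if x_add.shape[0] != noise.shape[0]:
        raise ValueError("x_add length must equal the number of time points")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if abs(x_add.mean()) > 1e-8 or abs(x_add.std() - 1.0) > 1e-6:
        raise ValueError("x_add must be standardized to mean 0, variance 1")
    data = noise.copy()
    data[:, mask] += rho * x_add[:, None]
    if design is None:
        design = EffectiveDesign(x_add)
    return SimulatedDataset(data=data, mask=mask, design=design,
                            added_signal=x_add, rho=float(rho),
                            noise_kind="synthetic-volume", seed=seed,
                            geometry=geometry)


def blob_mask(geometry: VolumeGeometry, fraction: float = 0.1,
              seed: int = 0, n_blobs: int = 4) -> np.ndarray:
    """Union of random ellipsoidal blobs covering ``fraction`` of the brain.

    Blobs are grown inside the brain mask until the target count
    ``floor(fraction * Q)`` is reached, then trimmed deterministically (the
    voxels added last are removed first) so the count is exact.  Returns a
    flat boolean vector over in-mask voxels.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    target = int(math.floor(fraction * geometry.n_voxels))
    shape = np.array(geometry.shape)
    coords = np.indices(geometry.shape).reshape(3, -1).T
    in_brain = geometry.mask.ravel()
    chosen_order: list[np.ndarray] = []
    chosen = np.zeros(in_brain.shape[0], dtype=bool)
    mean_radius = max(2.0, (target / max(n_blobs, 1) * 3.0 / (4.0 * np.pi)) ** (1 / 3))
    while chosen[in_brain].sum() < target:
        center = rng.uniform(0, shape - 1)
        semi = rng.uniform(0.6, 1.6, size=3) * mean_radius
        d2 = (((coords - center) / semi) ** 2).sum(axis=1)
        new = (d2 <= 1.0) & in_brain & ~chosen
        order = np.flatnonzero(new)[np.argsort(d2[new], kind="stable")]
        chosen[order] = True
        chosen_order.append(order)
    overshoot = int(chosen[in_brain].sum()) - target
    if overshoot > 0:
        last = chosen_order[-1]
        chosen[last[len(last) - overshoot:]] = False
    return chosen[in_brain]


def data_driven_xadd(data: np.ndarray, xeff: EffectiveDesign,
                     top_fraction: float = 0.01, seed: int = 0) -> np.ndarray:
    """Added signal resampled from the most task-correlated voxels.

    The time series of the ``top_fraction`` most ``xeff``-correlated columns
    are averaged after a random circular time shuffle of their order across
    voxels, giving a signal that resembles measured responses rather than
    the hypothesized regressor.  The result is standardized.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    x = standardize_columns(xeff.values[:, None]).ravel()
    cols = standardize_columns(data)
    corr = cols.T @ x / len(x)
    k = max(1, int(math.floor(top_fraction * data.shape[1])))
    top = np.argsort(-corr, kind="stable")[:k]
    picked = cols[:, rng.permutation(top)]
    return standardize_columns(picked.mean(axis=1)[:, None]).ravel()


# --------------------------------------------------------------------------
# signal-strength calibration
# --------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    pass


def calibrate_rho(dataset_factory: Callable[[float], object],
                  evaluator: Callable[[object], float],
                  rho_init: float = 0.1,
                  auc_low: float = 0.035, auc_high: float = 0.05,
                  step: float = 0.005, max_iter: int = 200) -> float:
    """Adjust ``rho`` until the baseline partial AUC lands in the target band.

    ``evaluator(dataset_factory(rho))`` must return the baseline's partial
    AUC at FPR < 0.1.  ``rho`` moves up by ``step`` while the AUC is below
    ``auc_low`` and down while above ``auc_high``; iteration stops inside the
    band.
    """
    if rho_init <= 0:
        raise ValueError("rho_init must be positive")
    rho = float(rho_init)
    for _ in range(max_iter):
        auc = float(evaluator(dataset_factory(rho)))
        if auc < auc_low:
            rho += step
        elif auc > auc_high:
            rho -= step
        else:
            return rho
        if rho <= 0:
            raise CalibrationError("rho driven to a nonpositive value")
    raise CalibrationError(f"calibration did not converge in {max_iter} iterations")
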