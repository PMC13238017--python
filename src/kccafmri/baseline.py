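"""GLM + Gaussian-smoothing baseline and the permutation activation threshold.

The baseline activation is the Pearson correlation of each (Gaussian-
smoothed) voxel time series with the effective design signal — the
conventional single-regressor GLM read-out that every kernel method is
normalized against.  For the 1D benchmark no smoothing is applied.

The activation threshold is calibrated from a null distribution obtained by
permuting the canonical vector ``v_Y`` in time and recomputing alpha with
everything else frozen (for the GLM, the effective design is permuted
instead).  The threshold is the pooled (1 - target_rate) quantile of the
null activations, so the fraction of null values above it equals the target
false-activation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kcca import ActivationMap, CanonicalSolution, back_reconstruct_bc1
from .kernels import KernelMatrix
from .smoothing import FilterBank, SmoothedData, smooth
from .geometry import VolumeGeometry

__all__ = ["glm_gs", "NullDistribution", "null_threshold", "FrozenKcca",
           "glm_null_recompute"]

logger = logging.getLogger(__name__)


def glm_gs(data: np.ndarray, xeff, bank: FilterBank | None = None,
           geometry: VolumeGeometry | None = None) -> ActivationMap:
    """Per-voxel correlation of (smoothed) data with the effective design.

    ``bank`` should be the single Gaussian filter matched in FWHM to the
    steerable bank; pass ``None`` for the unsmoothed 1D benchmark.
    Zero-variance voxels receive alpha 0 (counted and logged).
    """
    x = np.asarray(getattr(xeff, "values", xeff), dtype=float).ravel()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] != x.shape[0]:
        raise ValueError("data time axis does not match the design length")
    if bank is not None and bank.count != 1:
        raise ValueError("the GLM baseline uses a single Gaussian filter")
    values = smooth(data, bank, geometry).values if bank is not None else data

    xc = x - x.mean()
    x_norm = np.linalg.norm(xc)
    if x_norm == 0:
        raise ValueError("effective design is constant")
    centered = values - values.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    flat = norms == 0
    if flat.any():
        logger.warning("%d zero-variance voxels set to alpha 0", int(flat.sum()))
    alpha = np.zeros(values.shape[1])
    good = ~flat
    alpha[good] = (centered[:, good].T @ xc) / (norms[good] * x_norm)
    return ActivationMap(alpha=alpha, method="glm")


@dataclass(frozen=True)
class NullDistribution:
    """Pooled null activations and the calibrated threshold."""

    alpha_null: np.ndarray  # n_draws x Q
    n_draws: int
    threshold: float
    target_rate: float

    @property
    def exceedance_rate(self) -> float:
        return float((self.alpha_null > self.threshold).mean())


@dataclass(frozen=True)
class FrozenKcca:
    """Everything held fixed while ``v_Y`` is permuted."""

    smoothed: SmoothedData
    ky: KernelMatrix
    sol: CanonicalSolution

    def alpha_from_vy(self, v_y: np.ndarray) -> np.ndarray:
        permuted_sol = CanonicalSolution(v_x=self.sol.v_x, v_y=v_y,
                                         r=self.sol.r, gamma=self.sol.gamma,
                                         s=self.sol.s)
        return back_reconstruct_bc1(self.smoothed, self.ky, permuted_sol).alpha


def glm_null_recompute(data: np.ndarray, bank: FilterBank | None = None,
                       geometry: VolumeGeometry | None = None
                       ) -> Callable[[np.ndarray], np.ndarray]:
    """Null recomputation for the GLM: permute the effective design."""
    def recompute(xeff_permuted: np.ndarray) -> np.ndarray:
        return glm_gs(data, xeff_permuted, bank, geometry).alpha
    return recompute


def null_threshold(state: FrozenKcca | Callable[[np.ndarray], np.ndarray],
                   base_vector: np.ndarray | None = None,
                   target_rate: float = 0.05, n_draws: int = 20,
                   seed: int = 0) -> NullDistribution:
    """Activation threshold from time-permuted canonical vectors.

    ``state`` is a :class:`FrozenKcca` (its ``v_Y`` is permuted) or any
    callable mapping a permuted vector to a null alpha (for the GLM,
    ``glm_null_recompute`` with the effective design as ``base_vector``).
    Null values are pooled over all draws and the threshold is set so their
    exceedance fraction equals ``target_rate``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    if not 0 < target_rate < 1:
        raise ValueError("target_rate must lie in (0, 1)")
    if isinstance(state, FrozenKcca):
        recompute = state.alpha_from_vy
        vector = state.sol.v_y
    else:
        recompute = state
        if base_vector is None:
            raise ValueError("a base vector is required with a callable state")
        vector = np.asarray(base_vector, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    draws = [np.asarray(recompute(vector[rng.permutation(vector.shape[0])]),
                        dtype=float).ravel()
             for _ in range(n_draws)]
    alpha_null = np.stack(draws)
    pooled = alpha_null.ravel()
    pooled = pooled[np.isfinite(pooled)]
    threshold = float(np.quantile(pooled, 1.0 - target_rate))
    return NullDistribution(alpha_null=alpha_null, n_draws=n_draws,
                            threshold=threshold, target_rate=target_rate)
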