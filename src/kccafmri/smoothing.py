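"""Spatial smoothing as an explicit linear map from voxels to features.

Smoothing is the linear transformation ``Y~ = Y A`` taking T x Q in-mask data
to T x P features, where ``A`` (Q x P) is realized by convolution with a
filter bank: a single Gaussian stencil (P = Q, the GLM baseline) or a bank of
seven steerable stencils (P = 7 Q, used by all kernel analyses).

The steerable bank's normative property is the *sum contract*: the equally
weighted (1/7) sum of the seven stencils equals the single Gaussian stencil
of the same FWHM.  The construction here decomposes the Gaussian into one
isotropic low-pass component plus six orientation-selective components built
from second-order directional derivatives along the six edge-diagonal
orientations (±x±y, ±x±z, ±y±z); the directional terms are mean-corrected so
the equal-weight sum telescopes back to the Gaussian exactly.  The
decomposition is an implementation choice and is swappable — only the count
and the sum contract are contractual.

Boundary convention: voxels outside the brain mask contribute zeros
(mask-then-smooth); stencils are truncated at 3 sigma per axis with odd
support and no renormalization at edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import VolumeGeometry

__all__ = [
    "FilterBank",
    "SmoothedData",
    "gaussian_filter",
    "steerable_bank",
    "identity_bank",
    "smooth",
    "pullback",
    "dense_transform",
    "fwhm_to_sigma",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return np.asarray([fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm])


@dataclass(frozen=True)
class FilterBank:
    """A list of 3D convolution stencils sharing one FWHM."""

    stencils: tuple[np.ndarray, ...]
    fwhm_mm: float
    voxel_size_mm: tuple[float, float, float]

    @property
    def count(self) -> int:
        return len(self.stencils)

    def summed(self) -> np.ndarray:
        """Equally weighted (1/count) sum of the stencils."""
        return sum(self.stencils) / self.count

    def as_stack(self) -> np.ndarray:
        """Stencils stacked along a trailing axis (for NIfTI export)."""
        return np.stack(self.stencils, axis=-1)


def _gaussian_stencil(sigma_vox: np.ndarray) -> np.ndarray:
    """Separable Gaussian stencil truncated at 3 sigma, odd support, sum 1."""
    axes = []
    for s in sigma_vox:
        half = max(1, int(np.ceil(3.0 * s)))
        x = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-0.5 * (x / s) ** 2)
        axes.append(g)
    stencil = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    return stencil / stencil.sum()


def gaussian_filter(fwhm_mm: float, voxel_size_mm=(2.0, 2.0, 2.0)) -> FilterBank:
    """Single isotropic Gaussian stencil with the given FWHM."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if any(v <= 0 for v in voxel_size_mm):
        raise ValueError("voxel size must be positive")
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    return FilterBank((_gaussian_stencil(sigma),), float(fwhm_mm),
                      tuple(float(v) for v in voxel_size_mm))


# Six edge-diagonal orientations; symmetric under coordinate permutation
# and sign flips.
_ORIENTATIONS = np.array([
    [1, 1, 0], [1, -1, 0],
    [1, 0, 1], [1, 0, -1],
    [0, 1, 1], [0, 1, -1],
], dtype=float) / np.sqrt(2.0)


def steerable_bank(fwhm_mm: float, voxel_size_mm=(2.0, 2.0, 2.0)) -> FilterBank:
    """Seven-stencil steerable bank whose 1/7-weighted sum is the Gaussian.

    Stencil 0 is the isotropic Gaussian itself; stencils 1..6 add
    mean-corrected second-order directional components of the Gaussian along
    the six edge-diagonal orientations, so orientation selectivity is gained
    while the sum contract holds to machine precision.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    g = _gaussian_stencil(sigma)
    half = [(n - 1) // 2 for n in g.shape]
    grids = np.meshgrid(*[np.arange(-h, h + 1, dtype=float) for h in half],
                        indexing="ij")
    # physical coordinates in units of sigma per axis
    coords = [grids[a] / sigma[a] for a in range(3)]

    # second directional derivative of the Gaussian along u (up to sign):
    # D_u(x) = g(x) * ((u.x/sigma)^2 - 1); even, zero-mean weighted by g.
    directional = []
    for u in _ORIENTATIONS:
        proj = u[0] * coords[0] + u[1] * coords[1] + u[2] * coords[2]
        directional.append(g * (proj ** 2 - 1.0))
    mean_dir = sum(directional) / len(directional)

    # scale keeps the oriented components comparable to the low-pass term
    scale = 0.5
    stencils = [g] + [g + scale * (d - mean_dir) for d in directional]
    return FilterBank(tuple(stencils), float(fwhm_mm),
                      tuple(float(v) for v in voxel_size_mm))


def identity_bank() -> FilterBank:
    """Single delta stencil: smoothing is the identity map (P = Q)."""
    delta = np.zeros((1, 1, 1))
    delta[0, 0, 0] = 1.0
    return FilterBank((delta,), 0.0, (1.0, 1.0, 1.0))


@dataclass(frozen=True)
class SmoothedData:
    """T x P feature matrix with the transform that produced it.

    ``bank is None`` (or geometry None) marks the identity transform used by
    the 1D benchmark, where features coincide with voxels (P = Q).
    Columns are filter-major: feature block k occupies columns
    [k*Q, (k+1)*Q).
    """

    values: np.ndarray
    bank: FilterBank | None = None
    geometry: VolumeGeometry | None = None

    @classmethod
    def identity(cls, values: np.ndarray) -> "SmoothedData":
        return cls(np.asarray(values, dtype=float))

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def pullback(self, w: np.ndarray) -> np.ndarray:
        """Apply the Q x P transform matrix A to a feature vector (P -> Q)."""
        if self.bank is None or self.geometry is None:
            return np.asarray(w, dtype=float)
        return pullback(np.asarray(w, dtype=float), self.bank, self.geometry)


def smooth(data: np.ndarray, bank: FilterBank,
           geometry: VolumeGeometry | None = None) -> SmoothedData:
    """Apply the filter bank to T x Q in-mask data: ``Y~ = Y A`` (T x P).

    Each time frame is scattered onto the grid (zeros outside the mask),
    convolved with each stencil, and gathered back within the mask.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if geometry is None:
        if bank.count == 1 and bank.stencils[0].size == 1:
            return SmoothedData.identity(data * bank.stencils[0].ravel()[0])
        raise ValueError("volumetric smoothing requires a geometry")
    if data.shape[1] != geometry.n_voxels:
        raise ValueError(
            f"data has {data.shape[1]} columns but the mask holds "
            f"{geometry.n_voxels} voxels")
    t = data.shape[0]
    q = geometry.n_voxels
    out = np.empty((t, bank.count * q))
    for i in range(t):
        vol = geometry.scatter(data[i])
        for k, stencil in enumerate(bank.stencils):
            sm = ndimage.convolve(vol, stencil, mode="constant", cval=0.0)
            out[i, k * q:(k + 1) * q] = geometry.gather(sm)
    return SmoothedData(out, bank, geometry)


def pullback(w: np.ndarray, bank: FilterBank, geometry: VolumeGeometry) -> np.ndarray:
    """Adjoint application: map a length-P feature vector to Q voxels.

    This is multiplication by A (Q x P): scatter each filter block, convolve
    with the flipped stencil, gather, and accumulate.
    """
    w = np.asarray(w, dtype=float)
    q = geometry.n_voxels
    if w.shape[-1] != bank.count * q:
        raise ValueError("feature vector length does not match bank * mask size")
    result = np.zeros(w.shape[:-1] + (q,))
    for k, stencil in enumerate(bank.stencils):
        flipped = stencil[::-1, ::-1, ::-1]
        block = w[..., k * q:(k + 1) * q]
        vol = geometry.scatter(block)
        sm = ndimage.convolve(vol, flipped, mode="constant", cval=0.0)
        result += geometry.gather(sm)
    return result


def dense_transform(bank: FilterBank, geometry: VolumeGeometry) -> np.ndarray:
    """Materialize A (Q x P) as a dense matrix.

    Exploits translation invariance: the contribution of source voxel j to
    target voxel j + d is the stencil weight at offset d, so A is assembled
    by one vectorized scatter per stencil offset.  Pipelines on small grids
    use it to turn repeated smoothing into one BLAS product; tests use the
    convolution path as its oracle.
    """
    q = geometry.n_voxels
    shape = np.array(geometry.shape)
    index_grid = np.full(geometry.shape, -1, dtype=np.int64)
    index_grid[geometry.mask] = np.arange(q)
    coords = np.argwhere(geometry.mask)
    a = np.zeros((q, bank.count * q))
    for k, stencil in enumerate(bank.stencils):
        center = [(n - 1) // 2 for n in stencil.shape]
        for offset in np.ndindex(stencil.shape):
            weight = stencil[offset]
            if weight == 0.0:
                continue
            d = np.array(offset) - center
            target = coords + d
            valid = np.all((target >= 0) & (target < shape), axis=1)
            target = target[valid]
            inside = geometry.mask[tuple(target.T)]
            src = np.flatnonzero(valid)[inside]
            dst = index_grid[tuple(target[inside].T)]
            a[src, k * q + dst] += weight
    return a
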