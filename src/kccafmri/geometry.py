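"""Voxel-grid bookkeeping shared by the volumetric modules.

A :class:`VolumeGeometry` fixes the 3D grid, the physical voxel size and the
brain mask, and provides the scatter/gather maps between flat in-mask voxel
vectors (length ``Q``) and 3D volumes.  Voxel indices are 0-based; the flat
ordering is ``np.flatnonzero(mask)`` (C order) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGeometry:
    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    mask: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(f"mask shape {mask.shape} != grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def full_grid(cls, shape, voxel_size_mm=(2.0, 2.0, 2.0)) -> "VolumeGeometry":
        return cls(tuple(shape), tuple(float(v) for v in voxel_size_mm),
                   np.ones(shape, dtype=bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())

    def scatter(self, values: np.ndarray) -> np.ndarray:
        """Place in-mask values (length Q) onto the 3D grid, zeros elsewhere."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError("value length does not match in-mask voxel count")
        vol = np.zeros(values.shape[:-1] + tuple(self.shape), dtype=values.dtype)
        vol[..., self.mask] = values
        return vol

    def gather(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask voxels of a volume as a flat vector."""
        volume = np.asarray(volume)
        if volume.shape[-3:] != tuple(self.shape):
            raise ValueError("volume shape does not match grid")
        return volume[..., self.mask]
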