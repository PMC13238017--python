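"""Regularized kernel canonical correlation and back-reconstruction.

The solver maximizes

    r = max  v_X' K_X K_Y v_Y / sqrt( v_X'(K_X^2 + g K_X)v_X
                                      * v_Y'(K_Y^2 + g K_Y)v_Y ),

the canonical correlation between the design and data representations in
kernel space with ridge-style regularization ``g`` on both sides.  With
``a = (K_X^2+gK_X)^{1/2} v_X`` and ``b = (K_Y^2+gK_Y)^{1/2} v_Y`` the problem
becomes the leading singular triple of
``(K_X^2+gK_X)^{-1/2} K_X K_Y (K_Y^2+gK_Y)^{-1/2}``.

Nonlinear Grams (tanh family) are indefinite, so ``K^2 + gK`` can have
nonpositive eigenvalues; the ratio is only real on the positive-variance
subspace.  The spectral square roots therefore *truncate* (pseudo-inverse
convention) rather than floor: directions with eigenvalue below
``1e-10 * max`` are excluded from the maximization.

Two maps carry the kernel-space solution back to a per-voxel activation
pattern alpha, both derived from the identification ``Y alpha = s K_Y v_Y``
with ``s`` the sign of ``corr(x_eff, K_Y v_Y)``:

* BC1 (pseudo-inverse identity):  alpha = s A Y~'(Y~ Y~')^+ K_Y v_Y
* BC2 (sensitivity / heat map):   alpha = s sum_t1,t2 dK_t1t2/dY_t1 (v_Y)_t2

For the linear kernel both reduce to ``A A' Y' v_Y`` up to a positive scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .kernels import KernelMatrix, KernelSpec, KernelWorkspace, gradient_weights
from .smoothing import SmoothedData

__all__ = [
    "CanonicalSolution",
    "ActivationMap",
    "solve_kcca",
    "activation_sign",
    "back_reconstruct_bc1",
    "back_reconstruct_bc2",
]

logger = logging.getLogger(__name__)

_TRUNC_RTOL = 1e-10


@dataclass(frozen=True)
class CanonicalSolution:
    """Leading canonical pair in kernel space."""

    v_x: np.ndarray
    v_y: np.ndarray
    r: float
    gamma: float
    s: int = 1

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.v_x)) and np.all(np.isfinite(self.v_y))):
            raise ValueError("canonical vectors contain non-finite entries")
        if not np.any(self.v_x != 0) and not np.any(self.v_y != 0):
            raise ValueError("canonical vectors are both zero")
        if not -1e-8 <= self.r <= 1 + 1e-8:
            raise ValueError(f"canonical correlation r={self.r} outside [0, 1]")
        if self.s not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


@dataclass(frozen=True)
class ActivationMap:
    """Per-voxel signed activation values."""

    alpha: np.ndarray
    method: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float).ravel()
        if not np.all(np.isfinite(a)):
            raise ValueError("activation map contains non-finite values")
        object.__setattr__(self, "alpha", a)

    @property
    def alpha_std(self) -> np.ndarray:
        """alpha normalized by its standard deviation."""
        sd = self.alpha.std()
        if sd == 0:
            raise ValueError("activation map has zero variance")
        return self.alpha / sd

    def with_labels(self, labels: np.ndarray) -> "ActivationMap":
        return replace(self, labels=np.asarray(labels, dtype=bool))


def _inv_sqrt(matrix: np.ndarray) -> np.ndarray:
    """Truncated inverse square root of a symmetric matrix."""
    w, u = np.linalg.eigh(matrix)
    keep = w > _TRUNC_RTOL * np.abs(w).max()
    if not np.any(keep):
        raise np.linalg.LinAlgError("regularized Gram has no positive spectrum")
    return (u[:, keep] / np.sqrt(w[keep])) @ u[:, keep].T


def solve_kcca(kx: KernelMatrix, ky: KernelMatrix, gamma: float) -> CanonicalSolution:
    """Leading canonical pair of the regularized kernel CCA problem.

    Deterministic: the leading singular triple is used (exact ties resolved
    by LAPACK ordering, first index); the joint sign of the pair is fixed so
    the largest-magnitude entry of ``K_Y v_Y`` is positive.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a, b = kx.values, ky.values
    if a.shape != b.shape:
        raise ValueError("kernel matrices must have identical shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    left = _inv_sqrt(a @ a + gamma * a)
    right = _inv_sqrt(b @ b + gamma * b)
    u, sv, vt = np.linalg.svd(left @ a @ b @ right)
    v_x = left @ u[:, 0]
    v_y = right @ vt[0]
    ky_vy = b @ v_y
    pivot = np.argmax(np.abs(ky_vy))
    if ky_vy[pivot] < 0:
        v_x, v_y = -v_x, -v_y
    return CanonicalSolution(v_x=v_x, v_y=v_y, r=float(min(sv[0], 1.0 + 1e-8)),
                             gamma=float(gamma))


def activation_sign(xeff, ky: KernelMatrix, v_y: np.ndarray) -> int:
    """Sign of the correlation between the design and ``K_Y v_Y``.

    A zero-variance ``K_Y v_Y`` yields +1 with a logged warning.
    """
    x = np.asarray(getattr(xeff, "values", xeff), dtype=float).ravel()
    projected = ky.values @ np.asarray(v_y, dtype=float).ravel()
    if projected.std() == 0 or x.std() == 0:
        logger.warning("constant K_Y v_Y (or design); defaulting sign to +1")
        return 1
    c = np.corrcoef(x, projected)[0, 1]
    return -1 if c < 0 else 1


def back_reconstruct_bc1(smoothed: SmoothedData, ky: KernelMatrix,
                         sol: CanonicalSolution,
                         feature_eig: tuple[np.ndarray, np.ndarray] | None = None
                         ) -> ActivationMap:
    """Pseudo-inverse back-reconstruction (BC1).

    ``alpha = s A Y~' (Y~ Y~')^+ K_Y v_Y``; the T x T matrix ``Y~ Y~'`` is
    pseudo-inverted with singular values below ``1e-10 * max`` truncated.
    ``feature_eig`` may carry a precomputed ``eigh(Y~ Y~')`` (performance
    hook for pipelines that reuse one data matrix across many kernels).
    """
    feats = smoothed.values
    if feature_eig is not None:
        w, u = feature_eig
    else:
        w, u = np.linalg.eigh(feats @ feats.T)
    wmax = np.abs(w).max()
    if wmax == 0:
        raise np.linalg.LinAlgError("feature Gram Y~ Y~' is identically zero")
    inv_w = np.where(w > 1e-10 * wmax, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    target = ky.values @ sol.v_y
    z = (u * inv_w) @ (u.T @ target)
    alpha = sol.s * smoothed.pullback(feats.T @ z)
    return ActivationMap(alpha=alpha, method="bc1")


def back_reconstruct_bc2(smoothed: SmoothedData, spec: KernelSpec,
                         sol: CanonicalSolution,
                         workspace: KernelWorkspace | None = None) -> ActivationMap:
    """Sensitivity-map back-reconstruction (BC2).

    Differentiates each Gram entry with respect to the feature row of its
    first time index, holding ``v_Y`` and all normalization constants fixed,
    and pulls the resulting feature-space vector back to voxel space through
    the smoothing adjoint:

        alpha_feat = sum_i,j v_j [ dK_ij/dL_ij * dL_ij/dY~_i
                                   + dK_ij/dD_ij * dD_ij/dY~_i ]

    which collapses to ``Y~' c`` for a T-vector ``c`` (O(T^2 + TP)).
    """
    feats = smoothed.values
    if workspace is None:
        workspace = KernelWorkspace(feats)
    v = np.asarray(sol.v_y, dtype=float).ravel()
    d_l, d_d = gradient_weights(workspace, spec)

    # linear-statistic term: sum_ij d_l[i,j] v[j] * Y~_j / m_L, with the
    # diagonal picking up an extra Y~_i (d/dY_i of Y_i.Y_i is 2 Y_i)
    coeff = (d_l * v[None, :]).sum(axis=0)
    coeff = coeff + np.diag(d_l) * v
    # distance term: sum_ij d_d[i,j] v[j] * 2 (Y~_i - Y~_j) / m_D
    row = d_d @ v
    col = d_d.sum(axis=0) * v
    c = coeff / workspace.m_linear + 2.0 * (row - col) / workspace.m_distance
    alpha = sol.s * smoothed.pullback(feats.T @ c)
    return ActivationMap(alpha=alpha, method="bc2")
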