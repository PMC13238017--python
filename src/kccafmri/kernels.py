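"""Kernel mappings from smoothed data to T x T Gram matrices.

Every kernel is an elementwise function of two pre-normalized statistics of
the feature rows ``Y~_i`` (the smoothed data at time i):

* the linear Gram ``L_ij = Y~_i . Y~_j / m_L`` and
* the squared distance ``D_ij = ||Y~_i - Y~_j||^2 / m_D``,

where ``m_L`` and ``m_D`` are the mean absolute values of the raw statistics
(pre-normalization, keeping data ranges comparable across subjects).  After
the elementwise mapping the Gram is renormalized once more to mean absolute
entry 1 (post-normalization); both steps are pure rescalings.  No Gram
centering is performed: centering cannot remove the large diagonal produced
by noise self-correlation, which is the failure mode the bounded kernels
address by saturating large entries.

The regularization parameter ``gamma`` travels with the kernel spec but is
consumed only by the canonical-correlation solver, never by the Gram
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .smoothing import SmoothedData

__all__ = [
    "KernelSpec",
    "KernelMatrix",
    "KernelWorkspace",
    "KERNEL_TABLE",
    "GAMMA_BOUNDS",
    "build_kernel",
    "design_gram",
    "normalize_gram",
    "kernel_gradient",
    "gradient_weights",
]

GAMMA_BOUNDS = (0.1, 1.0e4)


@dataclass(frozen=True)
class KernelInfo:
    """Parameter bounds (open intervals) and optimization budget."""

    param_bounds: dict[str, tuple[float, float]]
    budget: int
    uses_linear: bool
    uses_distance: bool
    odd: bool  # K(-params) == -K(params), eigenvectors unchanged


KERNEL_TABLE: dict[str, KernelInfo] = {
    "linear": KernelInfo({}, 15, True, False, False),
    "parabolic": KernelInfo({"b2": (0.0, 1.0)}, 30, True, False, False),
    "gaussian": KernelInfo({"sigma2": (0.1, 10.0)}, 30, False, True, False),
    "inverse": KernelInfo({"b2": (0.1, 1.0)}, 30, False, True, False),
    "bounded_linear": KernelInfo({"C": (0.1, 10.0)}, 30, True, False, False),
    "square": KernelInfo({}, 15, False, True, False),
    "tanh": KernelInfo({"b": (-1.0, 1.0), "c": (-1.0, 1.0)}, 60, True, False, True),
    "mixed_tanh": KernelInfo({"b1": (-1.0, 1.0), "b2": (-1.0, 1.0),
                              "c": (-1.0, 1.0)}, 200, True, True, True),
    # one-parameter bounded kernel used by the eigendecomposition metric;
    # budget matches the other one-parameter-plus-gamma kernels
    "reduced_tanh": KernelInfo({"b": (-1.0, 1.0)}, 30, True, False, True),
}

# kernels whose optimization starts from the linear solution
LINEAR_INIT_KERNELS = ("bounded_linear", "tanh", "mixed_tanh")


@dataclass(frozen=True)
class KernelSpec:
    """A named kernel mapping with bounded parameters.

    ``params`` holds the kernel's own parameters; ``gamma`` is the
    regularization strength of the correlation solver.
    """

    name: str
    params: dict[str, float] = field(default_factory=dict)
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in KERNEL_TABLE:
            raise ValueError(f"unknown kernel {self.name!r}; "
                             f"choose from {sorted(KERNEL_TABLE)}")
        info = KERNEL_TABLE[self.name]
        missing = set(info.param_bounds) - set(self.params)
        extra = set(self.params) - set(info.param_bounds)
        if missing or extra:
            raise ValueError(f"kernel {self.name!r} expects parameters "
                             f"{sorted(info.param_bounds)}, got {sorted(self.params)}")
        for key, value in self.params.items():
            lo, hi = info.param_bounds[key]
            if not lo < value < hi:
                raise ValueError(
                    f"parameter {key}={value} outside open interval ({lo}, {hi})")
        if not GAMMA_BOUNDS[0] <= self.gamma <= GAMMA_BOUNDS[1]:
            raise ValueError(f"gamma={self.gamma} outside {GAMMA_BOUNDS}")
        object.__setattr__(self, "params", dict(self.params))

    @property
    def info(self) -> KernelInfo:
        return KERNEL_TABLE[self.name]

    @property
    def budget(self) -> int:
        return self.info.budget

    def with_gamma(self, gamma: float) -> "KernelSpec":
        return replace(self, gamma=float(gamma))

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params),
                "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(d["name"], dict(d.get("params", {})), float(d.get("gamma", 1.0)))


@dataclass(frozen=True)
class KernelMatrix:
    """T x T symmetric Gram matrix with its generating spec."""

    values: np.ndarray
    spec: KernelSpec | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Gram matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("Gram matrix contains non-finite entries")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("Gram matrix is not symmetric")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return self.values.shape[0]


class KernelWorkspace:
    """Pre-normalized statistics of one feature matrix.

    Computing the raw linear Gram and squared-distance matrix costs
    O(T^2 P); every kernel evaluation afterwards is an O(T^2) elementwise
    map.  Pipelines that evaluate many parameter settings on the same data
    build one workspace and reuse it.
    """

    def __init__(self, features: np.ndarray):
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if not np.all(np.isfinite(features)):
            raise ValueError("features contain non-finite entries")
        gram = features @ features.T
        gram = 0.5 * (gram + gram.T)
        sq = np.einsum("ij,ij->i", features, features)
        dist = sq[:, None] + sq[None, :] - 2.0 * gram
        np.fill_diagonal(dist, 0.0)
        dist = np.maximum(0.5 * (dist + dist.T), 0.0)
        self.m_linear = float(np.abs(gram).mean())
        # degenerate identical-row data: keep the (all-zero) distances usable
        self.m_distance = float(np.abs(dist).mean()) or 1.0
        if self.m_linear == 0.0:
            raise ValueError("all-zero feature matrix")
        self.linear = gram / self.m_linear
        self.distance = dist / self.m_distance
        self.n_timepoints = gram.shape[0]

    @classmethod
    def from_smoothed(cls, smoothed: SmoothedData) -> "KernelWorkspace":
        return cls(smoothed.values)

    # -- elementwise mappings ------------------------------------------------

    def raw_gram(self, spec: KernelSpec) -> np.ndarray:
        """Mapped Gram before post-normalization."""
        L, D, p = self.linear, self.distance, spec.params
        name = spec.name
        if name == "linear":
            return L.copy()
        if name == "parabolic":
            return (L + p["b2"]) ** 2
        if name == "gaussian":
            return np.exp(-D / p["sigma2"])
        if name == "inverse":
            return 1.0 / np.sqrt(D + p["b2"])
        if name == "bounded_linear":
            return np.minimum(p["C"], L)
        if name == "square":
            return D.copy()
        if name == "tanh":
            return np.tanh(p["b"] * L + p["c"])
        if name == "mixed_tanh":
            return np.tanh(p["b1"] * L + p["b2"] * D + p["c"])
        if name == "reduced_tanh":
            return np.tanh(p["b"] * L)
        raise ValueError(f"unknown kernel {name!r}")  # pragma: no cover

    def gram(self, spec: KernelSpec) -> KernelMatrix:
        """Mapped and post-normalized Gram matrix."""
        raw = self.raw_gram(spec)
        m = np.abs(raw).mean()
        if m == 0.0:
            raise ValueError(f"kernel {spec.name!r} produced an all-zero Gram")
        return KernelMatrix(raw / m, spec=spec, normalized=True)

    def post_norm(self, spec: KernelSpec) -> float:
        """The post-normalization constant m_K = mean|raw Gram|."""
        return float(np.abs(self.raw_gram(spec)).mean())


def build_kernel(data: SmoothedData | np.ndarray, spec: KernelSpec) -> KernelMatrix:
    """Construct the normalized Gram matrix of ``data`` under ``spec``."""
    if isinstance(data, SmoothedData):
        workspace = KernelWorkspace.from_smoothed(data)
    elif isinstance(data, KernelWorkspace):
        workspace = data
    else:
        workspace = KernelWorkspace(data)
    return workspace.gram(spec)


def design_gram(xeff) -> KernelMatrix:
    """Rank-1 linear Gram of the effective design: ``K_X = x x^T``.

    The design side stays linear; nonlinearity is applied to the data side
    only.
    """
    x = np.asarray(getattr(xeff, "values", xeff), dtype=float).ravel()
    if not np.any(x != 0):
        raise ValueError("effective design is the zero vector")
    return KernelMatrix(np.outer(x, x))


def normalize_gram(k: KernelMatrix) -> KernelMatrix:
    """Rescale so the mean absolute entry is exactly 1."""
    m = np.abs(k.values).mean()
    if m == 0.0:
        raise ValueError("cannot normalize an all-zero Gram matrix")
    return KernelMatrix(k.values / m, spec=k.spec, normalized=True)


# --------------------------------------------------------------------------
# analytic gradients (for the sensitivity-map back-reconstruction)
# --------------------------------------------------------------------------

def gradient_weights(workspace: KernelWorkspace,
                     spec: KernelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise derivative factors of the normalized Gram.

    Returns ``(dK/dL, dK/dD)`` as T x T arrays: the partial derivatives of
    the post-normalized kernel value with respect to the pre-normalized
    statistics L and D.  All normalization constants are treated as fixed.
    For the bounded-linear kink the linear branch applies at and below C
    (subgradient convention).
    """
    L, D, p = workspace.linear, workspace.distance, spec.params
    name = spec.name
    t = workspace.n_timepoints
    zeros = np.zeros((t, t))
    if name == "linear":
        d_l, d_d = np.ones((t, t)), zeros
    elif name == "parabolic":
        d_l, d_d = 2.0 * (L + p["b2"]), zeros
    elif name == "gaussian":
        d_l, d_d = zeros, -np.exp(-D / p["sigma2"]) / p["sigma2"]
    elif name == "inverse":
        d_l, d_d = zeros, -0.5 * (D + p["b2"]) ** (-1.5)
    elif name == "bounded_linear":
        d_l, d_d = np.where(L <= p["C"], 1.0, 0.0), zeros
    elif name == "square":
        d_l, d_d = zeros, np.ones((t, t))
    elif name == "tanh":
        sech2 = 1.0 - np.tanh(p["b"] * L + p["c"]) ** 2
        d_l, d_d = p["b"] * sech2, zeros
    elif name == "mixed_tanh":
        sech2 = 1.0 - np.tanh(p["b1"] * L + p["b2"] * D + p["c"]) ** 2
        d_l, d_d = p["b1"] * sech2, p["b2"] * sech2
    elif name == "reduced_tanh":
        sech2 = 1.0 - np.tanh(p["b"] * L) ** 2
        d_l, d_d = p["b"] * sech2, zeros
    else:  # pragma: no cover
        raise ValueError(f"unknown kernel {name!r}")
    m_k = workspace.post_norm(spec)
    return d_l / m_k, d_d / m_k


def kernel_gradient(data: SmoothedData | KernelWorkspace | np.ndarray,
                    spec: KernelSpec, i: int, j: int,
                    features: np.ndarray | None = None) -> np.ndarray:
    """Gradient of the normalized Gram entry (i, j) with respect to row i.

    Returns ``d(K_Y)_ij / d(Y~_i)`` as a length-P vector, with the
    pre/post-normalization constants held fixed.  Distance-based kernels
    have zero gradient on the diagonal (the distance of a row to itself
    stays zero); linear-statistic kernels pick up the factor 2 there.
    """
    if isinstance(data, KernelWorkspace):
        workspace = data
        if features is None:
            raise ValueError("pass the feature matrix alongside a workspace")
    else:
        features = data.values if isinstance(data, SmoothedData) else np.asarray(data)
        workspace = KernelWorkspace(features)
    features = np.atleast_2d(np.asarray(features, dtype=float))
    d_l, d_d = gradient_weights(workspace, spec)
    if i == j:
        grad_l = 2.0 * features[i] / workspace.m_linear
        grad_d = np.zeros(features.shape[1])
    else:
        grad_l = features[j] / workspace.m_linear
        grad_d = 2.0 * (features[i] - features[j]) / workspace.m_distance
    return d_l[i, j] * grad_l + d_d[i, j] * grad_d
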