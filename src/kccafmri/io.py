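"""Readers, writers, run configuration and the orchestrated pipeline.

Volumes travel as NIfTI (4D data, 3D masks and activation maps), 1D data
and designs as TSV, and every numeric artifact gets a JSON sidecar carrying
the kernel spec, seeds and a hash of the run configuration, so any output
can be traced back to the exact run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .baseline import FrozenKcca, null_threshold
from .geometry import VolumeGeometry
from .kcca import ActivationMap
from .kernels import KernelSpec
from .metrics import r_shuffling, r_truth
from .pipelines import Benchmark1DPipeline, VolumePipeline
from .selfsup import label_top_fraction, optimize_kernel_params
from .simulate import SimulatedDataset, simulate_1d
from .smoothing import steerable_bank

__all__ = [
    "load_fmri",
    "write_volume",
    "write_activation",
    "load_activation",
    "write_dataset_1d",
    "load_dataset_1d",
    "RunConfig",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# NIfTI / TSV round trips
# --------------------------------------------------------------------------

def _highpass(data: np.ndarray, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine high-pass: remove drifts slower than ``cutoff_hz``."""
    t = data.shape[0]
    n_basis = int(np.floor(2.0 * t * tr_s * cutoff_hz))
    if n_basis < 1:
        return data
    grid = np.arange(t)
    basis = np.column_stack([np.ones(t)] + [
        np.cos(np.pi * k * (2 * grid + 1) / (2 * t)) for k in range(1, n_basis + 1)])
    coeffs, *_ = np.linalg.lstsq(basis, data, rcond=None)
    return data - basis @ coeffs


def load_fmri(path, mask_path=None, highpass: bool = False,
              cutoff_hz: float = 1.0 / 120.0,
              standardize: bool = True) -> tuple[np.ndarray, VolumeGeometry]:
    """Load a 4D NIfTI as a T x Q in-mask matrix plus its geometry.

    Optional high-pass filtering (default cutoff 1/120 Hz) uses the TR from
    the NIfTI header; per-voxel standardization to temporal mean 0 and
    variance 1 is applied last.  Voxels with zero variance inside the mask
    are rejected.
    """
    img = nib.load(str(path))
    volume = np.asarray(img.get_fdata(), dtype=float)
    if volume.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI, got {volume.ndim}D")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if mask_path is not None:
        mask_img = nib.load(str(mask_path))
        if mask_img.shape != volume.shape[:3]:
            raise ValueError("mask grid does not match the data grid")
        if not np.allclose(mask_img.affine, img.affine, atol=1e-4):
            raise ValueError("mask affine does not match the data affine "
                             "(no silent resampling)")
        mask = np.asarray(mask_img.get_fdata()) > 0.5
    else:
        mask = np.ones(volume.shape[:3], dtype=bool)
    geometry = VolumeGeometry(volume.shape[:3], voxel_size, mask,
                              affine=np.asarray(img.affine))
    data = volume[mask].T  # T x Q
    if highpass:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
        if tr is None:
            raise ValueError("high-pass filtering requires TR metadata")
        data = _highpass(data, tr, cutoff_hz)
    if standardize:
        centered = data - data.mean(axis=0)
        sd = centered.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("mask contains zero-variance voxels")
        data = centered / sd
    return data, geometry


def _affine(geometry: VolumeGeometry) -> np.ndarray:
    if geometry.affine is not None:
        return geometry.affine
    return np.diag(list(geometry.voxel_size_mm) + [1.0])


def write_volume(path, values: np.ndarray, geometry: VolumeGeometry) -> None:
    """Write flat in-mask values (Q or T x Q) as a 3D/4D NIfTI."""
    values = np.asarray(values, dtype=float)
    vol = geometry.scatter(values)
    if vol.ndim == 4:  # T x X x Y x Z -> X x Y x Z x T
        vol = np.moveaxis(vol, 0, -1)
    img = nib.Nifti1Image(vol, _affine(geometry))
    img.header.set_zooms(tuple(geometry.voxel_size_mm) + (1.0,) * (vol.ndim - 3))
    nib.save(img, str(path))


def _sidecar(path: Path, payload: dict) -> None:
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def write_activation(path, amap: ActivationMap,
                     geometry: VolumeGeometry | None = None,
                     meta: dict | None = None) -> None:
    """Write an activation map as NIfTI (volumetric) or TSV (1D)."""
    path = Path(path)
    if geometry is not None:
        write_volume(path, amap.alpha, geometry)
    else:
        frame = pd.DataFrame({"voxel": np.arange(amap.alpha.size),
                              "alpha": amap.alpha})
        if amap.labels is not None:
            frame["label"] = amap.labels.astype(int)
        frame.to_csv(path, sep="\t", index=False)
    _sidecar(path, {"method": amap.method, **(meta or {})})


def load_activation(path) -> ActivationMap:
    """Read back a TSV activation map."""
    frame = pd.read_csv(path, sep="\t")
    meta_path = Path(path).with_suffix(Path(path).suffix + ".json")
    method = "bc1"
    if meta_path.exists():
        method = json.loads(meta_path.read_text()).get("method", "bc1")
    labels = frame["label"].to_numpy(bool) if "label" in frame else None
    return ActivationMap(frame["alpha"].to_numpy(), method=method, labels=labels)


def write_dataset_1d(path, dataset: SimulatedDataset) -> None:
    """Write a 1D benchmark dataset as TSV (+ JSON sidecar with rho, seed)."""
    path = Path(path)
    frame = pd.DataFrame(dataset.data)
    frame.insert(0, "xeff", np.r_[dataset.design.values])
    frame.to_csv(path, sep="\t", index=False)
    _sidecar(path, {"rho": dataset.rho, "seed": dataset.seed,
                    "noise_kind": dataset.noise_kind,
                    "mask": np.flatnonzero(dataset.mask),
                    "added_signal": dataset.added_signal})


def load_dataset_1d(path) -> SimulatedDataset:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = frame.drop(columns=["xeff"]).to_numpy(float)
    mask = np.zeros(data.shape[1], dtype=bool)
    mask[np.asarray(meta["mask"], dtype=int)] = True
    from .simulate import EffectiveDesign
    return SimulatedDataset(
        data=data, mask=mask, design=EffectiveDesign(frame["xeff"].to_numpy()),
        added_signal=np.asarray(meta["added_signal"], dtype=float),
        rho=float(meta["rho"]), noise_kind=meta["noise_kind"],
        seed=meta.get("seed"))


# --------------------------------------------------------------------------
# run configuration and orchestration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one subject-level run."""

    kernel: str = "mixed_tanh"
    seed: int = 0
    benchmark: str = "1d"           # "1d" or a path to a 4D NIfTI
    mask_path: str | None = None
    design_path: str | None = None  # TSV of HRF-convolved regressors
    contrast: tuple[float, ...] | None = None
    back_reconstruction: str = "bc1"
    fwhm_mm: float = 4.0
    activation_fraction: float = 0.10
    fpr_max: float = 0.1
    target_rate: float = 0.05
    n_null_draws: int = 20
    rho: float = 0.3
    n_timepoints: int = 100
    n_voxels: int = 10_000
    output_dir: str = "kcca_run"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _build_pipeline(config: RunConfig):
    if config.benchmark == "1d":
        dataset = simulate_1d(config.n_timepoints, config.n_voxels,
                              config.rho, config.activation_fraction,
                              seed=config.seed)
        pipeline = Benchmark1DPipeline(dataset,
                                       method=config.back_reconstruction,
                                       seed=config.seed)
        return pipeline, dataset, None
    data, geometry = load_fmri(config.benchmark, config.mask_path)
    if config.design_path is None or config.contrast is None:
        raise ValueError("volumetric runs need design_path and contrast")
    from .simulate import Contrast, DesignMatrix, effective_design
    design = DesignMatrix(pd.read_csv(config.design_path, sep="\t").to_numpy(float))
    xeff = effective_design(design, Contrast(np.asarray(config.contrast)))
    bank = steerable_bank(config.fwhm_mm, geometry.voxel_size_mm)
    pipeline = VolumePipeline(data, geometry, bank, xeff=xeff,
                              method=config.back_reconstruction)
    return pipeline, None, geometry


def run_pipeline(config: RunConfig) -> dict:
    """Simulate/load, optimize, back-reconstruct, score and write artifacts.

    Returns the result bundle as a dict (also serialized to
    ``output_dir/results.json``); all numeric outputs are deterministic
    functions of the configuration.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pipeline, dataset, geometry = _build_pipeline(config)

    gamma_init = None
    if config.kernel != "linear":
        linear_trace = optimize_kernel_params(pipeline.loss, "linear",
                                              seed=config.seed)
        gamma_init = linear_trace.best_params.gamma
    trace = optimize_kernel_params(pipeline.loss, config.kernel,
                                   seed=config.seed, gamma_init=gamma_init)
    best = trace.best_params
    amap = pipeline.activation_map(best)
    labels = label_top_fraction(amap.alpha, config.activation_fraction)
    amap = amap.with_labels(labels)
    baseline_map = pipeline.baseline()

    from .metrics import partial_auc, roc_curve
    results: dict = {
        "config_hash": config.config_hash,
        "version": __version__,
        "kernel": best.to_dict(),
        "best_loss": trace.best_loss,
        "n_evaluations": len(trace),
        "r_shuffling_like": r_shuffling(trace.best_loss,
                                        pipeline.loss(KernelSpec("linear", gamma=best.gamma)))
        if config.kernel != "linear" else 1.0,
    }
    if dataset is not None:
        curve = roc_curve(dataset.mask, amap.alpha)
        base_curve = roc_curve(dataset.mask, baseline_map.alpha)
        results["partial_auc"] = partial_auc(curve.fpr, curve.tpr, config.fpr_max)
        results["baseline_partial_auc"] = partial_auc(base_curve.fpr,
                                                      base_curve.tpr,
                                                      config.fpr_max)
        results["r_truth"] = r_truth(results["partial_auc"],
                                     results["baseline_partial_auc"])

    ky, sol = pipeline.solution(best)
    null = null_threshold(FrozenKcca(pipeline._original.smoothed, ky, sol),
                          target_rate=config.target_rate,
                          n_draws=config.n_null_draws, seed=config.seed)
    results["activation_threshold"] = null.threshold
    results["canonical_r"] = sol.r

    meta = {"config": json.loads(config.to_json()), "seeds": {"main": config.seed}}
    write_activation(out / ("activation.nii.gz" if geometry is not None
                            else "activation.tsv"),
                     amap, geometry, meta={**meta, "kernel": best.to_dict()})
    (out / "results.json").write_text(json.dumps(results, indent=2,
                                                 default=_jsonify))
    (out / "config.json").write_text(config.to_json())
    return results
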