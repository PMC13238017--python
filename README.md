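# kccafmri

Nonlinear kernel canonical correlation analysis (KCCA) for task-fMRI
activation mapping, with self-supervised kernel-parameter selection and
fully synthetic benchmarks.

## Who this is for

Neuroimaging methods researchers who want a subject-level, volume-based
alternative to the GLM read-out for task activation: one that represents
the BOLD data through a nonlinear kernel, maximizes its canonical
correlation with the task design in kernel space, and maps the solution
back to a signed per-voxel activation pattern — without needing labeled
data to tune the kernel.

## The model

For data `Y` (T×Q, standardized) smoothed by a steerable filter bank
(`Ỹ = YA`) and an effective design signal
`x_eff = X(XᵀX)⁻¹C[Cᵀ(XᵀX)⁻¹C]⁻¹`, the method solves the regularized KCCA
problem

    r = max  v_Xᵀ K_X K_Y v_Y / sqrt( v_Xᵀ(K_X²+γK_X)v_X · v_Yᵀ(K_Y²+γK_Y)v_Y )

with `K_X = x_eff x_effᵀ` and `K_Y` one of nine kernels (linear, parabolic,
Gaussian, inverse, bounded linear, square, tanh, mixed tanh, reduced tanh)
of the smoothed data.  The activation map is recovered by the
pseudo-inverse back-reconstruction `α = s·AỸᵀ(ỸỸᵀ)⁺K_Y v_Y` (BC1; a
sensitivity-map variant BC2 is also provided), with
`s = sign corr(x_eff, K_Y v_Y)`.

Kernel parameters are selected self-supervised: by maximizing the
stability of α under order-reversal voxel shuffling (volumes) or noise
injection (1D benchmark), under a fixed per-kernel evaluation budget.
See `docs/methods.md` for the full account.

## Worked example

Run the full pipeline on one subject of the 1D benchmark (10⁴ locations,
100 time points, 10% active, signal strength 0.3) with the mixed
hyperbolic tangent kernel:

```bash
kccafmri fit --kernel mixed_tanh --seed 3 --out run3
```

prints (abridged):

```json
{
  "kernel": {"name": "mixed_tanh",
             "params": {"b1": 0.0770, "b2": 0.2953, "c": -0.4575},
             "gamma": 218.19},
  "best_loss": 0.0076843,
  "n_evaluations": 200,
  "partial_auc": 0.053306,
  "baseline_partial_auc": 0.045441,
  "r_truth": 1.173087,
  "activation_threshold": 2.02e-05,
  "canonical_r": 0.09177
}
```

Reading the numbers: the optimizer spent exactly its 200-evaluation budget
minimizing the noise-injection loss and settled on a mildly nonlinear
mixed tanh kernel.  Its activation map detects the ground-truth active
locations with a partial AUC (FPR < 0.1) of 0.0533 against 0.0454 for the
per-location-correlation baseline — an `r_truth` of 1.17, i.e. a 17%
improvement.  `activation_threshold` is the α cutoff at a 5% false
activation rate estimated from time-permuted canonical vectors.  The map
itself is written to `run3/activation.tsv` with a JSON sidecar recording
the kernel, γ, seeds and config hash.

The same machinery runs on volumetric data (`simulate volume`, NIfTI
in/out, steerable-bank smoothing) and exposes every stage as a library
function: `simulate_1d`, `synthetic_noise_volume`, `steerable_bank`,
`build_kernel`, `solve_kcca`, `back_reconstruct_bc1/2`,
`optimize_kernel_params`, the five validation metrics, and the
permutation-based activation threshold.

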