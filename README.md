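# aniso4d

Paradigm-free recovery of activity-inducing signals from 4D fMRI by an
anisotropic diffusion flow on the joint space–time volume.

## The problem

Task fMRI analysis (e.g. the GLM) needs the experimental paradigm to build
regressors. Resting-state data, epileptic discharges, or any unscripted
activity offer no such regressors, so the underlying neural activation must
be recovered blindly from the BOLD signal — which is the activity-inducing
signal *u(t)* convolved with the hemodynamic response function (HRF) *h(t)*
and buried in noise. `aniso4d` is for researchers who want a deconvolution-
flavoured spatiotemporal regularizer that treats the 4D image (3D space ×
1D time) as a single geometric object instead of decoupling spatial and
temporal penalties.

## The method

The observed, preprocessed image **I**₀ evolves by explicit Euler steps of
the flow

    ∂I/∂t = (1 − α) · Hᵀ(I₀ − H I) / ‖I₀‖₂  +  α · div(D̃ ∇I) / ‖div(D̃₀ ∇I₀)‖₂

* **H** — causal convolution with the HRF along time (default: canonical
  double-gamma sampled at TR, peak-normalized; any kernel can be supplied);
  **Hᵀ** is its exact adjoint (correlation with the time-reversed kernel).
* **D̃** — the steering tensor. The 4D structure tensor
  D = (∇I ∇Iᵀ / (‖∇I‖₂ + ε)) * G_{σ_G} is eigendecomposed per voxel,
  D = QΛQᵀ, and its leading eigenvalue is remapped by
  λ̃₁ = exp(−(λ₁ / max Λ)² / (2σ_D²)) with λ̃₂ = λ̃₃ = λ̃₄ = 1, then
  D̃ = QΛ̃Qᵀ. Strong spatiotemporal gradients (activation onsets, tissue
  edges) get λ̃₁ ≈ 0 — diffusion is suppressed across them — while flat
  regions diffuse isotropically.
* Gradients are forward differences, the divergence the matching backward
  difference, with Neumann (replicate-edge) boundaries: −div is the exact
  adjoint of grad, and div∘grad is the 4D Laplacian stencil.
* Both denominators are global L2 norms frozen at iteration 0.

Defaults follow the reference parameterization: α = 0.9997, σ_G = 1 voxel,
σ_D = 0.2, step 0.1, 40 iterations, steering tensor recomputed every
iteration. The final image is returned as the recovered activity-inducing
signal **û**.

The package also ships the synthetic phantom generator used for
validation (block/spike design × Gaussian-blob amplitude map, two-stage
Gaussian noise, HRF convolution: y = H(map·u + ε_m) + ε_a), the evaluation
metrics (voxel-wise Pearson maps over a gray-matter mask, RMSE/STD-root
summaries, spherical MNI ROIs with a packaged motor-task coordinate
table), NIfTI-1 I/O, detrend + z-score preprocessing, and a CLI.

## Worked example

`examples/block_recovery.py` builds the standard block phantom
(12×12×12 voxels, TR 1 s, 100 s, one activation block from 20 to 60 s,
amplitude map in [0, 3]) at a 6.5 dB peak SNR and runs the default flow:

```
phantom: (12, 12, 12) voxels x 100 timepoints, pSNR = 6.47 dB, sigma_a = 8.375
flow: 40 iterations, final regularization-term L2 = 0.9988
mean GM correlation with the true activation: raw y = 0.2059, recovered u-hat = 0.2061
recovered RMSE over GM = 8.914 across 687 voxels
```

The recovered image correlates better with the ground-truth activation
than the raw data — the flow denoises — but the margin is small: at
α = 0.9997 with the frozen global-norm scaling, per-iteration updates are
a tiny fraction of the image (see `docs/methods.md` for the quantitative
analysis, including why the HRF lag bounds the attainable correlation).
`examples/spike_recovery.py` and `examples/steering_tensor_tour.py` walk
through the event-related design and the tensor remap.

The same pipeline from the shell:

```sh
aniso4d simulate --shape 12 12 12 --duration 100 --blocks 20:60:1 \
    --sigma-a 8.4 --seed 42 --out-dir sim/
aniso4d filter --input sim/y.nii.gz --output uhat.nii.gz   # defaults as above
aniso4d evaluate --input uhat.nii.gz --reference sim/u.txt \
    --mask sim/gm_mask.nii.gz --out-dir eval/
```

Every run writes a JSON manifest; `aniso4d rerun MANIFEST` reproduces its
outputs byte-for-byte.

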