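# Methods

## Signal model

Each voxel's BOLD series is modelled as an activity-inducing signal passed
through a causal linear time-invariant hemodynamic system and corrupted in
two stages:

    u_n(v, t) = a(v) · u(t) + ε_m(v, t),    ε_m ~ N(0, σ_m²)
    x(v, t)   = (u_n(v, ·) * h)(t)
    y(v, t)   = x(v, t) + ε_a(v, t),        ε_a ~ N(0, σ_a²)

`u(t)` is a block (boxcar, half-open intervals on the TR grid) or spike
train; `a(v)` a 3D amplitude map; ε_m "model noise" (intrinsic neural
fluctuation, added *before* the HRF); ε_a acquisition noise. The phantom
generator implements exactly this chain, with a sum of 3D Gaussian blobs
rescaled to [0, 3] standing in for a scanner-simulated activation map, and
a gray-matter mask defined as map > 10 % of its peak. Noise regimes are
labelled by peak SNR, pSNR = 20·log₁₀(max|x| / RMS(y − x)) dB, and
`noise_for_target_psnr` inverts this to calibrate σ_a (E[RMS] = σ).

What the generator does **not** emulate: physiological (cardiac,
respiratory) noise spectra, motion, scanner drift, spatial noise
correlations, or T2*-weighted acquisition physics. Passing tests therefore
demonstrate correctness of the operators and the flow's behaviour under
the stated two-stage Gaussian model — not performance on real scanner
data.

### HRF kernel

The hemodynamic system is the canonical double-gamma response: gamma
densities (unit dispersion) peaking at 6 s minus 1/6 of one peaking at
16 s, sampled at TR over 32 s and normalized to unit peak. The
normalization keeps the fidelity term comparable across TRs; any
user-supplied single-column kernel file can replace it, since the flow
only requires *some* causal LTI response. `H` is causal convolution
truncated to the scan length (implicit zero history); `Hᵀ` is its exact
adjoint on the fixed-length time axis. A degenerate sampling that leaves
no positive lobe (e.g. a single sample at lag 0) falls back to a unit
impulse so the kernel stays a valid response.

## The regularization flow

    ∂I/∂t = (1 − α) · Hᵀ(I₀ − H I) / ‖I₀‖₂  +  α · div(D̃ ∇I) / ‖div(D̃₀ ∇I₀)‖₂

Explicit Euler, initialized at I⁰ = I₀ (the observed, preprocessed
image — a standard warm start that makes the fidelity term begin at
Hᵀ(I₀ − HI₀)). Both denominators are global L2 norms over all voxels and
timepoints, computed once from I₀ and the initial steering tensor and
frozen. The steering tensor is recomputed from the evolving image every
iteration (configurable for speed). A fixed iteration count (default 40)
is the stopping rule; a per-iteration callback supports monitoring
quantities such as correlation with a reference.

### Discretization

* Gradient: forward first differences per axis, trailing difference 0
  (replicate-edge Neumann boundary), divided by the axis spacing (unit
  index spacing by default — σ_G and the step size are calibrated in
  index space).
* Divergence: backward differences with outer-face flux treated as zero,
  the unique convention making −div the exact adjoint of grad; with an
  identity tensor, div∘grad is the 4D Neumann Laplacian stencil (exact on
  integer inputs). This yields exact global sum conservation for *any*
  steering tensor (telescoping flux balance).
* Structure tensor: per-voxel outer product ∇I∇Iᵀ divided by ‖∇I‖₂ + ε
  (ε = 1e−8; a squared-norm variant giving a unit-trace orientation
  tensor is available as a config switch), each of the 10 unique
  components Gaussian-smoothed with σ_G, truncation 4σ, reflect boundary
  (consistent with the Neumann domain). σ_G = 0 skips smoothing.
* Eigendecomposition: batched symmetric solver; eigenvalues sorted
  descending; values in [−1e−8, 0) clipped to 0, anything lower raises
  (corrupted tensor). Repeated eigenvalues keep the solver's stable
  order; only the reconstruction QΛQᵀ is contractual, never eigenvector
  uniqueness.
* Remap: λ̃₁ = exp(−(λ₁/max Λ)²/(2σ_D²)), λ̃₂..₄ = 1, where max Λ is the
  **global** maximum of λ₁ over the image, recomputed with the tensor
  each iteration. A per-voxel maximum would make the ratio identically 1
  and the remap constant; the global maximum lets it discriminate edge
  from flat voxels. A zero global maximum (constant image) is guarded by
  ε. Since λ̃₂..₄ = 1, the rebuilt tensor is
  D̃ = Id + (λ̃₁ − 1)θ₁θ₁ᵀ: identity wherever λ̃₁ = 1.
* Stability: explicit steps with spectrum(D̃) ⊆ (0, 1] and step 0.1
  satisfy the 4D explicit-diffusion bound (0.1 · 2 · 4 < 1). If an update
  still produces non-finite values (e.g. a deliberately huge step), the
  run aborts with an instability error rather than clipping.
* Update sign: the right-hand side is **added** (I ← I + τ·RHS); both
  terms as written point toward data fit and smoothing. A subtractive
  variant is available behind `FlowConfig.subtractive_update` for
  completeness, since the iteration has also been described as a removal
  from the previous image; the subtractive reading makes the fidelity
  term increase misfit and is off by default.

### Parameters

| name | meaning | default | unit |
|---|---|---|---|
| α | regularization weight (1 − α on fidelity) | 0.9997 | — |
| σ_G | structure-tensor smoothing width | 1 | voxels |
| σ_D | eigenvalue-remap width | 0.2 | — (ratio scale) |
| step | explicit Euler pseudo-time increment | 0.1 | — |
| n_iter | iterations | 40 | — |
| tensor_update_every | steering-tensor refresh period | 1 | iterations |
| ε | zero guards (tensor norm, global max) | 1e−8 | — |

## Quantitative behaviour of the default flow (read this)

Two consequences of the frozen global-norm scaling deserve emphasis,
because they bound what the method can do at the default parameters. The
numbers below are measured by the test suite and `scripts/acceptance.py`
on the 12×12×12×100 block phantom.

1. **The updates are small.** ‖I₀‖₂ and ‖div(D̃₀∇I₀)‖₂ are norms over all
   ~1.7e5 voxel-timepoints (≈930 and ≈78 on the noise-free phantom), so
   the normalized flow terms have RMS far below the image scale and
   40 steps of 0.1 change the image by a fraction of a percent. The flow
   *is* a strict improvement — mean gray-matter correlation with the true
   activation rises at every tested noise level, monotonically over
   iterations — but by small margins.
2. **The fidelity term cannot deconvolve at α = 0.9997.** Its total
   weight over a run is (1 − α)·n_iter·step ≈ 1.2e−3. The recovered
   signal therefore retains the hemodynamic lag: a 40 s block convolved
   with the canonical HRF correlates ≈0.78 with the unshifted block, and
   that is, to within the small diffusion gain, where recovery lands
   (noise-free ceiling ≈0.784; a control experiment with the
   regularization term un-normalized and 10× the pseudo-time reaches only
   ≈0.83). Likewise a single spike's recovered peak sits ~6 TR after the
   true spike — the HRF peak delay — at any admissible diffusion speed.
   Correlations approaching 1 with the *pre-convolution* signal, or spike
   localization within ±2 TR, would require a dominant fidelity weight or
   an explicit inverse-system operator, both outside this
   parameterization. The corresponding acceptance checks are left failing
   by design rather than weakening the normalization contract.

## Evaluation metrics

* Voxel-wise Pearson correlation of each masked series with a reference;
  zero-variance voxels are flagged undefined and excluded from means
  (setting them to 0 would bias ROI averages).
* Per-voxel temporal MSE summarized as RMSE = √(mean MSE) and the root of
  the std of the MSEs; both raw moments also exposed, since "root of the
  mean and the standard deviation" admits more than one reading.
* Spherical ROIs: a voxel belongs if its world-space center lies within
  the radius; per-task ROIs are unioned **before** gray-matter
  intersection. A packaged TSV ships the somatosensory-homunculus MNI
  centers grouped into five motor tasks (finger centers per hand, tongue
  base/middle/tip bilaterally, feet).
* Task regressors are unit-amplitude boxcars on the TR grid (half-open
  intervals).

## Preprocessing and I/O

Per voxel: least-squares linear detrend, then division by the residual
std; constant-after-detrend voxels are zeroed and flagged. NIfTI-1 TR is
read from pixdim[4] only when the header declares a time unit (converted
to seconds); otherwise an explicit TR is required, and an explicit TR
always wins with a warning. Affines are carried through untouched — all
computation is in voxel index space. Every CLI run writes a JSON manifest
from which `aniso4d rerun` reproduces outputs byte-identically (NIfTI
writes are deterministic, gzip mtime included).

## Study sizes

The bundled studies use the 12×12×12×100 phantom (block design: two
calibrated noise regimes, 6.5 and 4.0 dB, five seeds each, plus a
noise-free run; spike design: one spike at 30 s, ~13 dB), pure-diffusion
physics on a 16³×20 noise image over 50 steps, and operator checks on
randomized small grids — sizes chosen so the whole battery runs in a few
minutes on one CPU while exercising every code path at realistic aspect
ratios.

## Known limitations

* No voxel-wise HRF estimation, basis-set HRFs, or nonlinear balloon
  models; the kernel is global.
* The remap frees only one direction per voxel; structures needing
  suppression in two or more directions (e.g. spike trains, point
  events) are over-smoothed.
* Explicit time stepping only; no implicit or semi-implicit solvers.
* The default parameterization denoises but does not materially
  deconvolve (see above); treat û as a regularized image whose *shape*
  is scored by correlation, not as an amplitude-calibrated estimate of
  neural activity.
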