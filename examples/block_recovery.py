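"""Recover a block activation from a noisy synthetic BOLD phantom.

Builds the default 12x12x12 phantom (TR 1 s, 100 s, one 40 s activation
block from 20 to 60 s, amplitude map in [0, 3]), adds acquisition noise
calibrated to a 6.5 dB peak SNR, runs the anisotropic 4D flow at the
default parameters, and scores the result against the known activity-
inducing signal over the gray-matter mask.
"""

import numpy as np

from aniso4d import (
    FlowConfig,
    PhantomSpec,
    build_canonical_hrf,
    mse_summary,
    noise_for_target_psnr,
    psnr,
    run,
    synthesize,
    voxelwise_pearson,
)

kernel = build_canonical_hrf(tr=1.0)

clean = synthesize(PhantomSpec(seed=42), kernel)
sigma_a = noise_for_target_psnr(clean.x, 6.5)
ds = synthesize(PhantomSpec(sigma_a=sigma_a, seed=42), kernel)
print(f"phantom: {ds.y.shape[:3]} voxels x {ds.y.shape[3]} timepoints, "
      f"pSNR = {psnr(ds.x, ds.y):.2f} dB, sigma_a = {sigma_a:.3f}")

recovered, diagnostics = run(ds.y, kernel, FlowConfig())
print(f"flow: {len(diagnostics)} iterations, final regularization-term "
      f"L2 = {diagnostics['regularization_l2'].iloc[-1]:.4f}")

r_raw = voxelwise_pearson(ds.y, ds.u, mask=ds.gm_mask).mean()
cmap = voxelwise_pearson(recovered, ds.u, mask=ds.gm_mask)
summary = mse_summary(recovered, ds.u, mask=ds.gm_mask, correlations=cmap)
print(f"mean GM correlation with the true activation: "
      f"raw y = {r_raw:.4f}, recovered u-hat = {cmap.mean():.4f}")
print(f"recovered RMSE over GM = {summary.rmse:.3f} across {summary.n_voxels} voxels")
print()
print("The recovered image correlates better with the true activity-inducing")
print("signal than the acquired data: the flow has removed noise. The margin")
print("is small because at alpha = 0.9997 with the frozen global-norm")
print("scaling the per-iteration updates are a tiny fraction of the image.")
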