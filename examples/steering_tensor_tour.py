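"""Anatomy of the steering tensor on a noisy block phantom.

Shows how the 4D structure tensor's eigenvalue remap separates edge
voxels (diffusion suppressed along the dominant gradient) from flat
voxels (isotropic diffusion): the leading remapped eigenvalue lambda-1
is near 0 at activation boundaries and near 1 in the background.
"""

import numpy as np

from aniso4d import PhantomSpec, RemapConfig, build_canonical_hrf, synthesize
from aniso4d.tensor import eigendecompose, gradient4d, remap_eigenvalues, structure_tensor

kernel = build_canonical_hrf(tr=1.0)
ds = synthesize(PhantomSpec(sigma_a=0.2, seed=3), kernel)

grad = gradient4d(ds.y)
st = structure_tensor(grad, sigma_g=1.0)
eigs = eigendecompose(st)
lam1 = eigs.values[..., 0]
gmax = float(lam1.max())
remapped = remap_eigenvalues(eigs, gmax, RemapConfig(sigma_d=0.2))[..., 0]

print(f"leading structure-tensor eigenvalue: max = {gmax:.3f}, "
      f"median = {np.median(lam1):.4f}")
print(f"remapped diffusivity lambda-1: min = {remapped.min():.2e}, "
      f"median = {np.median(remapped):.3f}")
aniso = np.mean(remapped < 0.5)
print(f"voxels with strongly suppressed diffusion (lambda-1 < 0.5): "
      f"{100 * aniso:.1f}%")
inside = remapped[ds.gm_mask].mean()
outside = remapped[~ds.gm_mask].mean()
print(f"mean lambda-1 inside the active region = {inside:.3f}, "
      f"outside = {outside:.3f}")
print()
print("Edges of the activation pattern carry large spatiotemporal gradients,")
print("so their leading eigenvalue is large and the remap drives their")
print("diffusivity toward zero - smoothing is steered along, not across,")
print("coherent structure.")
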