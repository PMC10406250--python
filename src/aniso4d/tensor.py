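"""4D finite differences and the steering (structure) tensor field.

The diffusion flow is driven by a per-voxel symmetric 4×4 tensor built
from the spatiotemporal gradient of the evolving image:

1. :func:`gradient4d` — forward ("left-to-right") first differences with
   replicate-edge (Neumann) boundaries.
2. :func:`structure_tensor` — normalized gradient outer product, each of
   the 10 unique components smoothed by a 4D Gaussian of width σ_G.
3. :func:`eigendecompose` / :func:`remap_eigenvalues` /
   :func:`rebuild_tensor` — the eigenvalue remap that reverses diffusion
   across strong gradients: the leading eigenvalue is sent through
   ``exp(−(λ₁/max Λ)² / (2 σ_D²))`` while the other three are set to 1,
   so diffusion is suppressed only along the dominant gradient direction.
4. :func:`divergence4d` — backward ("right-to-left") differences chosen
   so that −div is the exact numerical adjoint of the gradient; with an
   identity tensor div∘grad is the 4D Neumann Laplacian stencil.

Gradients are arrays of shape ``grid + (4,)``; tensor fields store the 10
unique components of the symmetric 4×4 matrix in the order
(xx, xy, xz, xt, yy, yz, yt, zz, zt, tt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "TensorField4D",
    "EigenSystem",
    "RemapConfig",
    "gradient4d",
    "divergence4d",
    "structure_tensor",
    "eigendecompose",
    "remap_eigenvalues",
    "rebuild_tensor",
    "steering_tensor",
]

# row/col index of each stored component of the symmetric 4x4 matrix
_COMP_IJ = [(0, 0), (0, 1), (0, 2), (0, 3),
            (1, 1), (1, 2), (1, 3),
            (2, 2), (2, 3), (3, 3)]

_NEG_EIG_TOL = 1e-8


@dataclass
class TensorField4D:
    """Per-voxel symmetric 4×4 tensor stored as 10 unique components.

    ``components`` has shape ``grid + (10,)``; symmetry is exact by
    construction since only the upper triangle is stored.
    """

    components: np.ndarray
    smoothing_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape[-1] != 10:
            raise ValueError(
                f"expected 10 components on the last axis, got shape {self.components.shape}"
            )

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.components.shape[:-1]

    def to_matrices(self) -> np.ndarray:
        """Expand to full symmetric matrices of shape ``grid + (4, 4)``."""
        mats = np.empty(self.grid_shape + (4, 4), dtype=float)
        for c, (i, j) in enumerate(_COMP_IJ):
            mats[..., i, j] = self.components[..., c]
            mats[..., j, i] = self.components[..., c]
        return mats

    @classmethod
    def from_matrices(cls, mats: np.ndarray, smoothing_sigma: float = 0.0) -> "TensorField4D":
        mats = np.asarray(mats, dtype=float)
        comps = np.stack([mats[..., i, j] for (i, j) in _COMP_IJ], axis=-1)
        return cls(components=comps, smoothing_sigma=smoothing_sigma)


@dataclass
class EigenSystem:
    """Per-voxel orthogonal eigenvectors and descending eigenvalues.

    ``vectors[..., :, k]`` is the eigenvector for ``values[..., k]``;
    eigenvalues are sorted so ``values[..., 0]`` is the largest.
    """

    vectors: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class RemapConfig:
    """Parameters of the eigenvalue remap.

    sigma_d
        Width σ_D of the exponential remap (unitless; operates on the
        ratio λ₁ / max Λ ∈ [0, 1]).
    epsilon
        Guard substituted for a zero global maximum (constant image).
    """

    sigma_d: float = 0.2
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not self.sigma_d > 0:
            raise ValueError("sigma_d must be positive")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


def _check_spacing(spacing) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (4,) or not np.all(spacing > 0):
        raise ValueError("spacing must be 4 positive scalars")
    return spacing


def gradient4d(values: np.ndarray, spacing=(1.0, 1.0, 1.0, 1.0)) -> np.ndarray:
    """Forward-difference 4D gradient with replicate-edge boundary.

    Along each axis ``g[i] = (v[i+1] − v[i]) / h``; the trailing
    difference is 0 (Neumann: replicated edge).  Returns ``grid + (4,)``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 4:
        raise ValueError(f"expected a 4D array, got ndim={values.ndim}")
    spacing = _check_spacing(spacing)
    grad = np.zeros(values.shape + (4,), dtype=float)
    for ax in range(4):
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_out = [slice(None)] * 4
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        sl_out[ax] = slice(None, -1)
        grad[tuple(sl_out) + (ax,)] = (
            values[tuple(sl_hi)] - values[tuple(sl_lo)]
        ) / spacing[ax]
    return grad


def divergence4d(flux: np.ndarray, spacing=(1.0, 1.0, 1.0, 1.0)) -> np.ndarray:
    """Backward-difference divergence, exact negative adjoint of the gradient.

    For each component ``p`` along its own axis::

        div p[0]    =  p[0] / h
        div p[i]    = (p[i] − p[i−1]) / h      (0 < i < n−1)
        div p[n−1]  = −p[n−2] / h

    i.e. the flux is treated as zero on the outer faces, which makes
    ``⟨grad v, p⟩ = −⟨v, div p⟩`` hold exactly and reduces div∘grad to the
    4D Neumann Laplacian when the tensor is the identity.
    """
    flux = np.asarray(flux, dtype=float)
    if flux.ndim != 5 or flux.shape[-1] != 4:
        raise ValueError(f"expected flux of shape grid + (4,), got {flux.shape}")
    spacing = _check_spacing(spacing)
    out = np.zeros(flux.shape[:-1], dtype=float)
    for ax in range(4):
        p = flux[..., ax]
        n = p.shape[ax]
        if n == 1:
            # gradient along a single-sample axis is identically zero, so
            # its adjoint contributes nothing
            continue
        d = np.zeros_like(p)
        first = [slice(None)] * 4
        first[ax] = slice(0, 1)
        d[tuple(first)] = p[tuple(first)]
        if n > 1:
            mid_out = [slice(None)] * 4
            mid_out[ax] = slice(1, n - 1)
            hi = [slice(None)] * 4
            hi[ax] = slice(1, n - 1)
            lo = [slice(None)] * 4
            lo[ax] = slice(0, n - 2)
            d[tuple(mid_out)] = p[tuple(hi)] - p[tuple(lo)]
            last = [slice(None)] * 4
            last[ax] = slice(n - 1, n)
            prev = [slice(None)] * 4
            prev[ax] = slice(n - 2, n - 1)
            d[tuple(last)] = -p[tuple(prev)]
        out += d / spacing[ax]
    return out


def structure_tensor(
    grad: np.ndarray,
    sigma_g: float = 1.0,
    epsilon: float = 1e-8,
    normalization: str = "norm",
) -> TensorField4D:
    """Gaussian-smoothed 4D structure tensor of a gradient field.

    Per voxel the outer product ``∇I ∇Iᵀ`` is divided by ``‖∇I‖₂ + ε``
    (or by ``‖∇I‖₂² + ε`` with ``normalization="squared"``, which yields a
    unit-trace orientation tensor), then each of the 10 unique components
    is convolved with a 4D Gaussian of standard deviation ``sigma_g`` in
    voxel units (truncated at 4σ, reflect boundary).  ``sigma_g = 0``
    skips the smoothing.
    """
    grad = np.asarray(grad, dtype=float)
    if grad.ndim != 5 or grad.shape[-1] != 4:
        raise ValueError(f"expected gradient of shape grid + (4,), got {grad.shape}")
    if sigma_g < 0:
        raise ValueError("sigma_g must be non-negative")
    if normalization not in ("norm", "squared"):
        raise ValueError(f"unknown normalization {normalization!r}")
    norm = np.sqrt(np.sum(grad * grad, axis=-1))
    denom = (norm if normalization == "norm" else norm * norm) + epsilon
    comps = np.empty(grad.shape[:-1] + (10,), dtype=float)
    for c, (i, j) in enumerate(_COMP_IJ):
        comp = grad[..., i] * grad[..., j] / denom
        if sigma_g > 0:
            comp = gaussian_filter(comp, sigma_g, truncate=4.0, mode="reflect")
        comps[..., c] = comp
    return TensorField4D(components=comps, smoothing_sigma=sigma_g)


def eigendecompose(fld: TensorField4D) -> EigenSystem:
    """Per-voxel symmetric eigendecomposition, eigenvalues descending.

    Small negative eigenvalues (numerical noise in a PSD tensor) are
    clipped to 0; anything below −1e−8 signals a corrupted tensor and
    raises.
    """
    mats = fld.to_matrices()
    w, v = np.linalg.eigh(mats)  # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    wmin = w.min() if w.size else 0.0
    if wmin < -_NEG_EIG_TOL:
        raise ValueError(
            f"tensor field is not positive semi-definite (min eigenvalue {wmin:.3e})"
        )
    w = np.clip(w, 0.0, None)
    return EigenSystem(vectors=np.ascontiguousarray(v), values=np.ascontiguousarray(w))


def remap_eigenvalues(
    eigs: EigenSystem, global_max: float, cfg: RemapConfig = RemapConfig()
) -> np.ndarray:
    """Remap eigenvalues: λ̃₁ = exp(−(λ₁/max Λ)² / (2 σ_D²)), λ̃₂..₄ = 1.

    ``global_max`` is the largest leading eigenvalue over the whole image,
    so the ratio λ₁/max Λ discriminates edge voxels (ratio near 1, λ̃₁
    near 0 — diffusion suppressed along the gradient) from flat voxels
    (ratio near 0, λ̃₁ near 1 — isotropic diffusion).  Returns the λ̃
    field of shape ``grid + (4,)`` with every entry in (0, 1].
    """
    lam1 = eigs.values[..., 0]
    if global_max < 0:
        raise ValueError("global_max must be non-negative")
    gmax = global_max if global_max > 0 else cfg.epsilon
    if np.any(lam1 > gmax * (1 + 1e-12) + cfg.epsilon):
        raise ValueError("global_max must dominate every per-voxel leading eigenvalue")
    ratio = lam1 / gmax
    out = np.ones(eigs.values.shape, dtype=float)
    out[..., 0] = np.exp(-(ratio * ratio) / (2.0 * cfg.sigma_d**2))
    return out


def rebuild_tensor(eigs: EigenSystem, remapped: np.ndarray) -> TensorField4D:
    """Rebuild the steering tensor D̃ = Q Λ̃ Qᵀ from remapped eigenvalues.

    With λ̃₂ = λ̃₃ = λ̃₄ = 1 this is ``Id + (λ̃₁ − 1) θ₁ θ₁ᵀ``: identity
    (isotropic) wherever λ̃₁ = 1, rank-one suppression along θ₁ elsewhere.
    """
    remapped = np.asarray(remapped, dtype=float)
    if remapped.shape != eigs.values.shape:
        raise ValueError("remapped eigenvalue grid does not match the eigensystem")
    mats = np.einsum(
        "...ik,...k,...jk->...ij", eigs.vectors, remapped, eigs.vectors, optimize=True
    )
    return TensorField4D.from_matrices(mats)


def steering_tensor(
    values: np.ndarray,
    sigma_g: float = 1.0,
    cfg: RemapConfig = RemapConfig(),
    spacing=(1.0, 1.0, 1.0, 1.0),
    normalization: str = "norm",
) -> tuple[TensorField4D, float]:
    """Full pipeline image → D̃: gradient, structure tensor, remap, rebuild.

    Returns the steering tensor and the global maximum leading eigenvalue
    (a useful per-iteration diagnostic of edge strength).
    """
    grad = gradient4d(values, spacing)
    st = structure_tensor(grad, sigma_g=sigma_g, epsilon=cfg.epsilon,
                          normalization=normalization)
    eigs = eigendecompose(st)
    gmax = float(eigs.values[..., 0].max())
    remapped = remap_eigenvalues(eigs, gmax, cfg)
    out = rebuild_tensor(eigs, remapped)
    out.smoothing_sigma = sigma_g
    return out, gmax
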