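"""Synthetic 4D BOLD phantoms: the two-stage Gaussian noise forward model.

Each voxel's acquired series is built in four stages:

1. activity-inducing signal ``u(t)`` — boxcar blocks or spikes on the TR
   grid, shared by all voxels;
2. per-voxel scaling by a 3D amplitude map (sum of Gaussian blobs
   rescaled into a target range, standing in for a scanner-simulated
   activation map) plus i.i.d. "model noise" ε_m ~ N(0, σ_m²)
   representing intrinsic neural fluctuations:
   ``u_n(v,t) = map(v)·u(t) + ε_m``;
3. HRF convolution: ``x(v,t) = (u_n(v,·) * h)(t)`` — the noiseless BOLD
   course;
4. additive acquisition noise: ``y = x + ε_a`` with ε_a ~ N(0, σ_a²).

Noise regimes are labelled by peak signal-to-noise ratio,
``pSNR = 20·log₁₀(max|clean| / RMS(noisy − clean))`` in dB, and
:func:`noise_for_target_psnr` inverts that definition to calibrate σ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hrf import HRFKernel, apply_hrf

__all__ = [
    "PhantomSpec",
    "SyntheticDataset",
    "boxcar",
    "spike_train",
    "make_activation_map",
    "synthesize",
    "psnr",
    "noise_for_target_psnr",
]

#: default blob layout for a 12-voxel cube: two activation foci of
#: different sizes, off-center so edges fall inside the volume
DEFAULT_BLOBS = (
    ((3.5, 4.0, 4.0), 1.8, 1.0),
    ((8.0, 7.5, 7.0), 2.4, 0.8),
)


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic forward model.

    Defaults reproduce the block-design validation condition: a
    12×12×12 grid at 2 mm isotropic resolution, TR 1 s, 100 s duration,
    one 40 s block from 20 to 60 s, amplitude map in [0, 3].
    """

    shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size: float = 2.0
    tr: float = 1.0
    duration: float = 100.0
    blocks: Sequence[tuple[float, float, float]] = (((20.0, 60.0, 1.0)),)
    spikes: Optional[Sequence[float]] = None
    spike_amplitude: float = 1.0
    sigma_m: float = 0.0
    sigma_a: float = 0.0
    blobs: Sequence[tuple[tuple[float, float, float], float, float]] = DEFAULT_BLOBS
    map_range: tuple[float, float] = (0.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < self.tr:
            raise ValueError("duration must cover at least one TR")
        if self.sigma_m < 0 or self.sigma_a < 0:
            raise ValueError("noise standard deviations must be non-negative")
        lo, hi = self.map_range
        if not hi > lo:
            raise ValueError("map_range must be a non-degenerate interval")

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration / self.tr))


@dataclass
class SyntheticDataset:
    """Output of the forward model; ``y = x + ε_a`` holds by construction."""

    u: np.ndarray            # (nt,) ground-truth activity-inducing signal
    u_n: np.ndarray          # (nx, ny, nz, nt) noisy per-voxel activity
    x: np.ndarray            # (nx, ny, nz, nt) activity-related (noiseless BOLD)
    y: np.ndarray            # (nx, ny, nz, nt) acquired image
    amplitude_map: np.ndarray  # (nx, ny, nz)
    gm_mask: np.ndarray      # (nx, ny, nz) bool
    tr: float
    seed: int
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.eye(4)


def boxcar(
    duration: float,
    tr: float,
    events: Sequence[tuple[float, float, float]] | Sequence[tuple[float, float]],
) -> np.ndarray:
    """Piecewise-constant series on the TR grid.

    Each event is ``(onset, offset[, amplitude])`` in seconds; the sample
    at time t is active iff ``onset ≤ t < offset`` (half-open).  Events
    must not overlap.
    """
    nt = int(round(duration / tr))
    series = np.zeros(nt)
    intervals = []
    for ev in events:
        onset, offset = ev[0], ev[1]
        amp = ev[2] if len(ev) > 2 else 1.0
        if not (0 <= onset < offset <= duration):
            raise ValueError(f"event ({onset}, {offset}) outside [0, {duration}]")
        intervals.append((onset, offset, amp))
    intervals.sort()
    for (a, b, _), (c, _, _) in zip(intervals, intervals[1:]):
        if c < b:
            raise ValueError("events overlap")
    t = np.arange(nt) * tr
    for onset, offset, amp in intervals:
        series[(t >= onset) & (t < offset)] += amp
    return series


def spike_train(
    duration: float,
    tr: float,
    times: Sequence[float],
    amplitude: float = 1.0,
) -> np.ndarray:
    """Zeros with single-sample impulses at the given times.

    Off-grid times are snapped to the nearest TR sample with a warning.
    """
    nt = int(round(duration / tr))
    series = np.zeros(nt)
    for t in times:
        if not 0 <= t < duration:
            raise ValueError(f"spike time {t} outside [0, {duration})")
        idx = t / tr
        nearest = int(round(idx))
        if abs(idx - nearest) > 1e-9:
            warnings.warn(
                f"spike at t={t} s is off the TR grid; snapped to t={nearest * tr} s",
                stacklevel=2,
            )
        series[min(nearest, nt - 1)] += amplitude
    return series


def make_activation_map(
    shape: tuple[int, int, int],
    blobs: Sequence[tuple[tuple[float, float, float], float, float]] = DEFAULT_BLOBS,
    map_range: tuple[float, float] = (0.0, 3.0),
    gm_threshold: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of 3D Gaussian blobs rescaled into ``map_range``.

    Each blob is ``(center voxel, width in voxels, peak)``.  The summed
    field is affinely rescaled so its minimum and maximum hit the range
    bounds exactly.  Returns ``(map, gm_mask)`` where the mask marks
    voxels above ``gm_threshold`` of the map's peak.
    """
    if len(blobs) == 0:
        raise ValueError("at least one blob is required")
    lo, hi = map_range
    if not hi > lo:
        raise ValueError("map_range must be a non-degenerate interval")
    grid = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"),
        axis=-1,
    )
    amap = np.zeros(shape)
    for center, width, peak in blobs:
        d2 = np.sum((grid - np.asarray(center, dtype=float)) ** 2, axis=-1)
        amap += peak * np.exp(-d2 / (2.0 * width**2))
    span = amap.max() - amap.min()
    if span == 0:
        raise ValueError("degenerate blob layout: the map is constant")
    amap = lo + (amap - amap.min()) * (hi - lo) / span
    gm_mask = amap > gm_threshold * amap.max()
    return amap, gm_mask


def synthesize(spec: PhantomSpec, kernel: HRFKernel) -> SyntheticDataset:
    """Run the full forward model for one seeded realization."""
    if not np.isclose(spec.tr, kernel.tr):
        raise ValueError(f"spec TR {spec.tr} does not match kernel TR {kernel.tr}")
    if spec.spikes is not None:
        u = spike_train(spec.duration, spec.tr, spec.spikes, spec.spike_amplitude)
    else:
        u = boxcar(spec.duration, spec.tr, spec.blocks)
    amap, gm_mask = make_activation_map(spec.shape, spec.blobs, spec.map_range)
    rng = np.random.default_rng(spec.seed)
    nt = u.size
    u_n = amap[..., None] * u[None, None, None, :]
    if spec.sigma_m > 0:
        u_n = u_n + rng.normal(0.0, spec.sigma_m, size=spec.shape + (nt,))
    x = apply_hrf(u_n, kernel)
    y = x
    if spec.sigma_a > 0:
        y = x + rng.normal(0.0, spec.sigma_a, size=x.shape)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    return SyntheticDataset(
        u=u, u_n=u_n, x=x, y=y, amplitude_map=amap, gm_mask=gm_mask,
        tr=spec.tr, seed=spec.seed, affine=affine,
    )


def psnr(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Peak SNR in dB: 20·log₁₀(max|clean| / RMS(noisy − clean)).

    Returns +inf when the residual is exactly zero.
    """
    clean = np.asarray(clean, dtype=float)
    noisy = np.asarray(noisy, dtype=float)
    if clean.shape != noisy.shape:
        raise ValueError("clean and noisy arrays must share a shape")
    rms = np.sqrt(np.mean((noisy - clean) ** 2))
    if rms == 0.0:
        return float("inf")
    peak = np.max(np.abs(clean))
    return float(20.0 * np.log10(peak / rms))


def noise_for_target_psnr(clean: np.ndarray, target_db: float) -> float:
    """Additive-noise σ whose expected pSNR equals ``target_db``.

    For ε ~ N(0, σ²) the residual RMS converges to σ, so
    σ = max|clean| / 10^(target/20).
    """
    if not np.isfinite(target_db):
        raise ValueError("target pSNR must be finite")
    peak = float(np.max(np.abs(clean)))
    if peak == 0:
        raise ValueError("clean signal is identically zero")
    return peak / 10.0 ** (target_db / 20.0)
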