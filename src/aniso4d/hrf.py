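"""Discrete hemodynamic response kernel and its linear operators.

The BOLD signal is modelled as the activity-inducing signal passed through
a causal linear time-invariant system ``h(t)`` — the hemodynamic response
function (HRF) — sampled on the TR grid.  Two operators act purely along
the time axis of a series or 4D image:

* ``H``  (:func:`apply_hrf`): causal convolution with the kernel,
  truncated to the input length.
* ``Hᵀ`` (:func:`apply_hrf_adjoint`): the exact adjoint under the standard
  inner product on the fixed-length time axis, i.e. correlation with the
  kernel (convolution with the time-reversed kernel).

Both treat every spatial voxel independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gammaln

__all__ = [
    "HRFKernel",
    "build_canonical_hrf",
    "load_kernel",
    "apply_hrf",
    "apply_hrf_adjoint",
]

_TR_RTOL = 1e-6


@dataclass(frozen=True)
class HRFKernel:
    """Causal HRF sampled at lags 0, TR, 2·TR, ...

    Parameters
    ----------
    samples
        Kernel amplitudes (dimensionless), first entry at lag 0.
    tr
        Seconds between successive samples.
    """

    samples: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        if samples.size < 1:
            raise ValueError("kernel must have at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("kernel samples must be finite")
        if not np.any(samples > 0):
            raise ValueError("kernel must have at least one positive sample")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        object.__setattr__(self, "samples", samples)

    @property
    def length(self) -> int:
        return self.samples.size


def _gamma_pdf(t: np.ndarray, shape: float, scale: float = 1.0) -> np.ndarray:
    """Gamma density, zero for t <= 0 (avoids scipy.stats overhead)."""
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def build_canonical_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> HRFKernel:
    """Canonical double-gamma HRF sampled at TR, peak-normalized to 1.

    The kernel is the difference of two gamma densities: a positive lobe
    peaking near ``peak_delay`` seconds and a delayed undershoot scaled by
    ``undershoot_ratio``.  With unit dispersion a gamma density with shape
    ``k`` peaks at ``k − 1`` seconds, so the shapes are ``delay + 1``.

    Parameters
    ----------
    tr
        Sampling interval in seconds.
    duration
        Kernel support in seconds; the kernel has ``ceil(duration/tr)``
        samples.
    peak_delay, undershoot_delay
        Modes of the response and undershoot lobes, seconds.
    undershoot_ratio
        Relative amplitude of the undershoot lobe.
    """
    if not tr > 0:
        raise ValueError(f"tr must be positive, got {tr}")
    if duration < tr:
        raise ValueError(f"duration ({duration}) must be at least one tr ({tr})")
    if peak_delay <= 0 or undershoot_delay <= 0:
        raise ValueError("delays must be positive")
    n = int(np.ceil(duration / tr))
    lags = np.arange(n) * tr
    h = _gamma_pdf(lags, peak_delay + 1.0) - undershoot_ratio * _gamma_pdf(
        lags, undershoot_delay + 1.0
    )
    peak = h.max()
    if peak <= 0:
        # degenerate sampling (e.g. single sample at lag 0): fall back to a
        # unit impulse so the kernel stays a valid causal LTI response
        h = np.zeros(n)
        h[0] = 1.0
    else:
        h = h / peak
    return HRFKernel(samples=h, tr=tr)


def load_kernel(path, tr: float) -> HRFKernel:
    """Read a user-supplied kernel: one sample per line at TR spacing."""
    samples = np.loadtxt(path, dtype=float)
    return HRFKernel(samples=np.atleast_1d(samples), tr=tr)


def _check_tr(data_tr: float | None, kernel: HRFKernel) -> None:
    if data_tr is not None and not np.isclose(
        data_tr, kernel.tr, rtol=_TR_RTOL, atol=0.0
    ):
        raise ValueError(
            f"TR mismatch: data TR {data_tr} vs kernel TR {kernel.tr}"
        )


def apply_hrf(data: np.ndarray, kernel: HRFKernel, tr: float | None = None) -> np.ndarray:
    """Apply H: causal convolution along the last (time) axis.

    ``out[..., t] = Σ_{k ≤ t} kernel[k] · data[..., t − k]`` — implicit zero
    history before t = 0, output truncated to the input length.
    """
    _check_tr(tr, kernel)
    data = np.asarray(data, dtype=float)
    if data.shape[-1] < 1:
        raise ValueError("time axis must have at least one sample")
    k = kernel.samples.reshape((1,) * (data.ndim - 1) + (-1,))
    full = fftconvolve(data, k, axes=-1)
    return np.ascontiguousarray(full[..., : data.shape[-1]])


def apply_hrf_adjoint(
    data: np.ndarray, kernel: HRFKernel, tr: float | None = None
) -> np.ndarray:
    """Apply Hᵀ: anti-causal correlation along the last (time) axis.

    Exact adjoint of :func:`apply_hrf` on the fixed-length time axis:
    ``out[..., t] = Σ_{k ≥ 0, t+k < nt} kernel[k] · data[..., t + k]``,
    implemented as convolution with the time-reversed kernel.
    """
    _check_tr(tr, kernel)
    data = np.asarray(data, dtype=float)
    nt = data.shape[-1]
    if nt < 1:
        raise ValueError("time axis must have at least one sample")
    k = kernel.samples[::-1].reshape((1,) * (data.ndim - 1) + (-1,))
    full = fftconvolve(data, k, axes=-1)
    lo = kernel.length - 1
    return np.ascontiguousarray(full[..., lo : lo + nt])
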