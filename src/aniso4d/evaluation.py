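"""Validation metrics: correlation maps, RMSE summaries, spherical ROIs.

Recovered activity is scored against a reference time course (the
ground-truth activity-inducing signal for phantoms, or a unit-amplitude
task regressor for task fMRI) by voxel-wise Pearson correlation over a
gray-matter mask, and by the root of the mean (and of the std) of the
per-voxel mean squared errors.  Spherical ROIs in world (MNI mm)
coordinates support region-level correlation summaries; a packaged table
ships the somatosensory homunculus centers grouped into the five motor
tasks (left/right hand, left/right foot, tongue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .flow import Image4D
from .phantom import boxcar

__all__ = [
    "CorrelationMap",
    "ROISpec",
    "MetricSummary",
    "voxelwise_pearson",
    "mse_summary",
    "build_spherical_roi",
    "union_rois",
    "task_regressor",
    "roi_mean_correlation",
    "load_motor_roi_table",
]


@dataclass
class CorrelationMap:
    """Voxel-wise Pearson r with an undefined-voxel mask.

    ``values`` holds r in [−1, 1] where defined and NaN elsewhere;
    ``defined`` marks voxels where both series had nonzero variance (and
    the evaluation mask was set).
    """

    values: np.ndarray
    defined: np.ndarray
    reference: str = ""

    def mean(self) -> float:
        return float(np.mean(self.values[self.defined]))


@dataclass(frozen=True)
class ROISpec:
    """Spherical region of interest in world coordinates."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius must be positive")


@dataclass
class MetricSummary:
    """Roots of mean / std of per-voxel MSEs plus correlation moments."""

    rmse: float
    mse_std_root: float
    mse_mean: float
    mse_std: float
    r_mean: Optional[float] = None
    r_std: Optional[float] = None
    n_voxels: int = 0


def _as_values(image) -> np.ndarray:
    return image.values if isinstance(image, Image4D) else np.asarray(image, dtype=float)


def voxelwise_pearson(
    image,
    reference: np.ndarray,
    mask: Optional[np.ndarray] = None,
    reference_name: str = "",
) -> CorrelationMap:
    """Pearson correlation of every (masked) voxel series with a reference.

    Voxels whose series — or the reference — have zero variance are
    flagged undefined and excluded from downstream means.
    """
    values = _as_values(image)
    reference = np.asarray(reference, dtype=float).ravel()
    if values.shape[-1] != reference.size:
        raise ValueError(
            f"reference length {reference.size} != image time axis {values.shape[-1]}"
        )
    if mask is None:
        mask = np.ones(values.shape[:-1], dtype=bool)
    mask = np.asarray(mask).astype(bool)
    ref_c = reference - reference.mean()
    ref_ss = float(ref_c @ ref_c)
    vox = values - values.mean(axis=-1, keepdims=True)
    vox_ss = np.sum(vox * vox, axis=-1)
    out = np.full(values.shape[:-1], np.nan)
    defined = mask & (vox_ss > 0) & (ref_ss > 0)
    if not defined.any():
        raise ValueError("no voxel has a defined correlation under the mask")
    num = vox[defined] @ ref_c
    out[defined] = num / np.sqrt(vox_ss[defined] * ref_ss)
    return CorrelationMap(values=out, defined=defined, reference=reference_name)


def mse_summary(
    recovered,
    truth,
    mask: Optional[np.ndarray] = None,
    correlations: Optional[CorrelationMap] = None,
) -> MetricSummary:
    """Per-voxel MSE over time, summarized over the mask.

    ``truth`` may be a single reference series (broadcast to every voxel)
    or a full 4D image.  ``rmse`` is the root of the mean of per-voxel
    MSEs; ``mse_std_root`` the root of their standard deviation.  When a
    correlation map is supplied its defined-voxel mean/std are attached.
    """
    rec = _as_values(recovered)
    tru = _as_values(truth) if np.asarray(truth).ndim == 4 else np.asarray(
        truth, dtype=float
    ).ravel()
    if tru.ndim == 1:
        if tru.size != rec.shape[-1]:
            raise ValueError("truth series length does not match the image time axis")
        tru = np.broadcast_to(tru, rec.shape)
    elif tru.shape != rec.shape:
        raise ValueError("truth image shape does not match the recovered image")
    if mask is None:
        mask = np.ones(rec.shape[:-1], dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask selects no voxels")
    mse = np.mean((rec - tru) ** 2, axis=-1)[mask]
    summary = MetricSummary(
        rmse=float(np.sqrt(mse.mean())),
        mse_std_root=float(np.sqrt(mse.std())),
        mse_mean=float(mse.mean()),
        mse_std=float(mse.std()),
        n_voxels=int(mask.sum()),
    )
    if correlations is not None:
        r_def = correlations.values[correlations.defined & mask]
        if r_def.size:
            summary.r_mean = float(r_def.mean())
            summary.r_std = float(r_def.std())
    return summary


def build_spherical_roi(
    spec: ROISpec, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Binary mask of voxels whose world-space centers lie within the sphere."""
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 voxel-to-world map")
    idx = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"),
        axis=-1,
    )
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    d2 = np.sum((world - np.asarray(spec.center_mm, dtype=float)) ** 2, axis=-1)
    mask = d2 <= spec.radius_mm**2
    if not mask.any():
        warnings.warn(
            f"ROI {spec.label or spec.center_mm} lies entirely outside the grid",
            stacklevel=2,
        )
    return mask


def union_rois(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Union of per-center ROI masks (grouping per task)."""
    if len(masks) == 0:
        raise ValueError("at least one mask is required")
    out = np.zeros_like(np.asarray(masks[0], dtype=bool))
    for m in masks:
        out |= np.asarray(m, dtype=bool)
    return out


def task_regressor(
    duration: float, tr: float, blocks: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Unit-amplitude piecewise-constant task time course."""
    return boxcar(duration, tr, [(a, b, 1.0) for a, b in blocks])


def roi_mean_correlation(
    cmap: CorrelationMap, roi: np.ndarray
) -> tuple[float, int]:
    """Mean of defined correlation values inside an ROI, with the count."""
    roi = np.asarray(roi).astype(bool)
    sel = roi & cmap.defined
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI contains no voxels with a defined correlation")
    return float(cmap.values[sel].mean()), n


def load_motor_roi_table() -> pd.DataFrame:
    """Packaged somatosensory-homunculus ROI centers (MNI mm) per task."""
    with resources.files("aniso4d.data").joinpath("motor_rois.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
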