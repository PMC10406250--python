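"""NIfTI-1 reading/writing, preprocessing, and reproducibility manifests.

TR is taken from the NIfTI header (pixdim[4]); an explicit override wins
with a warning.  Preprocessing follows the standard recipe: per-voxel
linear detrend followed by normalization to zero mean and unit standard
deviation, with constant voxels left at zero and flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from . import __version__
from .flow import Image4D

__all__ = [
    "read_nifti",
    "read_mask",
    "write_nifti",
    "preprocess",
    "RunManifest",
]


def read_nifti(path, tr: Optional[float] = None) -> Image4D:
    """Load a 4D NIfTI-1 image; TR from pixdim[4] unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    # pixdim[4] defaults to 1 even when no TR was recorded; trust it only
    # when the header declares a time unit, and convert to seconds
    time_unit = int(img.header["xyzt_units"]) & 0x38
    unit_scale = {8: 1.0, 16: 1e-3, 24: 1e-6}.get(time_unit)
    if unit_scale is None:
        header_tr = 0.0
    else:
        header_tr *= unit_scale
    if tr is not None:
        if header_tr > 0 and not np.isclose(tr, header_tr):
            warnings.warn(
                f"{path}: overriding header TR {header_tr} s with {tr} s",
                stacklevel=2,
            )
        use_tr = tr
    elif header_tr > 0:
        use_tr = header_tr
    else:
        raise ValueError(
            f"{path}: no TR in the NIfTI header (pixdim[4]); pass tr explicitly"
        )
    return Image4D(values=data, tr=use_tr, affine=np.asarray(img.affine))


def read_mask(path, shape: Optional[tuple[int, int, int]] = None) -> np.ndarray:
    """Load a 3D binary mask."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    if shape is not None and data.shape != tuple(shape):
        raise ValueError(f"{path}: mask shape {data.shape} != image grid {shape}")
    return data > 0


def write_nifti(image: Image4D | np.ndarray, path, tr: Optional[float] = None,
                affine: Optional[np.ndarray] = None) -> None:
    """Write an image (or bare array) as NIfTI-1 with TR in pixdim[4]."""
    if isinstance(image, Image4D):
        data, use_affine, use_tr = image.values, image.affine, image.tr
    else:
        data = np.asarray(image, dtype=float)
        use_affine = affine if affine is not None else np.eye(4)
        use_tr = tr if tr is not None else 1.0
    img = nib.Nifti1Image(data, np.asarray(use_affine, dtype=float))
    if data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = use_tr
        img.header.set_zooms(zooms)
        img.header["xyzt_units"] = 10  # mm + s
    nib.save(img, str(path))


def preprocess(image: Image4D, return_flags: bool = False):
    """Per-voxel linear detrend then z-normalization.

    Each voxel's time course has its least-squares line removed, then is
    divided by the residual standard deviation.  Voxels constant after
    detrending are set to zero and flagged.
    """
    values = image.values
    nt = values.shape[-1]
    if nt < 3:
        raise ValueError(f"need at least 3 time points to detrend, got {nt}")
    t = np.arange(nt, dtype=float)
    design = np.stack([np.ones(nt), t], axis=1)           # (nt, 2)
    flat = values.reshape(-1, nt)
    coef, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat - (design @ coef).T
    std = resid.std(axis=1)
    flat_ok = std > 1e-12
    out = np.zeros_like(resid)
    out[flat_ok] = resid[flat_ok] / std[flat_ok, None]
    result = Image4D(
        values=out.reshape(values.shape), tr=image.tr, affine=image.affine
    )
    if return_flags:
        constant = (~flat_ok).reshape(values.shape[:-1])
        return result, constant
    return result


@dataclass
class RunManifest:
    """Everything needed to reproduce one CLI run bit-identically."""

    command: str
    config: dict
    inputs: dict
    outputs: dict
    seed: Optional[int] = None
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            self.version = __version__

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
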