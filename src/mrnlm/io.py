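"""NIfTI-1 input/output for volumes and label masks.

Volumes are stored as 32-bit float NIfTI with the voxel spacing carried in
the header (pixdim, via a diagonal affine); label masks as int16. Existing
files are never overwritten unless ``force`` is set.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .core import Volume
from .errors import ParameterError, ShapeError

__all__ = ["read_volume", "write_volume", "read_labels", "write_labels"]


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ShapeError(f"{path}: expected a 3-D volume, got {img.ndim}-D data")
    return img


def _spacing(img) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume(path) -> Volume:
    """Read a 3-D NIfTI volume; spacing is taken from the header zooms.

    Volumes containing NaN/Inf are rejected.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ParameterError(f"{path}: volume contains NaN or Inf values")
    return Volume(data, _spacing(img))


def write_volume(vol: Volume, path, force: bool = False, description: str = "") -> None:
    """Write a volume as float32 NIfTI-1. Refuses to overwrite without ``force``."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*vol.spacing, 1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_labels(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an integer label volume; returns (labels, spacing)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    return np.rint(data).astype(np.int16), _spacing(img)


def write_labels(labels: np.ndarray, spacing, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), str(path))
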