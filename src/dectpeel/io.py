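"""NIfTI I/O helpers.

Volumes are stored with a diagonal RAS affine built from the voxel spacing;
world coordinates of voxel ``(i, j, k)`` are ``(i*sx, j*sy, k*sz)`` mm with
0-based indices and voxel-center semantics.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ValidationError


def spacing_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(path, data: np.ndarray, spacing, dtype=None) -> None:
    """Write a 3-D array as NIfTI with the given mm spacing."""
    arr = np.asarray(data)
    if arr.ndim != 3:
        raise ValidationError(f"expected a 3-D volume, got shape {arr.shape}")
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, spacing_affine(spacing))
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI volume; returns ``(array, spacing)``."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume not found: {p}")
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_mask(path):
    data, spacing = read_volume(path)
    return data > 0, spacing


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
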