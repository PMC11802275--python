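"""NIfTI and table I/O.

Volumes are NIfTI-1 via nibabel with voxel sizes carried in the header;
arrays are used in voxel-index order with the slice (k) axis treated as the
B0-parallel axis unless configured otherwise.  Tables are plain CSV/TSV.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

Array = np.ndarray


def read_volume(path) -> tuple[Array, tuple[float, float, float], Array]:
    """Read a 3D NIfTI volume; returns (array, voxel_size_mm, affine).

    4D (or higher) inputs are rejected: the pipeline is single-echo.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms, img.affine


def write_volume(path, data: Array, voxel_size_mm=(1.0, 1.0, 1.0), affine=None) -> None:
    data = np.asarray(data)
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms(tuple(voxel_size_mm))
    nib.save(img, str(path))


def check_same_grid(path_a, a_affine: Array, a_shape, path_b, b_affine: Array, b_shape) -> None:
    """Reject volumes that do not share grid and affine (no registration here)."""
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"grid mismatch: {path_a} {tuple(a_shape)} vs {path_b} {tuple(b_shape)}")
    if not np.allclose(a_affine, b_affine, atol=1e-4):
        raise ValueError(f"affine mismatch between {path_a} and {path_b}")


def read_label_names(path) -> dict[int, str]:
    """Tab-separated ``code<TAB>region`` table."""
    out: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            code, name = line.split("\t", 1)
            out[int(code)] = name.strip()
    return out


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "region", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table {path} missing columns {sorted(missing)}")
    return df
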