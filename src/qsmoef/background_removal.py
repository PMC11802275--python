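"""V-SHARP background field removal.

Fields measured inside the brain are the sum of the local (tissue) field
and a background field generated by sources outside the brain.  The
background is harmonic inside the mask, so the spherical-mean-value (SMV)
operator leaves it unchanged wherever the sphere fits inside the mask:
(I - SMV) annihilates it.  V-SHARP applies (I - SMV_r) with progressively
smaller radii toward the mask boundary (largest sphere that still fits at
each voxel), then deconvolves by (I - SMV_rmax) in k-space with truncated
singular values to undo the high-pass distortion of the tissue field.

Spheres are defined in millimetres (radius in units of the smallest voxel
edge) and rasterized per-axis, so anisotropic grids are handled by physical
distance.  The TSVD threshold is relative to the largest spectral magnitude
of (I - SMV_rmax): a threshold of 1 truncates everything, a threshold
approaching 0 is plain deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import VsharpParams
from .phase_proc import BrainMask

Array = np.ndarray


@dataclass
class FieldVolume:
    """Normalized field (ppm) with the mask on which it is valid."""

    values: Array
    mask: Array

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("field contains non-finite values inside its mask")


def sphere_footprint(radius_voxels: float, voxel_size_mm) -> Array:
    """Boolean sphere of physical radius ``radius_voxels * min(voxel edge)``.

    Rasterized per-axis: voxel offsets whose physical center distance is
    within the radius.  Always contains at least the center voxel.
    """
    if radius_voxels < 1:
        raise ValueError(f"radius must be >= 1 voxel, got {radius_voxels}")
    vx = np.asarray(voxel_size_mm, dtype=float)
    r_mm = radius_voxels * vx.min()
    half = np.maximum(np.floor(r_mm / vx).astype(int), 0)
    g = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    d2 = sum((gi * v) ** 2 for gi, v in zip(g, vx))
    fp = d2 <= r_mm**2
    fp[tuple(h for h in half)] = True
    return fp


def _smv_kernel_fft(shape, footprint: Array) -> Array:
    """k-space SMV kernel: FFT of the normalized sphere centered at 0."""
    kern = np.zeros(shape)
    half = tuple(h // 2 for h in footprint.shape)
    idx = np.argwhere(footprint) - np.array(half)
    kern[tuple((idx % np.array(shape)).T)] = 1.0
    kern /= kern.sum()
    return np.fft.fftn(kern)


def smv_filter(field: Array, radius_voxels: float, voxel_size_mm=(1.0, 1.0, 1.0)) -> Array:
    """Spherical-mean-value filter: convolution with a normalized sphere."""
    field = np.asarray(field, dtype=float)
    if radius_voxels > min(field.shape) / 2:
        raise ValueError(
            f"SMV radius {radius_voxels} exceeds half the smallest dimension "
            f"of volume shape {field.shape}"
        )
    fp = sphere_footprint(radius_voxels, voxel_size_mm)
    s = _smv_kernel_fft(field.shape, fp)
    return np.fft.ifftn(s * np.fft.fftn(field)).real


def vsharp(
    total_field: Array,
    mask: BrainMask | Array,
    params: VsharpParams = VsharpParams(),
    voxel_size_mm=(1.0, 1.0, 1.0),
):
    """Variable-kernel SMV background removal with TSVD deconvolution.

    Returns ``(tissue_field, eroded_mask)``.  At each voxel the high-pass
    (I - SMV_r) uses the largest radius whose sphere fits inside the mask;
    the combined high-passed field is deconvolved by (I - SMV_rmax) with
    spectral magnitudes below ``tsvd_threshold * max|I - SMV_rmax|``
    truncated.  Voxels where no sphere fits are excluded from the eroded
    mask and set to zero.
    """
    field = np.asarray(total_field, dtype=float)
    m = mask.values if isinstance(mask, BrainMask) else np.asarray(mask, dtype=bool)
    radii = params.radii_voxels
    if max(radii) > min(field.shape) / 2:
        raise ValueError(
            f"largest radius {max(radii)} does not fit volume shape {field.shape}"
        )

    # Physical distance (mm) from each in-mask voxel to the mask boundary:
    # a sphere of radius r_mm fits wherever the distance is >= r_mm.
    dist_mm = ndimage.distance_transform_edt(m, sampling=voxel_size_mm)
    vmin = float(np.min(voxel_size_mm))

    combined = np.zeros_like(field)
    assigned = np.zeros(field.shape, dtype=bool)
    smv_max_fft = None
    for i, r in enumerate(radii):
        fp = sphere_footprint(r, voxel_size_mm)
        s_fft = _smv_kernel_fft(field.shape, fp)
        if i == 0:
            smv_max_fft = s_fft
        fits = dist_mm >= r * vmin
        sel = fits & ~assigned
        if np.any(sel):
            highpass = field - np.fft.ifftn(s_fft * np.fft.fftn(field)).real
            combined[sel] = highpass[sel]
            assigned |= sel
    eroded = assigned
    if not np.any(eroded):
        raise ValueError(
            f"mask too thin: no sphere of radius >= {min(radii)} voxels fits inside"
        )

    c = 1.0 - smv_max_fft
    cmax = np.abs(c).max()
    keep = np.abs(c) > params.tsvd_threshold * cmax
    inv = np.where(keep, 1.0 / np.where(keep, c, 1.0), 0.0)
    tissue = np.fft.ifftn(inv * np.fft.fftn(combined)).real
    tissue = np.where(eroded, tissue, 0.0)
    return tissue, BrainMask(values=eroded, erosion_level=int(np.ceil(min(radii))))
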