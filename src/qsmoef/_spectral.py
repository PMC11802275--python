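"""Shared k-space machinery: dipole kernel, spectral Laplacian, padding.

All spectral operators use numpy's FFT frequency layout and respect
anisotropic voxel sizes (frequencies in cycles/mm).  B0 is taken along a
configurable array axis, default the third (axial slices).
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray


def freq_grids(shape: tuple[int, ...], voxel_size_mm) -> list[Array]:
    """Per-axis FFT frequencies (cycles/mm) broadcastable to ``shape``."""
    grids = []
    for ax, (n, d) in enumerate(zip(shape, voxel_size_mm)):
        f = np.fft.fftfreq(n, d=float(d))
        sh = [1] * len(shape)
        sh[ax] = n
        grids.append(f.reshape(sh))
    return grids


def dipole_kernel(shape, voxel_size_mm, b0_axis: int = 2) -> Array:
    """Unit dipole kernel D(k) = 1/3 - k_b0^2/|k|^2, with D(0) = 0.

    The zero-frequency value is a convention: the spatially uniform part of
    the susceptibility produces no observable internal field offset, so the
    mean is pinned to zero.
    """
    fx, fy, fz = freq_grids(shape, voxel_size_mm)
    k2 = fx**2 + fy**2 + fz**2
    kb = (fx, fy, fz)[b0_axis]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kb**2 / k2
    d = np.where(k2 == 0, 0.0, d)
    return d.astype(np.float64)


def laplacian_kernel(shape, voxel_size_mm) -> Array:
    """Continuous spectral Laplacian -(2*pi*|f|)^2 on the FFT grid."""
    fx, fy, fz = freq_grids(shape, voxel_size_mm)
    return -((2.0 * np.pi) ** 2) * (fx**2 + fy**2 + fz**2)


def apply_spectral(volume: Array, kernel: Array) -> Array:
    """Real part of F^-1(kernel * F(volume))."""
    return np.fft.ifftn(kernel * np.fft.fftn(volume)).real


def pad_volume(volume: Array, margin: int, value: float = 0.0):
    """Zero-pad by ``margin`` voxels per side; returns (padded, crop slices)."""
    if margin < 0:
        raise ValueError(f"pad margin must be >= 0, got {margin}")
    if margin == 0:
        return volume, tuple(slice(None) for _ in volume.shape)
    padded = np.pad(volume, margin, mode="constant", constant_values=value)
    crop = tuple(slice(margin, margin + n) for n in volume.shape)
    return padded, crop


def wrap_phase(phase: Array) -> Array:
    """Wrap to (-pi, pi] via atan2 of the phasor; exact for any input."""
    wrapped = np.arctan2(np.sin(phase), np.cos(phase))
    # atan2 returns -pi at the branch point; fold it onto +pi so the
    # interval is half-open as (-pi, pi].
    return np.where(wrapped == -np.pi, np.pi, wrapped)
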