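"""Phase normalization, Laplacian unwrapping and magnitude-based masking.

Stored phase comes in vendor-specific integer dialects; ``normalize_phase``
maps any of them affinely onto (-pi, pi].  Unwrapping uses the Laplacian
identity

    lap(phi_true) = cos(phi) * lap(sin(phi)) - sin(phi) * lap(cos(phi))

evaluated with spectral derivatives and inverted with the spectral inverse
Laplacian (k = 0 component set to zero).  The resulting arbitrary constant
is pinned by adding the circular mean of the in-mask difference to the
input, which matches the input's masked mean modulo 2*pi and makes the
output pointwise congruent to the wrapped input.

The brain mask stands in for an external brain-extraction tool: threshold
at a fraction of the 99th-percentile magnitude, keep the largest connected
component, morphologically close.  Real extraction masks can be supplied
instead wherever a mask is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._spectral import apply_spectral, laplacian_kernel, pad_volume, wrap_phase

Array = np.ndarray


@dataclass
class PhaseVolume:
    """Phase in radians; ``wrapped`` marks whether values live in (-pi, pi]."""

    values: Array
    wrapped: bool

    def __post_init__(self) -> None:
        if self.wrapped:
            v = self.values
            if v.size and (v.min() < -np.pi - 1e-12 or v.max() > np.pi + 1e-12):
                raise ValueError("wrapped phase must lie in (-pi, pi]")


@dataclass
class BrainMask:
    values: Array
    erosion_level: int = 0

    def __post_init__(self) -> None:
        if self.erosion_level < 0:
            raise ValueError("erosion_level must be >= 0")
        self.values = self.values.astype(bool)


def normalize_phase(raw: Array, dialect: str = "radians", custom_range=None) -> PhaseVolume:
    """Affinely rescale stored phase onto (-pi, pi].

    Dialects: ``radians`` (pass through, must already be in range),
    ``signed_int`` (symmetric about 0, e.g. [-4096, 4094] with scale
    2*pi/8192), ``unsigned_int`` (e.g. [0, 4095], midpoint maps to ~0),
    ``custom_range`` with explicit (lo, hi) mapping lo -> -pi and
    hi + one quantum -> +pi is approximated by the linear map of [lo, hi]
    onto [-pi, pi).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw phase contains non-finite values")
    if dialect == "radians":
        return PhaseVolume(values=wrap_phase(raw), wrapped=True)
    if dialect == "signed_int":
        # Symmetric integer storage: full span lo..lo+2^b-1 maps linearly,
        # scale 2*pi / 2^b inferred from the extreme magnitude.
        half = max(abs(raw.min()), abs(raw.max() + 1))
        values = raw * (np.pi / half)
    elif dialect == "unsigned_int":
        top = raw.max()
        if top <= 0:
            raise ValueError("unsigned_int phase must have a positive maximum")
        span = top + 1
        values = (raw - span / 2.0) * (2 * np.pi / span)
    elif dialect == "custom_range":
        if custom_range is None:
            raise ValueError("custom_range dialect requires custom_range=(lo, hi)")
        lo, hi = map(float, custom_range)
        if hi <= lo:
            raise ValueError(f"custom range has zero or negative width: ({lo}, {hi})")
        values = (raw - lo) / (hi - lo) * (2 * np.pi) - np.pi
    else:
        raise ValueError(f"unknown phase dialect {dialect!r}")
    return PhaseVolume(values=wrap_phase(values), wrapped=True)


def laplacian_unwrap(
    phase: PhaseVolume,
    mask: BrainMask,
    voxel_size_mm=(1.0, 1.0, 1.0),
    pad_voxels: int = 16,
) -> PhaseVolume:
    """Unwrap wrapped phase spectrally via the sin/cos Laplacian identity.

    Returns smooth phase congruent to the input modulo 2*pi inside the mask
    (up to a single global 2*pi multiple).  Spectral derivatives assume
    periodicity; the volume is zero-padded by ``pad_voxels`` per side to
    suppress wrap-around.
    """
    if not phase.wrapped:
        raise ValueError("laplacian_unwrap expects wrapped phase")
    m = mask.values
    if not np.any(m):
        raise ValueError("brain mask is empty")
    phi, crop = pad_volume(phase.values, pad_voxels)
    lap = laplacian_kernel(phi.shape, voxel_size_mm)
    s, c = np.sin(phi), np.cos(phi)
    lap_true = c * apply_spectral(s, lap) - s * apply_spectral(c, lap)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(lap == 0, 0.0, 1.0 / np.where(lap == 0, 1.0, lap))
    raw = apply_spectral(lap_true, inv)[crop]

    # Gauge: the inverse Laplacian leaves an arbitrary constant.  The
    # circular mean of (input - raw) over the mask is (mod 2*pi) the offset
    # that restores congruence with the input; adding it pins the masked
    # mean of the output to the input's masked mean up to a 2*pi multiple.
    diff = phase.values[m] - raw[m]
    offset = np.angle(np.exp(1j * diff).mean())
    return PhaseVolume(values=raw + offset, wrapped=False)


def make_mask(
    magnitude: Array,
    threshold_fraction: float = 0.4,
    closing_radius: int = 2,
) -> BrainMask:
    """Brain mask from magnitude: threshold, largest component, closing.

    The threshold is ``threshold_fraction`` times the 99th-percentile
    magnitude; ``threshold_fraction = 0`` keeps every voxel.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if magnitude.min() < 0:
        raise ValueError("magnitude must be nonnegative")
    if threshold_fraction <= 0:
        return BrainMask(values=np.ones(magnitude.shape, dtype=bool))
    thr = threshold_fraction * np.percentile(magnitude, 99)
    rough = magnitude > thr
    if not np.any(rough):
        raise ValueError(f"no voxels exceed magnitude threshold {thr:.4g}")
    labels, n = ndimage.label(rough)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        rough = labels == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        ball = _ball(closing_radius)
        rough = ndimage.binary_closing(rough, structure=ball)
    return BrainMask(values=rough)


def _ball(radius: int) -> Array:
    r = int(radius)
    g = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r**2
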