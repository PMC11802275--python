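"""Susceptibility phantoms with veins of known oxygenation.

The phantom is the ground truth against which the reconstruction and the
vein-based OEF estimator are validated.  It consists of a uniform tissue
susceptibility inside an ellipsoidal brain mask, plus cylindrical
paramagnetic veins whose susceptibility offset over tissue encodes a known
oxygen extraction fraction through

    delta_chi = delta_chi_do * Hct * OEF_true

(the intravascular contrast, i.e. the OEF model solved for delta_chi with a
partial-volume factor of 1).  Veins are rasterized with sub-voxel coverage
fractions, so edge voxels carry a diluted offset; this is exactly the
partial-volume effect the estimator's P_v factor corrects, and
:func:`rasterization_pv` computes the factor the rasterization implies.

The forward dipole model converts susceptibility to the normalized field
perturbation, and :func:`synthesize_phase` turns fields into wrapped phase
and magnitude at given acquisition settings, optionally adding a harmonic
background field (from sources strictly outside the mask) and complex
Gaussian noise.

Cohort simulation draws per-subject ROI means from published group summary
statistics, emulating the statistical structure of a two-group regional
study.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._spectral import apply_spectral, dipole_kernel, wrap_phase
from .params import AcquisitionParams, OefParams

Array = np.ndarray

#: Sub-voxel sampling density per axis used when rasterizing vein cylinders.
_SUBSAMPLES = 4


@dataclass(frozen=True)
class VeinRecord:
    """Bookkeeping for one rasterized vein."""

    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius_voxels: float
    oef_true: float
    hct: float
    chi_offset_ppm: float
    voxel_index: Array  # (n, 3) integer coords with center inside the cylinder
    mean_coverage: float  # mean sub-voxel coverage over those voxels
    coverage_index: Array  # (m, 3) coords of every voxel with coverage > 0
    coverage_values: Array  # matching coverage fractions in (0, 1]


@dataclass
class SusceptibilityPhantom:
    """Ground-truth susceptibility volume with vein records."""

    chi_ppm: Array
    brain_mask: Array
    tissue_chi_ppm: float
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_axis: int = 2
    vein_records: list[VeinRecord] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.chi_ppm.shape

    def vein_mask(self) -> Array:
        """Union of all recorded vein voxel sets."""
        mask = np.zeros(self.shape, dtype=bool)
        for rec in self.vein_records:
            if len(rec.voxel_index):
                mask[tuple(rec.voxel_index.T)] = True
        return mask

    def copy(self) -> "SusceptibilityPhantom":
        return copy.deepcopy(self)


def make_phantom(
    grid_shape,
    tissue_chi_ppm: float = 0.02,
    mask_margin_voxels: int = 4,
    voxel_size_mm=(1.0, 1.0, 1.0),
    b0_axis: int = 2,
) -> SusceptibilityPhantom:
    """Uniform-tissue phantom inside an ellipsoidal brain mask.

    The mask is the ellipsoid with semi-axes ``n/2 - margin`` per axis,
    centered in the grid; susceptibility is ``tissue_chi_ppm`` inside and 0
    outside.
    """
    shape = tuple(int(n) for n in grid_shape)
    for ax, n in enumerate(shape):
        if n < 16:
            raise ValueError(
                f"grid axis {ax} has size {n}; phantoms need >= 16 voxels per axis"
            )
    coords = np.ogrid[tuple(slice(0, n) for n in shape)]
    centers = [(n - 1) / 2.0 for n in shape]
    semi = [n / 2.0 - mask_margin_voxels for n in shape]
    if min(semi) <= 1:
        raise ValueError(
            f"mask_margin_voxels={mask_margin_voxels} leaves no interior for grid {shape}"
        )
    r2 = sum(((c - m) / s) ** 2 for c, m, s in zip(coords, centers, semi))
    mask = r2 <= 1.0
    chi = np.where(mask, float(tissue_chi_ppm), 0.0)
    return SusceptibilityPhantom(
        chi_ppm=chi,
        brain_mask=mask,
        tissue_chi_ppm=float(tissue_chi_ppm),
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        b0_axis=b0_axis,
    )


def _line_distance(shape, point, direction) -> Array:
    """Distance (voxel units) from each voxel center to an infinite line."""
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("vein direction must be a nonzero vector")
    d = d / norm
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    rel = [g - p for g, p in zip(grids, point)]
    proj = sum(r * di for r, di in zip(rel, d))
    perp2 = sum((r - proj * di) ** 2 for r, di in zip(rel, d))
    return np.sqrt(np.maximum(perp2, 0.0))


def add_vein(
    phantom: SusceptibilityPhantom,
    axis,
    radius_voxels: float,
    oef_true: float,
    params: OefParams | None = None,
) -> SusceptibilityPhantom:
    """Add one cylindrical vein; returns the same phantom, mutated.

    ``axis`` is ``(point, direction)`` in voxel coordinates; the cylinder is
    infinite along ``direction`` and clipped by the grid.  The vein's
    susceptibility offset over tissue is ``delta_chi_do * hct * oef_true``
    (intravascular contrast); voxels get the offset scaled by their
    sub-voxel coverage fraction.
    """
    if params is None:
        params = OefParams()
    if not 0.0 <= oef_true <= 1.0:
        raise ValueError(f"oef_true must be in [0, 1], got {oef_true}")
    if radius_voxels <= 0:
        raise ValueError(f"radius_voxels must be > 0, got {radius_voxels}")
    point, direction = axis
    dist = _line_distance(phantom.shape, point, direction)
    core = dist <= radius_voxels
    if not np.any(core & phantom.brain_mask):
        raise ValueError("vein cylinder does not intersect the brain mask")

    offset = params.delta_chi_do * params.hct * float(oef_true)

    # Sub-voxel coverage for voxels near the boundary; interior voxels get 1.
    coverage = np.zeros(phantom.shape)
    coverage[dist <= radius_voxels - 1.0] = 1.0
    shell = (dist > radius_voxels - 1.0) & (dist <= radius_voxels + 1.0)
    if np.any(shell):
        idx = np.argwhere(shell)
        s = _SUBSAMPLES
        offs = (np.arange(s) + 0.5) / s - 0.5
        sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1).reshape(-1, 3)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        p = np.asarray(point, dtype=float)
        pts = idx[:, None, :] + sub[None, :, :]  # (n, s^3, 3)
        rel = pts - p
        proj = rel @ d
        perp2 = np.einsum("ijk,ijk->ij", rel, rel) - proj**2
        inside = perp2 <= radius_voxels**2
        coverage[tuple(idx.T)] = inside.mean(axis=1)

    phantom.chi_ppm = phantom.chi_ppm + offset * coverage
    vox = np.argwhere(core)
    mean_cov = float(coverage[tuple(vox.T)].mean()) if len(vox) else 0.0
    cov_idx = np.argwhere(coverage > 0)
    phantom.vein_records.append(
        VeinRecord(
            point=tuple(float(p) for p in point),
            direction=tuple(float(dd) for dd in direction),
            radius_voxels=float(radius_voxels),
            oef_true=float(oef_true),
            hct=params.hct,
            chi_offset_ppm=offset,
            voxel_index=vox,
            mean_coverage=mean_cov,
            coverage_index=cov_idx,
            coverage_values=coverage[tuple(cov_idx.T)],
        )
    )
    return phantom


def rasterization_pv(record: VeinRecord, vein_mask: Array | None = None) -> float:
    """Partial-volume factor implied by the vein's rasterization.

    Ratio of the intravascular susceptibility offset to the mean offset the
    rasterized vein presents over a voxel set: the factor that maps a
    measured vein-minus-tissue delta_chi back to the intravascular value
    the OEF model expects.  With no ``vein_mask`` the set is the vein's
    recorded (center-inside) voxels; passing the detector's full-volume
    boolean vein mask yields the factor consistent with how veins are
    actually segmented, including partially covered edge voxels.
    """
    if vein_mask is None:
        if record.mean_coverage <= 0:
            raise ValueError("vein record has no coverage; cannot derive a P_v")
        return 1.0 / record.mean_coverage
    n = int(np.asarray(vein_mask, dtype=bool).sum())
    if n == 0:
        raise ValueError("empty vein mask; cannot derive a P_v")
    covered = vein_mask[tuple(record.coverage_index.T)]
    mean_cov = float(record.coverage_values[covered].sum()) / n
    if mean_cov <= 0:
        raise ValueError("vein mask does not overlap the vein's coverage support")
    return 1.0 / mean_cov


def forward_field(
    phantom_or_chi, voxel_size_mm=None, b0_axis: int | None = None
) -> Array:
    """Normalized field perturbation (ppm) of a susceptibility distribution.

    Spectral multiplication with the unit dipole kernel
    D(k) = 1/3 - k_b0^2/|k|^2 (D(0) = 0, zero-mean field convention).
    Accepts a phantom or a bare chi array (then voxel size defaults to
    isotropic and B0 to axis 2 unless given).
    """
    if isinstance(phantom_or_chi, SusceptibilityPhantom):
        chi = phantom_or_chi.chi_ppm
        voxel_size_mm = phantom_or_chi.voxel_size_mm
        b0_axis = phantom_or_chi.b0_axis
    else:
        chi = np.asarray(phantom_or_chi, dtype=float)
        if voxel_size_mm is None:
            voxel_size_mm = (1.0, 1.0, 1.0)
        if b0_axis is None:
            b0_axis = 2
    if not np.all(np.isfinite(chi)):
        raise ValueError("susceptibility volume contains non-finite values")
    d = dipole_kernel(chi.shape, voxel_size_mm, b0_axis=b0_axis)
    return apply_spectral(chi, d)


# ---------------------------------------------------------------------------
# Background fields (harmonic inside the mask)
# ---------------------------------------------------------------------------

#: Harmonic polynomial basis on centered normalized coordinates u in [-1, 1].
HARMONIC_BASIS = ("1", "x", "y", "z", "xy", "xz", "yz", "x2-y2", "2z2-x2-y2")


def harmonic_background(shape, coeffs: dict[str, float]) -> Array:
    """Low-order harmonic polynomial field (ppm) on normalized coordinates.

    Every basis term has zero Laplacian, so the field is harmonic everywhere
    and in particular inside any brain mask.
    """
    shape = tuple(int(n) for n in shape)
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    basis = {
        "1": np.ones(shape),
        "x": x,
        "y": y,
        "z": z,
        "xy": x * y,
        "xz": x * z,
        "yz": y * z,
        "x2-y2": x**2 - y**2,
        "2z2-x2-y2": 2 * z**2 - x**2 - y**2,
    }
    out = np.zeros(shape)
    for name, c in coeffs.items():
        if name not in basis:
            raise ValueError(f"unknown harmonic basis term {name!r}; use {HARMONIC_BASIS}")
        out += float(c) * basis[name]
    return out


def exterior_source_background(
    phantom: SusceptibilityPhantom,
    n_sources: int = 8,
    amplitude_ppm: float = 50.0,
    seed: int = 0,
    margin_voxels: int = 2,
) -> Array:
    """Dipole field (ppm) of point susceptibility sources outside the mask.

    Sources are placed at random voxels at least ``margin_voxels`` away from
    the brain mask, so the resulting field is harmonic throughout the mask
    interior — the property spherical-mean-value filtering removes exactly.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    forbidden = ndimage.binary_dilation(phantom.brain_mask, iterations=margin_voxels)
    candidates = np.argwhere(~forbidden)
    if len(candidates) == 0:
        raise ValueError("no exterior voxels available for background sources")
    pick = candidates[rng.choice(len(candidates), size=n_sources, replace=False)]
    chi = np.zeros(phantom.shape)
    signs = rng.choice([-1.0, 1.0], size=n_sources)
    chi[tuple(pick.T)] = signs * amplitude_ppm
    return forward_field(chi, phantom.voxel_size_mm, phantom.b0_axis)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def phase_from_field(field_ppm: Array, params: AcquisitionParams) -> Array:
    """True (unwrapped) phase in radians: gamma * B0 * TE * field."""
    return params.phase_per_ppm * np.asarray(field_ppm, dtype=float)


def synthesize_phase(
    field_ppm: Array,
    params: AcquisitionParams,
    noise_sd: float = 0.0,
    background_ppm: Array | None = None,
    background_coeffs: dict[str, float] | None = None,
    mask: Array | None = None,
    seed: int = 0,
):
    """Wrapped phase and magnitude of the complex gradient-echo signal.

    The true phase is ``gamma*B0*TE*(field + background)*1e-6``; the signal
    is unit magnitude inside ``mask`` (everywhere if no mask) with complex
    Gaussian noise of standard deviation ``noise_sd`` per channel added
    before taking magnitude and phase — so phase noise scales as 1/SNR.
    Returns ``(wrapped_phase, magnitude)``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    field = np.asarray(field_ppm, dtype=float)
    total = field.copy()
    if background_coeffs:
        total = total + harmonic_background(field.shape, background_coeffs)
    if background_ppm is not None:
        total = total + background_ppm
    true_phase = phase_from_field(total, params)
    amplitude = np.ones(field.shape) if mask is None else mask.astype(float)
    signal = amplitude * np.exp(1j * true_phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + noise_sd * (
            rng.standard_normal(field.shape) + 1j * rng.standard_normal(field.shape)
        )
    magnitude = np.abs(signal)
    wrapped = wrap_phase(np.angle(signal))
    return wrapped, magnitude


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Two-group regional summary statistics to draw per-subject data from.

    ``group_a``/``group_b`` map region name -> (mean, sd, n); units are
    those of the measured variable (regional OEF in percent for the shipped
    reference table).
    """

    region_names: tuple[str, ...]
    group_a: dict[str, tuple[float, float, int]]
    group_b: dict[str, tuple[float, float, int]]
    labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        for grp in (self.group_a, self.group_b):
            for region in self.region_names:
                mean, sd, n = grp[region]
                if sd < 0:
                    raise ValueError(f"SD must be >= 0 for region {region!r}")
                if n < 2:
                    raise ValueError(f"n must be >= 2 for region {region!r}")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-subject ROI means: independent normals per region and group.

    Returns a tidy table with columns (subject_id, group, region, value),
    reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, grp in zip(spec.labels, (spec.group_a, spec.group_b)):
        for region in spec.region_names:
            mean, sd, n = grp[region]
            draws = mean + sd * rng.standard_normal(int(n))
            for i, v in enumerate(draws, start=1):
                rows.append((f"{label}{i:02d}", label, region, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "region", "value"])
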