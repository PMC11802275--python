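"""Parameter containers and study defaults.

Every physical or algorithmic knob of the pipeline lives in one of the
dataclasses below so that a run is fully described by a single
:class:`PipelineConfig`.  Defaults follow the acquisition and physiology of
the 3 T susceptibility-weighted protocol the package targets: TE = 14 ms,
B0 = 3 T, 0.6 x 0.6 x 2.0 mm voxels, hematocrit 0.45, partial-volume factor
6.0, vein threshold mean + 2 SD inside 64 x 64 x 30-voxel windows.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (CODATA).
GAMMA_PROTON = 2.6752218744e8

#: Susceptibility difference between fully deoxygenated and fully oxygenated
#: blood per unit hematocrit, volume-susceptibility CGS convention.
DCHI_DO_CGS = 1.8e-7

#: The same constant in SI ppm: chi_SI = 4*pi*chi_CGS, so 4*pi*1.8e-7 = 2.262 ppm.
DCHI_DO_SI_PPM = 4.0 * math.pi * DCHI_DO_CGS * 1e6


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition geometry and timing.

    ``voxel_size_mm`` is ordered (x, y, z) with z the slice axis; the static
    field B0 is assumed parallel to ``b0_axis`` (default: axis 2, axial
    acquisition).
    """

    b0_tesla: float = 3.0
    te_seconds: float = 0.014
    gyromagnetic_ratio_rad_per_s_per_t: float = GAMMA_PROTON
    voxel_size_mm: tuple[float, float, float] = (0.6, 0.6, 2.0)
    b0_axis: int = 2

    def __post_init__(self) -> None:
        if self.b0_tesla <= 0:
            raise ValueError(f"b0_tesla must be > 0, got {self.b0_tesla}")
        if self.te_seconds <= 0:
            raise ValueError(f"te_seconds must be > 0, got {self.te_seconds}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be 3 positive lengths, got {self.voxel_size_mm}")
        if self.b0_axis not in (0, 1, 2):
            raise ValueError(f"b0_axis must be 0, 1 or 2, got {self.b0_axis}")

    @property
    def phase_per_ppm(self) -> float:
        """Phase accrued at TE by a 1 ppm field offset, in radians."""
        return (
            self.gyromagnetic_ratio_rad_per_s_per_t
            * self.b0_tesla
            * self.te_seconds
            * 1e-6
        )


@dataclass(frozen=True)
class OefParams:
    """Physiological constants of the susceptibility-based OEF model.

    OEF = (delta_chi * pv) / (delta_chi_do * hct), where delta_chi is the
    vein-minus-tissue susceptibility difference.  In ``unit_system='SI_ppm'``
    susceptibilities are ppm (SI); in ``'CGS'`` they are raw CGS volume
    susceptibilities and ``delta_chi_do`` defaults to 1.8e-7.
    """

    delta_chi_do: float = DCHI_DO_SI_PPM
    hct: float = 0.45
    pv: float = 6.0
    unit_system: str = "SI_ppm"

    def __post_init__(self) -> None:
        if self.delta_chi_do <= 0:
            raise ValueError("delta_chi_do must be > 0")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hct must be in (0, 1), got {self.hct}")
        if self.pv < 1.0:
            raise ValueError(f"pv must be >= 1, got {self.pv}")
        if self.unit_system not in ("SI_ppm", "CGS"):
            raise ValueError(f"unknown unit_system {self.unit_system!r}")

    @classmethod
    def cgs(cls, pv: float = 6.0, hct: float = 0.45) -> "OefParams":
        """The same model expressed in the CGS unit system."""
        return cls(delta_chi_do=DCHI_DO_CGS, hct=hct, pv=pv, unit_system="CGS")


@dataclass(frozen=True)
class VsharpParams:
    """Variable-kernel spherical-mean-value background removal settings.

    Radii are expressed in units of the smallest voxel edge and must be
    strictly decreasing.  ``tsvd_threshold`` is the truncation level of the
    deconvolution, as a fraction of the largest spectral magnitude of
    (I - SMV) at the largest radius.
    """

    radii_voxels: tuple[float, ...] = (25, 20, 15, 10, 5, 3, 2, 1)
    tsvd_threshold: float = 0.05

    def __post_init__(self) -> None:
        r = tuple(self.radii_voxels)
        if not r or any(b >= a for a, b in zip(r, r[1:])):
            raise ValueError(f"radii must be strictly decreasing, got {r}")
        if min(r) < 1:
            raise ValueError(f"all radii must be >= 1 voxel, got {r}")
        if not 0.0 < self.tsvd_threshold <= 1.0:
            raise ValueError(f"tsvd_threshold must be in (0, 1], got {self.tsvd_threshold}")


@dataclass(frozen=True)
class InversionParams:
    """Dipole-inversion regularization knobs.

    ``tkd_threshold`` bounds |D(k)| away from zero in the thresholded
    k-space division; the two-pass method reconstructs strong sources with
    ``strong_pass_threshold``, keeps voxels above ``strong_source_chi_ppm``,
    subtracts their forward field and inverts the residual with
    ``weak_pass_threshold``.
    """

    tkd_threshold: float = 0.1
    strong_pass_threshold: float = 0.25
    weak_pass_threshold: float = 0.08
    strong_source_chi_ppm: float = 0.2
    method: str = "two_pass"

    def __post_init__(self) -> None:
        for name in ("tkd_threshold", "strong_pass_threshold", "weak_pass_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 2.0 / 3.0:
                raise ValueError(f"{name} must be in (0, 2/3], got {v}")
        if self.strong_source_chi_ppm <= 0:
            raise ValueError("strong_source_chi_ppm must be > 0")
        if self.method not in ("tkd_only", "two_pass"):
            raise ValueError(f"unknown inversion method {self.method!r}")


@dataclass(frozen=True)
class VoiGrid:
    """Sliding-window geometry for local vein detection.

    ``voi_shape_voxels`` is the window size (default 64 x 64 x 30),
    ``stride_voxels`` the step between window origins (default: half the
    window), ``threshold_sd_multiplier`` the vein cutoff in local SD units,
    ``min_vein_voxels`` the minimum vein-voxel count for a window to report
    a value.
    """

    voi_shape_voxels: tuple[int, int, int] = (64, 64, 30)
    stride_voxels: tuple[int, int, int] | None = None
    threshold_sd_multiplier: float = 2.0
    min_vein_voxels: int = 5
    min_tissue_voxels: int = 27
    allow_negative_delta_chi: bool = False

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.voi_shape_voxels)
        if len(shape) != 3 or any(s < 4 for s in shape):
            raise ValueError(f"voi_shape_voxels entries must be >= 4, got {shape}")
        stride = self.stride_voxels
        if stride is None:
            stride = tuple(max(1, s // 2) for s in shape)
        else:
            stride = tuple(int(s) for s in stride)
            if any(st < 1 or st > sh for st, sh in zip(stride, shape)):
                raise ValueError(f"stride must be in [1, shape] per axis, got {stride}")
        object.__setattr__(self, "voi_shape_voxels", shape)
        object.__setattr__(self, "stride_voxels", stride)
        if self.threshold_sd_multiplier <= 0:
            raise ValueError("threshold_sd_multiplier must be > 0")
        if self.min_vein_voxels < 1:
            raise ValueError("min_vein_voxels must be >= 1")


@dataclass(frozen=True)
class StatsParams:
    """Options of the group-comparison layer."""

    alpha_normality: float = 0.05
    use_welch: bool = False
    exact_mannwhitney_max_n: int = 25


@dataclass
class PipelineConfig:
    """Everything that influences a pipeline run, in one auditable place."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    vsharp: VsharpParams = field(default_factory=VsharpParams)
    inversion: InversionParams = field(default_factory=InversionParams)
    oef: OefParams = field(default_factory=OefParams)
    voi: VoiGrid = field(default_factory=VoiGrid)
    stats: StatsParams = field(default_factory=StatsParams)
    mask_threshold_fraction: float = 0.4
    mask_closing_radius: int = 2
    unwrap_pad_voxels: int = 16
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = {}
        sub = {
            "acquisition": AcquisitionParams,
            "vsharp": VsharpParams,
            "inversion": InversionParams,
            "oef": OefParams,
            "voi": VoiGrid,
            "stats": StatsParams,
        }
        for key, val in raw.items():
            if key in sub and isinstance(val, dict):
                val = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in val.items()
                }
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def validate_sequence_positive(name: str, values: Sequence[float]) -> None:
    if any(v <= 0 for v in values):
        raise ValueError(f"{name} entries must be positive, got {tuple(values)}")
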