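"""End-to-end reconstruction: phase -> field -> tissue field -> chi -> OEF.

``run_pipeline`` chains the stages in acquisition order — phase
normalization, masking, Laplacian unwrapping, phase-to-field scaling,
V-SHARP background removal, dipole inversion, sliding-window OEF mapping
and optional ROI extraction — and records a provenance log naming every
parameter and a content hash for every stage output.  Identical inputs and
config produce identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background_removal import vsharp
from .dipole_inversion import invert
from .oef import OefMap, roi_means, sliding_window_oef
from .params import PipelineConfig
from .phase_proc import BrainMask, PhaseVolume, laplacian_unwrap, make_mask, normalize_phase

logger = logging.getLogger(__name__)


def _hash(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    mask: BrainMask
    unwrapped_phase: PhaseVolume
    total_field_ppm: np.ndarray
    tissue_field_ppm: np.ndarray
    eroded_mask: BrainMask
    chi: np.ndarray
    oef_map: OefMap
    roi_table: pd.DataFrame | None
    provenance: list[dict] = field(default_factory=list)


def run_pipeline(
    config: PipelineConfig,
    phase_raw: np.ndarray,
    magnitude: np.ndarray,
    labels: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
    phase_dialect: str = "radians",
    mask: np.ndarray | None = None,
) -> PipelineResult:
    """Run every reconstruction stage on in-memory volumes.

    ``mask`` overrides magnitude-based masking (e.g. an external brain
    extraction).  Without ``labels`` the pipeline stops after the OEF map
    and ``roi_table`` is None.
    """
    logging.basicConfig(level=config.log_level)
    prov: list[dict] = []
    acq = config.acquisition

    def log_stage(name: str, output, **params):
        entry = {"stage": name, "hash": _hash(output), **params}
        prov.append(entry)
        logger.info("stage %s: %s", name, entry)

    phase = normalize_phase(phase_raw, dialect=phase_dialect)
    log_stage("normalize_phase", phase.values, dialect=phase_dialect)

    if mask is not None:
        brain = BrainMask(values=np.asarray(mask, dtype=bool))
        log_stage("mask", brain.values, source="external")
    else:
        brain = make_mask(magnitude, config.mask_threshold_fraction, config.mask_closing_radius)
        log_stage("mask", brain.values,
                  threshold_fraction=config.mask_threshold_fraction,
                  closing_radius=config.mask_closing_radius)

    try:
        unwrapped = laplacian_unwrap(phase, brain, acq.voxel_size_mm, config.unwrap_pad_voxels)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"stage laplacian_unwrap failed: {exc}") from exc
    log_stage("laplacian_unwrap", unwrapped.values, pad_voxels=config.unwrap_pad_voxels,
              voxel_size_mm=acq.voxel_size_mm)

    total_field = unwrapped.values / acq.phase_per_ppm
    log_stage("phase_to_field", total_field, b0_tesla=acq.b0_tesla,
              te_seconds=acq.te_seconds, b0_axis=acq.b0_axis)

    try:
        tissue_field, eroded = vsharp(total_field, brain, config.vsharp, acq.voxel_size_mm)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage vsharp failed: {exc}") from exc
    log_stage("vsharp", tissue_field, radii=config.vsharp.radii_voxels,
              tsvd_threshold=config.vsharp.tsvd_threshold)

    chi = invert(tissue_field, eroded, config.inversion, acq.voxel_size_mm, acq.b0_axis)
    log_stage("dipole_inversion", chi.chi_ppm, method=config.inversion.method,
              tkd_threshold=config.inversion.tkd_threshold,
              strong_pass_threshold=config.inversion.strong_pass_threshold,
              weak_pass_threshold=config.inversion.weak_pass_threshold,
              strong_source_chi_ppm=config.inversion.strong_source_chi_ppm)

    oef_map = sliding_window_oef(chi.chi_ppm, eroded.values, config.voi, config.oef)
    log_stage("oef_map", np.nan_to_num(oef_map.values),
              voi_shape=config.voi.voi_shape_voxels, stride=config.voi.stride_voxels,
              sd_multiplier=config.voi.threshold_sd_multiplier,
              hct=config.oef.hct, pv=config.oef.pv,
              delta_chi_do=config.oef.delta_chi_do, unit_system=config.oef.unit_system)

    table = None
    if labels is not None:
        table = roi_means(oef_map, labels, label_names)
        log_stage("roi_means", table.to_numpy(dtype=object).astype(str),
                  n_regions=len(table))
    else:
        logger.info("no label volume supplied; stopping after the OEF map")

    return PipelineResult(
        mask=brain, unwrapped_phase=unwrapped, total_field_ppm=total_field,
        tissue_field_ppm=tissue_field, eroded_mask=eroded, chi=chi.chi_ppm,
        oef_map=oef_map, roi_table=table, provenance=prov,
    )
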