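"""Vein-based oxygen extraction fraction mapping.

Veins carry more deoxyhemoglobin and hence higher magnetic susceptibility
than surrounding tissue.  Within a local volume of interest, venous voxels
are the in-mask voxels exceeding mean + k*SD of the local susceptibility
(one-sided: veins are paramagnetic, so only the upper tail is venous).
The vein-minus-tissue susceptibility difference delta_chi converts to OEF
via

    OEF = delta_chi * P_v / (delta_chi_do * Hct)

with P_v a global partial-volume correction factor.  A sliding window
repeats this over the whole brain; each window's scalar OEF is spread over
its in-mask voxels and overlaps are averaged.  Windows without enough vein
or tissue voxels — or with negative delta_chi, unless configured otherwise
— contribute nothing and voxels never covered by a defined window are NaN,
never silent zeros.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import OefParams, VoiGrid

Array = np.ndarray
logger = logging.getLogger(__name__)

_SD_EPS = 1e-12


@dataclass
class OefMap:
    """OEF as a fraction; undefined voxels are NaN, coverage in window_count."""

    values: Array
    window_count: Array

    @property
    def defined(self) -> Array:
        return np.isfinite(self.values)


def _voi_slices(bounds) -> tuple[slice, slice, slice]:
    return tuple(slice(int(lo), int(hi)) for lo, hi in bounds)


def detect_veins(chi: Array, mask: Array, voi_bounds, grid: VoiGrid = VoiGrid()) -> Array:
    """Venous voxels inside one VOI: chi > local mean + multiplier * SD.

    Mean and SD are over in-mask VOI voxels.  Returns a boolean array of
    the VOI shape; all-False when the VOI has fewer than 27 in-mask voxels
    or a degenerate (constant) susceptibility distribution.
    """
    sl = _voi_slices(voi_bounds)
    chi_v = np.asarray(chi)[sl]
    m_v = np.asarray(mask, dtype=bool)[sl]
    veins = np.zeros(chi_v.shape, dtype=bool)
    if m_v.sum() < 27:
        return veins
    vals = chi_v[m_v]
    sd = vals.std()
    if sd < _SD_EPS:
        return veins
    cutoff = vals.mean() + grid.threshold_sd_multiplier * sd
    veins[m_v] = chi_v[m_v] > cutoff
    return veins


def estimate_delta_chi(chi: Array, mask: Array, vein_mask: Array, voi_bounds,
                       min_tissue_voxels: int = 27) -> float:
    """Vein-minus-tissue mean susceptibility difference within one VOI.

    NaN when the vein mask is empty or too few non-vein in-mask voxels
    remain to define "surrounding tissue".
    """
    sl = _voi_slices(voi_bounds)
    chi_v = np.asarray(chi)[sl]
    m_v = np.asarray(mask, dtype=bool)[sl]
    veins = np.asarray(vein_mask, dtype=bool)
    if veins.shape != chi_v.shape:
        veins = veins[sl]
    veins = veins & m_v
    tissue = m_v & ~veins
    if veins.sum() == 0 or tissue.sum() < min_tissue_voxels:
        return float("nan")
    return float(chi_v[veins].mean() - chi_v[tissue].mean())


def oef_from_delta_chi(delta_chi: float, params: OefParams = OefParams()) -> float:
    """OEF fraction from the susceptibility difference (no clamping)."""
    if not np.isfinite(delta_chi):
        return float("nan")
    return float(delta_chi * params.pv / (params.delta_chi_do * params.hct))


def _window_starts(dim: int, shape: int, stride: int) -> list[int]:
    if shape >= dim:
        return [0]
    starts = list(range(0, dim - shape + 1, stride))
    if starts[-1] != dim - shape:
        starts.append(dim - shape)  # flush final window so the edge is covered
    return starts


def window_oef(chi: Array, mask: Array, voi_bounds,
               grid: VoiGrid = VoiGrid(), params: OefParams = OefParams()) -> float:
    """Scalar OEF of one VOI: detect veins, estimate delta_chi, apply the model."""
    veins = detect_veins(chi, mask, voi_bounds, grid)
    if veins.sum() < grid.min_vein_voxels:
        return float("nan")
    dchi = estimate_delta_chi(chi, mask, veins, voi_bounds, grid.min_tissue_voxels)
    if np.isfinite(dchi) and dchi < 0 and not grid.allow_negative_delta_chi:
        return float("nan")
    return oef_from_delta_chi(dchi, params)


def sliding_window_oef(chi: Array, mask: Array,
                       grid: VoiGrid = VoiGrid(),
                       params: OefParams = OefParams()) -> OefMap:
    """Whole-volume OEF map by sliding-VOI aggregation.

    Windows of ``grid.voi_shape_voxels`` step by ``grid.stride_voxels``
    (final windows flush with the edge).  Each defined window's scalar OEF
    is added to all its in-mask voxels; overlapping windows are resolved by
    the unweighted mean of defined values.
    """
    chi = np.asarray(chi, dtype=float)
    m = np.asarray(mask, dtype=bool)
    shape = grid.voi_shape_voxels
    stride = grid.stride_voxels
    acc = np.zeros(chi.shape)
    count = np.zeros(chi.shape, dtype=np.int32)
    n_defined = 0
    for i0 in _window_starts(chi.shape[0], shape[0], stride[0]):
        for j0 in _window_starts(chi.shape[1], shape[1], stride[1]):
            for k0 in _window_starts(chi.shape[2], shape[2], stride[2]):
                bounds = ((i0, min(i0 + shape[0], chi.shape[0])),
                          (j0, min(j0 + shape[1], chi.shape[1])),
                          (k0, min(k0 + shape[2], chi.shape[2])))
                oef = window_oef(chi, m, bounds, grid, params)
                if np.isfinite(oef):
                    sl = _voi_slices(bounds)
                    sel = m[sl]
                    acc[sl][sel] += oef
                    count[sl][sel] += 1
                    n_defined += 1
    if n_defined == 0:
        warnings.warn("no window produced a defined OEF value; map is all-undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(count > 0, acc / np.maximum(count, 1), np.nan)
    values = np.where(m, values, np.nan)
    return OefMap(values=values, window_count=count)


def roi_means(oef_map: OefMap, labels: Array, names: dict[int, str] | None = None,
              subject_id: str = "subject", percent: bool = True) -> pd.DataFrame:
    """Per-region mean OEF over defined voxels against an integer label map.

    Labels with no defined voxels are omitted with a warning.  Values are
    reported in percent by default, matching the convention of regional
    group tables.
    """
    labels = np.asarray(labels)
    if labels.shape != oef_map.values.shape:
        raise ValueError(
            f"label volume shape {labels.shape} does not match map {oef_map.values.shape}"
        )
    rows = []
    scale = 100.0 if percent else 1.0
    requested = sorted(names) if names else sorted(int(v) for v in np.unique(labels) if v != 0)
    present = set(int(v) for v in np.unique(labels))
    for code in requested:
        name = names.get(code, str(code)) if names else str(code)
        if code not in present:
            logger.warning("label %s (%s) absent from label volume; omitted", code, name)
            continue
        sel = (labels == code) & oef_map.defined
        n = int(sel.sum())
        if n == 0:
            logger.warning("label %s (%s) has no defined OEF voxels; omitted", code, name)
            continue
        rows.append((subject_id, name, scale * float(oef_map.values[sel].mean()), n))
    return pd.DataFrame(rows, columns=["subject_id", "region", "mean_oef", "n_voxels"])
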