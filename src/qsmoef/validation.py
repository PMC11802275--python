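"""Desk-scale validation experiments for the whole pipeline.

Each function builds a synthetic experiment from scratch — a phantom, a
simulated acquisition, or a simulated null cohort — runs the corresponding
pipeline stage(s), and returns summary metrics.  They are used both by the
test suite and by the repository's acceptance script, so every number they
return is recomputed at call time.

Problem sizes are chosen for single-CPU desk runs: 96-voxel grids for the
end-to-end phantom, 64-voxel grids for stage-level checks, 2000 replicates
for the statistical calibration.
"""

from __future__ import annotations

import numpy as np

from .background_removal import vsharp
from .dipole_inversion import star_invert, tkd_invert
from .oef import detect_veins, estimate_delta_chi, oef_from_delta_chi, sliding_window_oef
from .params import (
    AcquisitionParams,
    InversionParams,
    OefParams,
    VoiGrid,
    VsharpParams,
)
from .phantom import (
    add_vein,
    exterior_source_background,
    forward_field,
    harmonic_background,
    make_phantom,
    rasterization_pv,
    synthesize_phase,
)
from .phase_proc import BrainMask, PhaseVolume, laplacian_unwrap, normalize_phase
from .stats import choose_and_run_test, cohens_d_from_summary

#: Kernel-radius schedule used for 96-voxel phantom reconstructions: large
#: enough to average over several voxels, small enough to keep a usable
#: eroded mask on a desk-scale brain.
PHANTOM_RADII = (12, 10, 8, 6, 4)


def effect_size_reproduction() -> dict:
    """Recompute pooled-SD Cohen's d from the shipped group summaries."""
    from .reference import printed_effect_sizes, regional_summaries

    summaries = regional_summaries(reproducible_only=True)
    printed = printed_effect_sizes(reproducible_only=True)
    errors = {
        region: abs(cohens_d_from_summary(summaries[region]).d - printed[region])
        for region in printed
    }
    return {"per_region_error": errors,
            "max_abs_error": max(errors.values()),
            "n_regions": len(errors)}


def _three_vein_phantom():
    """96^3 phantom with slightly oblique veins at OEF 0.30 / 0.45 / 0.60."""
    ph = make_phantom((96, 96, 96), tissue_chi_ppm=0.02, voxel_size_mm=(1, 1, 1))
    oefs = (0.30, 0.45, 0.60)
    xs = (28, 48, 68)
    for x, o in zip(xs, oefs):
        add_vein(ph, ((x, 38, 0), (0, 0.2, 1)), 2.5, o)
    return ph, xs, oefs


def _per_vein_estimates(ph, chi, mask, xs, pvs):
    grid = VoiGrid(voi_shape_voxels=(32,) + ph.shape[1:])
    ests = []
    for x, pv in zip(xs, pvs):
        bounds = ((x - 16, x + 16), (0, ph.shape[1]), (0, ph.shape[2]))
        veins = detect_veins(chi, mask, bounds, grid)
        dchi = estimate_delta_chi(chi, mask, veins, bounds)
        ests.append(oef_from_delta_chi(dchi, OefParams(pv=pv)))
    return ests


def phantom_oef_recovery(seed: int = 0) -> dict:
    """End-to-end OEF recovery on truth chi and on the reconstructed chi.

    Truth path: vein detection and delta-chi estimation on the phantom's
    own susceptibility, with the rasterization-derived partial-volume
    factor (computed over the detected vein voxels).  Reconstructed path:
    wrapped phase with a harmonic background -> Laplacian unwrap -> V-SHARP
    -> two-pass inversion, noiseless, then the same estimator.
    """
    ph, xs, oefs = _three_vein_phantom()
    acq = AcquisitionParams(voxel_size_mm=(1.0, 1.0, 1.0))
    grid = VoiGrid(voi_shape_voxels=(32,) + ph.shape[1:])

    pvs = []
    for rec, x in zip(ph.vein_records, xs):
        bounds = ((x - 16, x + 16), (0, ph.shape[1]), (0, ph.shape[2]))
        veins = detect_veins(ph.chi_ppm, ph.brain_mask, bounds, grid)
        full = np.zeros(ph.shape, dtype=bool)
        full[tuple(slice(a, b) for a, b in bounds)] = veins
        pvs.append(rasterization_pv(rec, full))

    est_truth = _per_vein_estimates(ph, ph.chi_ppm, ph.brain_mask, xs, pvs)

    field = forward_field(ph)
    bg = exterior_source_background(ph, n_sources=8, amplitude_ppm=100.0, seed=seed)
    wrapped, _mag = synthesize_phase(field, acq, background_ppm=bg,
                                     mask=ph.brain_mask, seed=seed)
    bm = BrainMask(values=ph.brain_mask)
    unwrapped = laplacian_unwrap(normalize_phase(wrapped), bm, acq.voxel_size_mm, 16)
    total_field = unwrapped.values / acq.phase_per_ppm
    tissue, eroded = vsharp(total_field, bm, VsharpParams(radii_voxels=PHANTOM_RADII),
                            acq.voxel_size_mm)
    chi_rec = star_invert(tissue, eroded, InversionParams(), acq.voxel_size_mm, 2)
    est_recon = _per_vein_estimates(ph, chi_rec.chi_ppm, eroded.values, xs, pvs)

    def rel_errors(ests):
        return [abs(e - o) / o for e, o in zip(ests, oefs)]

    return {
        "oef_true": list(oefs),
        "pv_rasterization": pvs,
        "estimates_truth": est_truth,
        "estimates_recon": est_recon,
        "rel_error_truth": rel_errors(est_truth),
        "rel_error_recon": rel_errors(est_recon),
        "monotone_truth": bool(est_truth[0] < est_truth[1] < est_truth[2]),
        "monotone_recon": bool(est_recon[0] < est_recon[1] < est_recon[2]),
        "n_voxels": int(np.prod(ph.shape)),
    }


def background_removal_metrics(seed: int = 3) -> dict:
    """Suppression of an exterior-source field and preservation of a vein's."""
    ph = make_phantom((96, 96, 48), tissue_chi_ppm=0.0)
    add_vein(ph, ((48, 48, 0), (0, 0.2, 1)), 2.5, 0.6)
    vein_field = forward_field(ph)
    bg = exterior_source_background(ph, n_sources=10, amplitude_ppm=200.0, seed=seed)
    bg = bg + harmonic_background(ph.shape, {"x": 0.3, "yz": 0.2, "x2-y2": 0.1})
    params = VsharpParams(radii_voxels=PHANTOM_RADII)
    tissue_bg, eroded = vsharp(bg, ph.brain_mask, params, ph.voxel_size_mm)
    tissue_both, _ = vsharp(bg + vein_field, ph.brain_mask, params, ph.voxel_size_mm)
    em = eroded.values
    rms_in = float(np.sqrt(np.mean(bg[em] ** 2)))
    rms_out = float(np.sqrt(np.mean(tissue_bg[em] ** 2)))
    corr = float(np.corrcoef(tissue_both[em], vein_field[em])[0, 1])
    return {
        "background_rms_reduction": 1.0 - rms_out / rms_in,
        "vein_field_correlation": corr,
        "n_voxels": int(em.sum()),
    }


def inversion_roundtrip_metrics(seed: int = 5) -> dict:
    """Forward-inverse consistency of the dipole model on a 64^3 phantom."""
    ph = make_phantom((64, 64, 64), tissue_chi_ppm=0.0)
    rng = np.random.default_rng(seed)
    ph.chi_ppm = ph.chi_ppm + 0.01 * rng.standard_normal(ph.shape) * ph.brain_mask
    add_vein(ph, ((0, 32, 32), (1, 0, 0)), 2.5, 0.45)
    field = forward_field(ph)
    m = ph.brain_mask
    truth = ph.chi_ppm - ph.chi_ppm[m].mean()

    out = {}
    for name, rec in (("tkd", tkd_invert(field, m, threshold=0.1)),
                      ("star", star_invert(field, m))):
        r = rec.chi_ppm - rec.chi_ppm[m].mean()
        out[f"{name}_correlation"] = float(np.corrcoef(r[m], truth[m])[0, 1])
        out[f"{name}_slope"] = float(np.polyfit(truth[m], r[m], 1)[0])
    out["n_voxels"] = int(m.sum())
    return out


def unwrap_accuracy() -> dict:
    """RMS recovery error of a wrapped smooth 6*pi-peak phase on 64^3."""
    from ._spectral import wrap_phase

    n = 64
    ax = np.linspace(-1, 1, n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = x**2 + y**2 + z**2
    truth = 6 * np.pi * np.exp(-r2 / (2 * 0.35**2))
    mask = r2 < 0.7**2
    out = laplacian_unwrap(PhaseVolume(wrap_phase(truth), True), BrainMask(mask))
    diff = out.values - truth
    k = np.round(np.mean(diff[mask]) / (2 * np.pi))
    resid = diff[mask] - 2 * np.pi * k
    rms_rel = float(np.sqrt(np.mean(resid**2)) / np.sqrt(np.mean(truth[mask] ** 2)))
    return {"rms_relative_error": rms_rel, "n_voxels": int(mask.sum())}


def type_one_error(seed: int = 42, reps: int = 2000,
                   n_a: int = 15, n_b: int = 16, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the normality-screened comparison."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        res = choose_and_run_test(rng.standard_normal(n_a), rng.standard_normal(n_b))
        rejections += res.p < alpha
    return {"rate": rejections / reps, "reps": reps,
            "binomial_halfwidth": 1.96 * float(np.sqrt(alpha * (1 - alpha) / reps))}


def unit_equivalence() -> dict:
    """SI-ppm vs CGS configuration on consistently converted volumes."""
    ph = make_phantom((48, 48, 32), tissue_chi_ppm=0.02)
    add_vein(ph, ((24, 24, 0), (0, 0, 1)), 2.0, 0.45)
    grid = VoiGrid(voi_shape_voxels=ph.shape)
    si = sliding_window_oef(ph.chi_ppm, ph.brain_mask, grid, OefParams())
    chi_cgs = ph.chi_ppm * 1e-6 / (4 * np.pi)
    cgs = sliding_window_oef(chi_cgs, ph.brain_mask, grid, OefParams.cgs())
    sel = si.defined
    rel = float(np.max(np.abs(si.values[sel] - cgs.values[sel]) / np.abs(si.values[sel])))
    return {"max_relative_difference": rel, "n_voxels": int(sel.sum())}
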