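"""Vein detection, delta-chi estimation and sliding-window OEF mapping."""

import numpy as np
import pytest

from qsmoef import (
    OefMap,
    OefParams,
    VoiGrid,
    add_vein,
    detect_veins,
    estimate_delta_chi,
    make_phantom,
    oef_from_delta_chi,
    rasterization_pv,
    roi_means,
    sliding_window_oef,
    window_oef,
)
from qsmoef.params import DCHI_DO_SI_PPM


def _constructed_voi():
    """10x10x10 VOI: tissue at 0.02 ppm with a 40-voxel block at 0.48 ppm."""
    chi = np.full((10, 10, 10), 0.02)
    chi[3:8, 3:7, 4:6] = 0.48  # 5*4*2 = 40 voxels
    mask = np.ones(chi.shape, dtype=bool)
    bounds = ((0, 10), (0, 10), (0, 10))
    return chi, mask, bounds


class TestDetectVeins:
    def test_constant_voi_detects_nothing(self):
        chi = np.full((10, 10, 10), 0.02)
        veins = detect_veins(chi, np.ones(chi.shape, bool), ((0, 10), (0, 10), (0, 10)))
        assert veins.sum() == 0

    def test_threshold_isolates_high_chi_block(self):
        # brute-force check: exactly the block voxels exceed mean + 2 SD
        chi, mask, bounds = _constructed_voi()
        veins = detect_veins(chi, mask, bounds)
        expected = chi > 0.02
        vals = chi[mask]
        assert vals.mean() + 2 * vals.std() < 0.48
        np.testing.assert_array_equal(veins, expected)
        assert veins.sum() == 40

    def test_huge_multiplier_detects_nothing(self):
        chi, mask, bounds = _constructed_voi()
        grid = VoiGrid(voi_shape_voxels=(10, 10, 10), threshold_sd_multiplier=1e6)
        assert detect_veins(chi, mask, bounds, grid).sum() == 0

    def test_tiny_voi_flagged_empty(self):
        chi = np.full((10, 10, 10), 0.02)
        mask = np.zeros(chi.shape, bool)
        mask[0, 0, 0] = True
        assert detect_veins(chi, mask, ((0, 10), (0, 10), (0, 10))).sum() == 0


class TestEstimateDeltaChi:
    def test_two_population_difference(self):
        chi, mask, bounds = _constructed_voi()
        veins = detect_veins(chi, mask, bounds)
        assert estimate_delta_chi(chi, mask, veins, bounds) == pytest.approx(0.46)

    def test_all_vein_voi_undefined(self):
        chi, mask, bounds = _constructed_voi()
        veins = np.ones(chi.shape, bool)
        assert np.isnan(estimate_delta_chi(chi, mask, veins, bounds))

    def test_empty_vein_mask_undefined(self):
        chi, mask, bounds = _constructed_voi()
        assert np.isnan(estimate_delta_chi(chi, mask, np.zeros(chi.shape, bool), bounds))

    def test_shift_invariance(self):
        chi, mask, bounds = _constructed_voi()
        veins = detect_veins(chi, mask, bounds)
        d0 = estimate_delta_chi(chi, mask, veins, bounds)
        d1 = estimate_delta_chi(chi + 3.7, mask, veins, bounds)
        assert d1 == pytest.approx(d0)


class TestOefFromDeltaChi:
    def test_zero_delta_chi_zero_oef(self):
        assert oef_from_delta_chi(0.0) == 0.0

    def test_model_forward_evaluation(self):
        # delta_chi solved from the model at OEF 0.45, then forward-evaluated
        params = OefParams()
        dchi = 0.45 * params.delta_chi_do * params.hct / params.pv
        assert dchi == pytest.approx(0.076335, abs=5e-5)
        assert oef_from_delta_chi(dchi, params) == pytest.approx(0.45)

    def test_pv_linearity(self):
        p1 = OefParams(pv=6.0)
        p2 = OefParams(pv=12.0)
        assert oef_from_delta_chi(0.05, p2) == pytest.approx(2 * oef_from_delta_chi(0.05, p1))

    def test_nonfinite_delta_chi_undefined(self):
        assert np.isnan(oef_from_delta_chi(float("nan")))


class TestSlidingWindow:
    def test_single_window_constant_map(self, small_phantom):
        ph = small_phantom
        grid = VoiGrid(voi_shape_voxels=ph.shape)
        oef = window_oef(ph.chi_ppm, ph.brain_mask, tuple((0, n) for n in ph.shape), grid)
        m = sliding_window_oef(ph.chi_ppm, ph.brain_mask, grid)
        assert np.isfinite(oef)
        vals = m.values[ph.brain_mask]
        np.testing.assert_allclose(vals, oef)
        assert np.all(np.isnan(m.values[~ph.brain_mask]))

    def test_nonoverlapping_windows_match_window_oef(self):
        ph = make_phantom((64, 64, 32), tissue_chi_ppm=0.02)
        add_vein(ph, ((16, 32, 0), (0, 0, 1)), 2.5, 0.4)
        add_vein(ph, ((48, 32, 0), (0, 0, 1)), 2.5, 0.6)
        grid = VoiGrid(voi_shape_voxels=(32, 64, 32), stride_voxels=(32, 64, 32))
        m = sliding_window_oef(ph.chi_ppm, ph.brain_mask, grid)
        for x0 in (0, 32):
            bounds = ((x0, x0 + 32), (0, 64), (0, 32))
            expected = window_oef(ph.chi_ppm, ph.brain_mask, bounds, grid)
            sl = tuple(slice(a, b) for a, b in bounds)
            sel = ph.brain_mask[sl]
            np.testing.assert_allclose(m.values[sl][sel], expected)

    def test_overlap_average_and_window_count(self):
        ph = make_phantom((64, 64, 32), tissue_chi_ppm=0.02)
        add_vein(ph, ((32, 32, 0), (0, 0, 1)), 2.5, 0.45)
        grid = VoiGrid(voi_shape_voxels=(64, 64, 16), stride_voxels=(64, 64, 8))
        m = sliding_window_oef(ph.chi_ppm, ph.brain_mask, grid)
        assert m.window_count.max() >= 2  # overlapping z-windows

    def test_all_undefined_warns(self):
        chi = np.full((16, 16, 16), 0.02)
        mask = np.ones(chi.shape, bool)
        with pytest.warns(UserWarning, match="all-undefined"):
            m = sliding_window_oef(chi, mask, VoiGrid(voi_shape_voxels=(16, 16, 16)))
        assert np.all(~m.defined)

    def test_shift_invariance_and_scale_equivariance(self, small_phantom):
        ph = small_phantom
        grid = VoiGrid(voi_shape_voxels=ph.shape)
        base = sliding_window_oef(ph.chi_ppm, ph.brain_mask, grid)
        shifted = sliding_window_oef(ph.chi_ppm + 0.5, ph.brain_mask, grid)
        scaled = sliding_window_oef(3.0 * ph.chi_ppm, ph.brain_mask, grid)
        sel = base.defined
        np.testing.assert_allclose(shifted.values[sel], base.values[sel], rtol=1e-9)
        np.testing.assert_allclose(scaled.values[sel], 3.0 * base.values[sel], rtol=1e-9)

    def test_unit_system_equivalence(self, small_phantom):
        # CGS configuration on a consistently converted volume matches SI
        ph = small_phantom
        grid = VoiGrid(voi_shape_voxels=ph.shape)
        si = sliding_window_oef(ph.chi_ppm, ph.brain_mask, grid, OefParams())
        chi_cgs = ph.chi_ppm * 1e-6 / (4 * np.pi)
        cgs = sliding_window_oef(chi_cgs, ph.brain_mask, grid, OefParams.cgs())
        sel = si.defined
        np.testing.assert_allclose(cgs.values[sel], si.values[sel], rtol=1e-9)


class TestGroundTruthRecovery:
    def test_phantom_truth_oef_recovery(self):
        # estimator on phantom-truth chi with the rasterization-derived P_v
        ph = make_phantom((64, 64, 48), tissue_chi_ppm=0.02)
        add_vein(ph, ((32, 32, 0), (0, 0.2, 1)), 2.5, 0.45)
        grid = VoiGrid(voi_shape_voxels=ph.shape)
        bounds = tuple((0, n) for n in ph.shape)
        veins = detect_veins(ph.chi_ppm, ph.brain_mask, bounds, grid)
        full = np.zeros(ph.shape, bool)
        full[tuple(slice(a, b) for a, b in bounds)] = veins
        pv = rasterization_pv(ph.vein_records[0], full)
        dchi = estimate_delta_chi(ph.chi_ppm, ph.brain_mask, veins, bounds)
        est = oef_from_delta_chi(dchi, OefParams(pv=pv))
        assert est == pytest.approx(0.45, rel=0.10)


class TestRoiMeans:
    def _uniform_map(self, value=0.4, shape=(8, 8, 8)):
        vals = np.full(shape, value)
        return OefMap(values=vals, window_count=np.ones(shape, dtype=np.int32))

    def test_uniform_map_every_roi_equal(self):
        m = self._uniform_map(0.4)
        labels = np.zeros((8, 8, 8), int)
        labels[:4] = 1
        labels[4:] = 2
        table = roi_means(m, labels, {1: "left", 2: "right"})
        assert set(table.region) == {"left", "right"}
        assert np.allclose(table.mean_oef, 40.0)  # percent

    def test_split_labels_give_split_means(self):
        vals = np.full((8, 8, 8), 0.3)
        vals[4:] = 0.5
        m = OefMap(values=vals, window_count=np.ones(vals.shape, dtype=np.int32))
        labels = np.zeros(vals.shape, int)
        labels[:4] = 1
        labels[4:] = 2
        table = roi_means(m, labels, percent=False)
        assert table.set_index("region").loc["1", "mean_oef"] == pytest.approx(0.3)
        assert table.set_index("region").loc["2", "mean_oef"] == pytest.approx(0.5)

    def test_absent_label_omitted_with_warning(self, caplog):
        m = self._uniform_map()
        labels = np.ones((8, 8, 8), int)
        with caplog.at_level("WARNING"):
            table = roi_means(m, labels, {1: "present", 9: "absent"})
        assert list(table.region) == ["present"]
        assert "absent" in caplog.text

    def test_grid_mismatch_rejected(self):
        m = self._uniform_map()
        with pytest.raises(ValueError, match="shape"):
            roi_means(m, np.zeros((4, 4, 4), int))
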