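"""Phantom construction, forward dipole model and cohort simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qsmoef import (
    AcquisitionParams,
    CohortSpec,
    OefParams,
    add_vein,
    forward_field,
    harmonic_background,
    make_phantom,
    phase_from_field,
    rasterization_pv,
    simulate_cohort,
    synthesize_phase,
)
from qsmoef._spectral import dipole_kernel, wrap_phase


class TestMakePhantom:
    def test_zero_tissue_gives_zero_volume(self):
        ph = make_phantom((64, 64, 32), tissue_chi_ppm=0.0)
        assert np.all(ph.chi_ppm == 0)
        assert ph.brain_mask.sum() > 0

    def test_constant_tissue_inside_mask(self):
        ph = make_phantom((64, 64, 32), tissue_chi_ppm=0.02)
        assert np.all(ph.chi_ppm[ph.brain_mask] == 0.02)
        assert np.all(ph.chi_ppm[~ph.brain_mask] == 0)

    def test_mask_respects_margin(self):
        # brute-force scan of every mask voxel coordinate
        margin = 4
        ph = make_phantom((32, 40, 24), mask_margin_voxels=margin)
        coords = np.argwhere(ph.brain_mask)
        for ax, n in enumerate(ph.shape):
            assert coords[:, ax].min() >= margin
            assert coords[:, ax].max() <= n - 1 - margin

    def test_degenerate_grid_rejected_with_axis(self):
        with pytest.raises(ValueError, match="axis 2"):
            make_phantom((32, 32, 8))


class TestAddVein:
    def test_zero_oef_vein_is_invisible(self):
        ph = make_phantom((32, 32, 32), tissue_chi_ppm=0.02)
        add_vein(ph, ((16, 16, 0), (0, 0, 1)), 2.0, 0.0)
        assert np.all(ph.chi_ppm[ph.brain_mask] == 0.02)

    def test_vein_offset_is_dchi_hct_oef(self):
        # independent hand calculation: 0.45 * 0.45 * 2.262 ~= 0.458 ppm
        params = OefParams()
        ph = make_phantom((48, 48, 32), tissue_chi_ppm=0.02)
        add_vein(ph, ((24, 24, 0), (0, 0, 1)), 3.0, 0.45, params)
        rec = ph.vein_records[0]
        expected = params.delta_chi_do * 0.45 * 0.45
        assert rec.chi_offset_ppm == pytest.approx(expected)
        assert expected == pytest.approx(0.458, abs=5e-4)
        # voxels well inside the cylinder carry the full offset
        interior = ph.chi_ppm.max() - 0.02
        assert interior == pytest.approx(expected, rel=1e-9)
        # mean over recorded voxels is diluted only by edge partial volume
        mean_offset = ph.chi_ppm[tuple(rec.voxel_index.T)].mean() - 0.02
        assert mean_offset == pytest.approx(expected, rel=0.15)
        assert mean_offset < expected

    def test_nonoverlapping_vein_voxel_counts_add(self):
        ph = make_phantom((64, 64, 32), tissue_chi_ppm=0.0)
        add_vein(ph, ((20, 20, 0), (0, 0, 1)), 2.0, 0.3)
        add_vein(ph, ((44, 44, 0), (0, 0, 1)), 2.0, 0.3)
        n1 = len(ph.vein_records[0].voxel_index)
        n2 = len(ph.vein_records[1].voxel_index)
        assert ph.vein_mask().sum() == n1 + n2

    def test_vein_outside_mask_rejected(self):
        ph = make_phantom((32, 32, 32))
        with pytest.raises(ValueError, match="does not intersect"):
            add_vein(ph, ((1, 1, 0), (0, 0, 1)), 1.0, 0.5)

    def test_vein_groundtruth_bookkeeping(self, small_phantom):
        # single vein: mean chi over vein voxels minus tissue mean matches
        # the intravascular offset once the rasterization P_v is applied
        ph = small_phantom
        rec = ph.vein_records[0]
        vm = ph.vein_mask()
        tissue = ph.brain_mask & ~vm
        measured = ph.chi_ppm[vm].mean() - ph.chi_ppm[tissue].mean()
        assert measured * rasterization_pv(rec) == pytest.approx(
            rec.chi_offset_ppm, rel=0.02
        )

    def test_rasterization_pv_over_detected_mask(self, small_phantom):
        rec = small_phantom.vein_records[0]
        full = np.zeros(small_phantom.shape, dtype=bool)
        full[tuple(rec.voxel_index.T)] = True
        assert rasterization_pv(rec, full) == pytest.approx(rasterization_pv(rec))
        assert rasterization_pv(rec) > 1.0


class TestForwardField:
    def test_zero_chi_zero_field(self):
        assert np.allclose(forward_field(np.zeros((16, 16, 16))), 0)

    def test_dipole_kernel_pointwise(self):
        d = dipole_kernel((16, 16, 16), (1, 1, 1))
        assert d[0, 0, 0] == 0.0  # convention
        assert d[0, 0, 3] == pytest.approx(-2.0 / 3.0)  # on the B0 axis
        assert d[3, 2, 0] == pytest.approx(1.0 / 3.0)  # in the k_z = 0 plane
        assert d[1, 1, 1] == pytest.approx(0.0, abs=1e-15)  # magic angle

    def test_impulse_response_matches_direct_convolution(self):
        # oracle: explicit spatial-domain circular convolution on an 8^3 grid
        rng = np.random.default_rng(0)
        chi = rng.standard_normal((8, 8, 8))
        d = dipole_kernel((8, 8, 8), (1, 1, 1))
        kernel = np.fft.ifftn(d).real
        expected = np.zeros_like(chi)
        for u in np.ndindex(8, 8, 8):
            for v in np.ndindex(8, 8, 8):
                expected[v] += chi[u] * kernel[
                    (v[0] - u[0]) % 8, (v[1] - u[1]) % 8, (v[2] - u[2]) % 8
                ]
        np.testing.assert_allclose(forward_field(chi), expected, atol=1e-10)

    def test_impulse_field_signs(self):
        # paramagnetic point source: field positive along B0, negative in
        # the transverse plane (3cos^2(theta) - 1 pattern)
        chi = np.zeros((16, 16, 16))
        chi[8, 8, 8] = 1.0
        f = forward_field(chi)
        assert f[8, 8, 9] > 0  # along B0
        assert f[9, 8, 8] < 0  # in-plane ring

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((12, 12, 12))
        b = rng.standard_normal((12, 12, 12))
        lhs = forward_field(2.0 * a + 3.0 * b)
        rhs = 2.0 * forward_field(a) + 3.0 * forward_field(b)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestSynthesizePhase:
    def test_zero_field_zero_phase(self):
        acq = AcquisitionParams()
        wrapped, mag = synthesize_phase(np.zeros((8, 8, 8)), acq)
        assert np.allclose(wrapped, 0)
        assert np.allclose(mag, 1)

    def test_wrap_identity(self):
        assert wrap_phase(np.array(3 * np.pi / 2)) == pytest.approx(-np.pi / 2)

    def test_deterministic_under_seed(self):
        acq = AcquisitionParams()
        f = np.ones((8, 8, 8))
        w1, m1 = synthesize_phase(f, acq, noise_sd=0.1, seed=7)
        w2, m2 = synthesize_phase(f, acq, noise_sd=0.1, seed=7)
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(m1, m2)

    def test_phase_scale(self):
        # 1 ppm at 3 T / 14 ms: gamma*B0*TE*1e-6 radians
        acq = AcquisitionParams()
        f = np.full((8, 8, 8), 0.1)
        truth = phase_from_field(f, acq)
        assert truth[0, 0, 0] == pytest.approx(
            2.6752218744e8 * 3.0 * 0.014 * 0.1e-6
        )

    def test_harmonic_background_is_harmonic(self):
        # the discrete 7-point Laplacian is exact for quadratics, so it
        # must vanish identically on every basis term
        from scipy import ndimage

        bg = harmonic_background((32, 32, 32), {"x": 1.0, "xy": 0.5, "x2-y2": 0.25,
                                                "2z2-x2-y2": 0.3})
        lap = ndimage.laplace(bg)
        interior = lap[1:-1, 1:-1, 1:-1]
        assert np.abs(interior).max() < 1e-10 * np.abs(bg).max()


class TestSimulateCohort:
    def _spec(self, sd=5.0, seed=0):
        return CohortSpec(
            region_names=("r1", "r2"),
            group_a={"r1": (46.99, sd, 15), "r2": (40.0, sd, 15)},
            group_b={"r1": (54.20, sd, 16), "r2": (48.0, sd, 16)},
            labels=("apnea", "control"),
            seed=seed,
        )

    def test_zero_sd_gives_exact_means(self):
        table = simulate_cohort(self._spec(sd=0.0))
        r1a = table[(table.region == "r1") & (table.group == "apnea")]
        assert np.all(r1a.value == 46.99)

    def test_large_n_recovers_means(self):
        # law of large numbers at n scaled x1000
        spec = CohortSpec(
            region_names=("right_hemisphere",),
            group_a={"right_hemisphere": (46.99, 6.90, 15000)},
            group_b={"right_hemisphere": (54.20, 7.35, 16000)},
            seed=3,
        )
        table = simulate_cohort(spec)
        ga = table[table.group == "A"].value.mean()
        gb = table[table.group == "B"].value.mean()
        assert ga == pytest.approx(46.99, abs=0.1)
        assert gb == pytest.approx(54.20, abs=0.1)

    def test_same_seed_identical(self):
        t1 = simulate_cohort(self._spec(seed=5))
        t2 = simulate_cohort(self._spec(seed=5))
        assert t1.equals(t2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(region_names=("r",), group_a={"r": (1, -1, 5)},
                       group_b={"r": (1, 1, 5)})


@given(st.floats(-50, 50), st.integers(-8, 8))
def test_wrap_invariant_under_2pi_shifts(x, k):
    assert wrap_phase(np.array(x + 2 * np.pi * k)) == pytest.approx(
        float(wrap_phase(np.array(x))), abs=1e-9
    )
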