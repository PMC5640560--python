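import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hybridose as h
from hybridose.core import empty_volume
from hybridose.kernel import (
    infinite_medium_photon_energy,
    kernel_total_absorbed_energy,
    photon_point_dose,
    radial_absorbed_energy,
)
from hybridose.dose import dose_map_bruteforce
from hybridose.nuclide import DECAYS_PER_MBQ_H, J_PER_KEV


class TestKernel:
    def test_electron_only_self_value_hand_arithmetic(self, electron_only_nuclide):
        kern = h.build_kernel(electron_only_nuclide, 4.418, 2)
        # 100 keV/decay fully absorbed in the 0.08626 g source voxel
        mass_kg = (0.4418**3) / 1000.0
        expect_mGy = 100.0 * J_PER_KEV * DECAYS_PER_MBQ_H / mass_kg * 1000.0
        assert kern.k[kern.center] == pytest.approx(expect_mGy, rel=1e-12)
        assert kern.k_photon.max() == 0.0

    @given(st.tuples(st.integers(-10, 10), st.integers(-10, 10), st.integers(-10, 10)))
    @settings(max_examples=30, deadline=None)
    def test_central_symmetry(self, offset):
        kern = _small_kernel()
        c = kern.center
        a = kern.k[c[0] + offset[0], c[1] + offset[1], c[2] + offset[2]]
        b = kern.k[c[0] - offset[0], c[1] - offset[1], c[2] - offset[2]]
        assert a == b

    def test_center_is_maximum_and_nonnegative(self, kernel49):
        assert kernel49.k.min() >= 0.0
        assert kernel49.k.max() == kernel49.k[kernel49.center]

    def test_energy_bookkeeping_vs_radial_oracle(self, nuclide, kernel49):
        # photon energy within the inscribed sphere vs 1-D radial quadrature
        h_ext = 24
        ax = np.arange(-h_ext, h_ext + 1) * 0.4418
        DX, DY, DZ = np.meshgrid(ax, ax, ax, indexing="ij")
        r = np.sqrt(DX**2 + DY**2 + DZ**2)
        inside = r <= h_ext * 0.4418
        kernel_J = kernel49.k_photon[inside].sum() / 1e6 * kernel49.voxel_mass_g
        oracle_J = radial_absorbed_energy(nuclide, h_ext * 0.4418)
        assert kernel_J == pytest.approx(oracle_J, rel=0.10)
        # never exceeds the emitted photon energy (energy-conserving buildup)
        emitted = nuclide.photon_energy_keV_per_decay * J_PER_KEV * DECAYS_PER_MBQ_H
        assert kernel_total_absorbed_energy(kernel49) <= emitted * (1 + 1e-9)
        assert infinite_medium_photon_energy(nuclide) == pytest.approx(emitted, rel=1e-12)

    def test_grid_refinement_stability(self, nuclide):
        # halving the voxel changes the absorbed energy in a fixed sphere < 2%
        R_cm = 8.0

        def absorbed(voxel_mm, half):
            kern = h.build_kernel(nuclide, voxel_mm, half)
            ax = np.arange(-half, half + 1) * voxel_mm / 10.0
            DX, DY, DZ = np.meshgrid(ax, ax, ax, indexing="ij")
            r = np.sqrt(DX**2 + DY**2 + DZ**2)
            return kern.k_photon[r <= R_cm].sum() / 1e6 * kern.voxel_mass_g

        coarse = absorbed(4.418, 19)
        fine = absorbed(2.209, 38)
        assert fine == pytest.approx(coarse, rel=0.02)

    def test_invalid_inputs_rejected(self, nuclide):
        with pytest.raises(ValueError):
            h.build_kernel(nuclide, -1.0, 4)
        with pytest.raises(ValueError):
            h.build_kernel(nuclide, 4.418, 0)


class TestDoseMap:
    def test_impulse_response_is_kernel(self, kernel49):
        n = 49
        cum = empty_volume((n, n, n), 4.418, unit="MBq.h")
        cum.data[n // 2, n // 2, n // 2] = 1.0
        dm = h.dose_map(cum, kernel49)
        np.testing.assert_allclose(dm.data, kernel49.k, rtol=1e-9, atol=1e-12)

    def test_fft_matches_bruteforce_double_sum(self, nuclide, rng):
        kern = h.build_kernel(nuclide, 4.418, 6)
        cum = empty_volume((12, 12, 12), 4.418, unit="MBq.h")
        cum = cum.with_data(rng.random((12, 12, 12)))
        fft = h.dose_map(cum, kern)
        brute = dose_map_bruteforce(cum, kern)
        dev = np.abs(fft.data - brute.data) / brute.data.max()
        assert dev.max() < 1e-9

    def test_linearity(self, kernel49, rng):
        cum = empty_volume((20, 20, 20), 4.418, unit="MBq.h").with_data(
            rng.random((20, 20, 20))
        )
        d1 = h.dose_map(cum, kernel49)
        d2 = h.dose_map(cum.with_data(2 * cum.data), kernel49)
        np.testing.assert_allclose(d2.data, 2 * d1.data, rtol=1e-12)

    def test_voxel_mismatch_rejected(self, kernel49):
        cum = empty_volume((8, 8, 8), 2.0, unit="MBq.h")
        with pytest.raises(ValueError, match="mismatch"):
            h.dose_map(cum, kernel49)

    def test_energy_in_map_vs_kernel_escape(self, nuclide):
        # centered source on an enlarged grid: the map captures the kernel's
        # own infinite-medium integral up to < 5% boundary escape
        kern = h.build_kernel(nuclide, 4.418, 60)
        n = 121
        cum = empty_volume((n, n, n), 4.418, unit="MBq.h")
        cum.data[n // 2, n // 2, n // 2] = 1.0
        dm = h.dose_map(cum, kern)
        in_map = dm.data.sum() / 1e6 * kern.voxel_mass_g
        electron = nuclide.electron_energy_J_per_MBqh
        total_inf = infinite_medium_photon_energy(nuclide) + electron
        assert in_map <= total_inf * (1 + 1e-9)
        assert (total_inf - in_map) / total_inf < 0.05


class TestDVH:
    def test_uniform_dose_step_function(self):
        d = np.full((5, 5, 5), 3.0)
        out = h.dvh(d, np.ones((5, 5, 5), bool), n_bins=10)
        assert out.fraction_ge[0] == 1.0
        assert np.all(out.fraction_ge[out.dose_edges_mGy <= 3.0] == 1.0)

    def test_median_bin_half_volume(self, rng):
        d = rng.normal(10, 2, size=(12, 12, 12))
        mask = np.ones(d.shape, bool)
        out = h.dvh(d, mask, n_bins=200)
        med = np.median(d)
        i = np.searchsorted(out.dose_edges_mGy, med)
        assert out.fraction_ge[i] == pytest.approx(0.5, abs=0.02)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.exponential(5.0, size=(8, 8, 8))
        out = h.dvh(d, rng.random((8, 8, 8)) > 0.3, n_bins=50)
        assert np.all(np.diff(out.fraction_ge) <= 1e-12)
        assert out.fraction_ge[0] == 1.0

    def test_mean_from_dvh_matches_direct_mean(self, rng):
        d = rng.gamma(3.0, 2.0, size=(16, 16, 16))
        mask = np.ones(d.shape, bool)
        out = h.dvh(d, mask, n_bins=400)
        bin_w = out.dose_edges_mGy[1] - out.dose_edges_mGy[0]
        assert abs(out.mean_dose() - d.mean()) <= bin_w

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            h.dvh(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))


class TestDecomposition:
    def test_single_organ_all_self(self, kernel49):
        n = 49
        mask = np.zeros((n, n, n), bool)
        mask[20:28, 20:28, 20:28] = True
        grid = empty_volume((n, n, n), 4.418, unit="MBq.h")
        cum = grid.with_data(np.where(mask, 1.0 / mask.sum(), 0.0))
        res = h.organ_dose_decomposition({"organ": cum}, kernel49, {"organ": mask})
        row = res.per_roi.iloc[0]
        assert row.cross_dose_mGy_per_MBq == pytest.approx(0.0, abs=1e-15)
        assert row.self_dose_mGy_per_MBq == pytest.approx(row.mean_dose_mGy_per_MBq)

    def test_two_point_sources_cross_equals_kernel_value(self, kernel49):
        n = 49
        grid = empty_volume((n, n, n), 4.418, unit="MBq.h")
        mA = np.zeros((n, n, n), bool)
        mB = np.zeros((n, n, n), bool)
        mA[24, 24, 24] = True
        mB[30, 26, 20] = True
        a_tiac, b_tiac = 1.0, 2.5
        maps = {
            "A": grid.with_data(np.where(mA, a_tiac, 0.0)),
            "B": grid.with_data(np.where(mB, b_tiac, 0.0)),
        }
        res = h.organ_dose_decomposition(maps, kernel49, {"A": mA, "B": mB})
        cross_A = res.per_roi.set_index("label").loc["A", "cross_dose_mGy_per_MBq"]
        c = kernel49.center
        expect = b_tiac * kernel49.k[c[0] + 6, c[1] + 2, c[2] - 4]
        assert cross_A == pytest.approx(expect, rel=1e-9)

    def test_self_plus_cross_additivity(self, kernel49, rng):
        n = 49
        grid = empty_volume((n, n, n), 4.418, unit="MBq.h")
        m1 = rng.random((n, n, n)) > 0.9
        m2 = ~m1 & (rng.random((n, n, n)) > 0.9)
        maps = {
            "r1": grid.with_data(np.where(m1, 0.3 / m1.sum(), 0.0)),
            "r2": grid.with_data(np.where(m2, 0.7 / m2.sum(), 0.0)),
        }
        res = h.organ_dose_decomposition(maps, kernel49, {"r1": m1, "r2": m2})
        for _, row in res.per_roi.iterrows():
            assert row.self_dose_mGy_per_MBq + row.cross_dose_mGy_per_MBq == pytest.approx(
                row.mean_dose_mGy_per_MBq, rel=1e-12
            )


def _small_kernel(_cache={}):
    if "k" not in _cache:
        _cache["k"] = h.build_kernel(h.load_nuclide(), 4.418, 10)
    return _cache["k"]


def test_point_dose_positive_and_decreasing(nuclide):
    r = np.linspace(0.5, 40, 200)
    phi = photon_point_dose(r, nuclide)
    assert np.all(phi > 0)
    assert np.all(np.diff(phi) < 0)
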