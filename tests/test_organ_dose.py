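import numpy as np
import pytest

import hybridose as h
from hybridose.core import empty_volume
from hybridose.kernel import photon_point_dose
from hybridose.organ_dose import uniform_source_maps
from hybridose.tiac import TIACEntry, TIACTable


def build_masks(n=49, voxel=4.418):
    grid = empty_volume((n, n, n), voxel, unit="MBq.h")
    masks = {}
    m = np.zeros((n, n, n), bool)
    m[20:29, 20:29, 20:29] = True  # ~63 mL cube "organ A"
    masks["organ_a"] = m
    m2 = np.zeros((n, n, n), bool)
    m2[5:10, 22:27, 22:27] = True  # smaller distant "organ B"
    masks["organ_b"] = m2
    voxel_ml = grid.voxel_volume_ml
    masses = {k: v.sum() * voxel_ml for k, v in masks.items()}
    return grid, masks, masses


class TestDeriveSFactors:
    def test_cross_arm_self_consistency(self, kernel49):
        # organ-level dose from derived S equals the voxel-level mean dose
        # for uniform intra-organ activity, within 2%
        grid, masks, masses = build_masks()
        sf = h.derive_sfactors(masks, masses, kernel49, grid.spacing)
        t = TIACTable()
        t.add(TIACEntry("organ_a", 0.8))
        t.add(TIACEntry("organ_b", 0.3))
        report = h.organ_doses(t, sf)
        maps = uniform_source_maps(t, masks, grid)
        voxel = h.organ_dose_decomposition(maps, kernel49, masks)
        for lab in masks:
            d_organ = report.doses.set_index("label").loc[lab, "dose_mGy_per_MBq"]
            d_voxel = voxel.per_roi.set_index("label").loc[lab, "mean_dose_mGy_per_MBq"]
            assert d_organ == pytest.approx(d_voxel, rel=0.02), lab

    def test_distant_pair_matches_point_source_estimate(self, kernel49, nuclide):
        grid, masks, masses = build_masks()
        sf = h.derive_sfactors(masks, masses, kernel49, grid.spacing)
        # centers: organ_a (24,24,24), organ_b (7,24,24) -> 17 voxels apart
        r_cm = 17 * 0.4418
        phi = float(photon_point_dose(np.array([r_cm]), nuclide)[0])
        s_cross = float(sf.total.loc["organ_b", "organ_a"])
        assert s_cross == pytest.approx(phi, rel=0.25)
        # electron cross terms vanish (up to FFT roundoff)
        self_e = sf.electron.loc["organ_a", "organ_a"]
        assert abs(sf.electron.loc["organ_b", "organ_a"]) < 1e-12 * self_e

    def test_small_organ_self_dominated_by_electrons(self, kernel49):
        grid, masks, masses = build_masks()
        sf = h.derive_sfactors(masks, masses, kernel49, grid.spacing)
        lab = "organ_b"  # ~11 mL
        assert sf.electron.loc[lab, lab] > sf.photon.loc[lab, lab]

    def test_self_entries_exceed_cross(self, kernel49):
        grid, masks, masses = build_masks()
        sf = h.derive_sfactors(masks, masses, kernel49, grid.spacing)
        for t in masks:
            for s in masks:
                if s != t:
                    assert sf.total.loc[t, t] > sf.total.loc[t, s]


class TestAdaptMasses:
    def sf(self, kernel49):
        grid, masks, masses = build_masks()
        return h.derive_sfactors(masks, masses, kernel49, grid.spacing), masses

    def test_identity_at_reference_mass(self, kernel49):
        sf, masses = self.sf(kernel49)
        out = h.adapt_masses(sf, masses)
        assert np.allclose(out.total.values, sf.total.values)

    def test_half_mass_doubles_electron_self(self, kernel49):
        sf, masses = self.sf(kernel49)
        out = h.adapt_masses(sf, {"organ_a": masses["organ_a"] / 2})
        assert out.electron.loc["organ_a", "organ_a"] == pytest.approx(
            2 * sf.electron.loc["organ_a", "organ_a"]
        )

    def test_eighth_mass_quadruples_photon_self(self, kernel49):
        sf, masses = self.sf(kernel49)
        out = h.adapt_masses(sf, {"organ_a": masses["organ_a"] / 8})
        assert out.photon.loc["organ_a", "organ_a"] == pytest.approx(
            4 * sf.photon.loc["organ_a", "organ_a"]
        )
        # cross terms untouched
        assert out.photon.loc["organ_b", "organ_a"] == sf.photon.loc["organ_b", "organ_a"]

    def test_mass_scaling_monotonicity(self, kernel49):
        sf, masses = self.sf(kernel49)
        t = TIACTable()
        t.add(TIACEntry("organ_a", 1.0))
        doses = []
        for f in (0.5, 1.0, 2.0):
            adapted = h.adapt_masses(sf, {"organ_a": masses["organ_a"] * f})
            doses.append(
                h.organ_doses(t, adapted).doses.set_index("label").loc[
                    "organ_a", "dose_mGy_per_MBq"
                ]
            )
        assert doses[0] > doses[1] > doses[2]

    def test_nonpositive_mass_rejected(self, kernel49):
        sf, _ = self.sf(kernel49)
        with pytest.raises(ValueError):
            h.adapt_masses(sf, {"organ_a": 0.0})


class TestOrganDoses:
    def test_single_source_equals_self_s(self, kernel49):
        grid, masks, masses = build_masks()
        sf = h.derive_sfactors(masks, masses, kernel49, grid.spacing)
        t = TIACTable()
        t.add(TIACEntry("organ_a", 1.0))
        d = h.organ_doses(t, sf).doses.set_index("label")
        assert d.loc["organ_a", "dose_mGy_per_MBq"] == pytest.approx(
            float(sf.total.loc["organ_a", "organ_a"])
        )

    def test_linearity_in_tiacs(self, kernel49):
        grid, masks, masses = build_masks()
        sf = h.derive_sfactors(masks, masses, kernel49, grid.spacing)
        t1, t2 = TIACTable(), TIACTable()
        for lab, a in (("organ_a", 0.5), ("organ_b", 0.2)):
            t1.add(TIACEntry(lab, a))
            t2.add(TIACEntry(lab, 2 * a))
        d1 = h.organ_doses(t1, sf).doses.set_index("label")["dose_mGy_per_MBq"]
        d2 = h.organ_doses(t2, sf).doses.set_index("label")["dose_mGy_per_MBq"]
        assert np.allclose(d2.values, 2 * d1.values)

    def test_unmapped_source_rejected(self, kernel49):
        grid, masks, masses = build_masks()
        sf = h.derive_sfactors(masks, masses, kernel49, grid.spacing)
        t = TIACTable()
        t.add(TIACEntry("organ_a", 0.5))
        t.add(TIACEntry("mystery", 0.5))
        with pytest.raises(ValueError, match="mystery"):
            h.organ_doses(t, sf)


class TestSphereModel:
    def test_electron_only_dose_halves_with_doubled_mass(self, electron_only_nuclide):
        d1 = h.sphere_dose(50.0, 1.0, electron_only_nuclide)
        d2 = h.sphere_dose(100.0, 1.0, electron_only_nuclide)
        assert d1 == pytest.approx(2 * d2, rel=1e-6)

    def test_study_tumor_mass_range_computable(self, nuclide):
        # the pediatric study's tumor masses span 14-546 g
        for mass in (14.0, 546.0):
            assert h.sphere_dose(mass, 0.07, nuclide) > 0

    def test_out_of_range_mass_rejected(self, nuclide):
        with pytest.raises(ValueError, match="range"):
            h.sphere_dose(0.5, 0.1, nuclide)
        with pytest.raises(ValueError, match="range"):
            h.sphere_dose(1500.0, 0.1, nuclide)

    def test_sphere_model_excludes_cross_dose(self, kernel49, nuclide):
        # a tumor inside an active phantom: the sphere model (self only)
        # must not exceed the voxel-level total that includes cross dose
        n = 49
        grid = empty_volume((n, n, n), 4.418, unit="MBq.h")
        ax = [grid.origin[a] + (np.arange(n) + 0.5) * 4.418 for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        tumor = (X**2 + Y**2 + Z**2) <= 20**2
        liver = ((X - 55) ** 2 + Y**2 + Z**2) <= 45**2
        t = TIACTable()
        t.add(TIACEntry("tumor", 0.07))
        t.add(TIACEntry("liver", 0.56))
        maps = uniform_source_maps(t, {"tumor": tumor, "liver": liver}, grid)
        voxel = h.organ_dose_decomposition(maps, kernel49, {"tumor": tumor})
        total = voxel.per_roi.iloc[0].mean_dose_mGy_per_MBq
        mass_g = tumor.sum() * grid.voxel_volume_ml
        sphere = h.sphere_dose(mass_g, 0.07, nuclide)
        assert sphere < total
        # and agrees with the voxel self dose for the same mass
        self_d = voxel.per_roi.iloc[0].self_dose_mGy_per_MBq
        assert sphere == pytest.approx(self_d, rel=0.1)
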