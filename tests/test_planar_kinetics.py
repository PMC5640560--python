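import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hybridose as h
from hybridose.core import PlanarImage
from hybridose.nuclide import LN2
from hybridose.planar_kinetics import (
    ROI2D,
    background_corrected_counts,
    biological_half_life,
    build_tac,
    make_background_rind,
    resample_planar,
)

T_PHYS = 6.0067


def planar(data, pixel=4.418):
    return PlanarImage(np.asarray(data, dtype=float), (pixel, pixel))


class TestRoi50:
    def test_half_max_inclusive_threshold(self):
        img = planar([[10.0, 5.0, 4.0]])
        roi = h.make_roi50(img, np.array([[True, True, True]]))
        assert roi.mask.tolist() == [[True, True, False]]  # 5 >= 0.5*10, 4 < 5

    def test_uniform_region_kept_whole(self):
        img = planar(np.full((6, 6), 7.0))
        mask = np.zeros((6, 6), bool)
        mask[1:5, 1:5] = True
        roi = h.make_roi50(img, mask)
        assert np.array_equal(roi.mask, mask)

    def test_gaussian_blob_area_matches_half_max_disk(self):
        # area of the >= half-max disk is pi * (sigma*sqrt(2 ln 2))^2
        n, sigma = 101, 6.0
        y, x = np.mgrid[:n, :n] - n // 2
        img = planar(1000.0 * np.exp(-(x**2 + y**2) / (2 * sigma**2)))
        roi = h.make_roi50(img, np.ones((n, n), bool))
        expect = np.pi * (sigma * np.sqrt(2 * np.log(2))) ** 2
        assert roi.mask.sum() == pytest.approx(expect, rel=0.05)

    def test_all_zero_region_rejected(self):
        img = planar(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="signal"):
            h.make_roi50(img, np.ones((4, 4), bool))


class TestPropagation:
    def blob(self, shift=(0, 0), scale=1.0, n=48):
        y, x = np.mgrid[:n, :n]
        img = scale * 1000.0 * np.exp(
            -((x - 20 - shift[1]) ** 2 + (y - 24 - shift[0]) ** 2) / 18.0
        )
        return planar(img)

    def roi(self):
        ref = self.blob()
        mask = ref.data >= 0.5 * ref.data.max()
        return h.make_roi50(ref, mask | True if False else np.asarray(ref.data > 100))

    def test_identical_images_zero_shift(self):
        ref = self.blob()
        roi = h.make_roi50(ref, ref.data > 100)
        (moved, flag), = h.propagate_roi(roi, ref, [ref])
        assert np.array_equal(moved.mask, roi.mask) and not flag

    def test_constructed_shift_recovered(self):
        ref = self.blob()
        roi = h.make_roi50(ref, ref.data > 100)
        shifted = self.blob(shift=(3, -2))
        (moved, flag), = h.propagate_roi(roi, ref, [shifted])
        assert np.array_equal(moved.mask, np.roll(roi.mask, (3, -2), axis=(0, 1)))
        assert not flag

    def test_decayed_image_zero_shift(self):
        # NCC is scale-invariant: a x0.5 decayed frame must not move the ROI
        ref = self.blob()
        roi = h.make_roi50(ref, ref.data > 100)
        (moved, _), = h.propagate_roi(roi, ref, [self.blob(scale=0.5)])
        assert np.array_equal(moved.mask, roi.mask)

    def test_dialect_resampling_conserves_counts(self):
        img = self.blob()
        out = resample_planar(img, 2.21)
        assert out.pixel_mm == (2.21, 2.21)
        assert out.total() == pytest.approx(img.total(), rel=1e-9)


class TestBackgroundCorrection:
    def test_arithmetic(self):
        img = planar(np.zeros((10, 10)))
        img.data[:5, :10] = 20.0  # ROI region: 50 px x 20 = 1000 total
        img.data[6:8, :] = 4.0
        roi = ROI2D("t", img.data == 20.0, background=img.data == 4.0)
        corrected, raw, bg, clipped = background_corrected_counts(img, roi)
        assert raw == 1000.0 and bg == 4.0
        assert corrected == 1000.0 - 4.0 * 50
        assert not clipped

    def test_zero_background_returns_raw(self):
        img = planar(np.zeros((6, 6)))
        img.data[0, :3] = 5.0
        roi = ROI2D("t", img.data > 0, background=np.roll(img.data > 0, 3, axis=0))
        corrected, raw, *_ = background_corrected_counts(img, roi)
        assert corrected == raw

    def test_negative_result_floored_with_flag(self):
        img = planar(np.ones((6, 6)))
        mask = np.zeros((6, 6), bool)
        mask[0, :2] = True
        bg = np.zeros((6, 6), bool)
        bg[3, :] = True
        img.data[3, :] = 50.0
        corrected, _, _, clipped = background_corrected_counts(img, ROI2D("t", mask, bg))
        assert corrected == 0.0 and clipped

    def test_empty_background_rejected(self):
        img = planar(np.ones((4, 4)))
        roi = ROI2D("t", np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="background"):
            background_corrected_counts(img, roi)

    def test_corrected_counts_isolate_organ_over_body(self):
        # organ over a uniform body: correction recovers the organ-only
        # projection counts within 5% (noiseless)
        from hybridose.core import empty_volume

        n = 48
        vol = empty_volume((n, n, n), 4.418, unit="MBq")
        ax = [vol.origin[a] + (np.arange(n) + 0.5) * 4.418 for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        organ = (((X - 20) / 30) ** 2 + (Y / 25) ** 2 + (Z / 30) ** 2) <= 1
        body = (X**2 + Y**2) <= 90**2
        acq = h.AcquisitionSpec(rng_seed=0, poisson=False, attenuation=False)
        organ_act = vol.with_data(np.where(organ, 10.0 / organ.sum(), 0.0))
        both = vol.with_data(organ_act.data + np.where(body & ~organ, 5e-4, 0.0))
        ant_organ, _ = h.simulate_planar(organ_act, None, acq)
        ant_both, _ = h.simulate_planar(both, None, acq)
        proj = organ.any(axis=1)
        oversized = proj.copy()
        bg = make_background_rind(oversized, gap_px=3, width_px=3)
        roi = h.make_roi50(ant_both, oversized, background=bg)
        corrected, *_ = background_corrected_counts(ant_both, roi)
        truth = ant_organ.data[roi.mask].sum()
        assert corrected == pytest.approx(truth, rel=0.05)


class TestMonoExponentialFit:
    def tac(self, times, counts):
        t = np.asarray(times, float)
        mask = np.ones((3, 3), bool)
        mask[2, 2] = False
        bg = ~mask
        images = []
        for v in np.asarray(counts, float):
            arr = np.zeros((3, 3))
            arr[mask] = v / mask.sum()
            images.append(planar(arr))
        return build_tac("t", t, images, [ROI2D("t", mask, bg)] * len(images))

    def test_two_point_exact_solution(self, nuclide):
        fit = h.fit_monoexponential(self.tac([1.0, 5.0], [100.0, 50.0]), nuclide)
        assert fit.T_eff_h == pytest.approx(4.0, rel=1e-12)
        assert fit.A0 == pytest.approx(100.0 * 2 ** (1 / 4.0), rel=1e-12)

    def test_t_bio_symmetry_point(self):
        # T_eff = T_phys/2  ->  T_bio = T_phys
        assert biological_half_life(T_PHYS / 2, T_PHYS) == pytest.approx(T_PHYS)

    def test_spleen_like_accumulation_flagged(self, nuclide):
        c0 = 1000.0
        counts = [c0 * 2 ** (-t / 8.22) for t in (2, 5, 22)]
        fit = h.fit_monoexponential(self.tac([2, 5, 22], counts), nuclide)
        assert fit.T_eff_h == pytest.approx(8.22, rel=1e-9)
        assert fit.T_bio_h < 0
        assert "accumulation" in fit.flags

    def test_t_bio_infinite_at_physical_half_life(self):
        assert biological_half_life(T_PHYS, T_PHYS) == np.inf

    @given(st.floats(0.1, T_PHYS - 0.01), st.floats(0.1, T_PHYS - 0.01))
    @settings(max_examples=50, deadline=None)
    def test_t_bio_monotone_decreasing_below_physical(self, t1, t2):
        lo, hi = sorted((t1, t2))
        if hi - lo > 1e-9:
            assert biological_half_life(hi, T_PHYS) >= biological_half_life(lo, T_PHYS)

    def test_noiseless_recovery_to_machine_precision(self, nuclide):
        A0, T_eff = 5000.0, 3.7
        times = [1.5, 4.0, 22.0]
        counts = [A0 * 2 ** (-t / T_eff) for t in times]
        fit = h.fit_monoexponential(self.tac(times, counts), nuclide)
        assert fit.T_eff_h == pytest.approx(T_eff, rel=1e-9)
        assert fit.A0 == pytest.approx(A0, rel=1e-9)

    def test_poisson_recovery_within_15pct_for_95pct_of_seeds(self, nuclide):
        # >= 1e4 ROI counts: T_eff within 15% in at least 95% of 200 seeds
        A0, T_eff = 3e4, 4.5
        times = np.array([2.0, 5.0, 22.0])
        expected = A0 * 2 ** (-times / T_eff)
        ok = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(expected)
            fit = h.fit_monoexponential(self.tac(times, counts), nuclide)
            ok += abs(fit.T_eff_h - T_eff) / T_eff <= 0.15
        assert ok >= 190

    def test_nonpositive_point_excluded_with_warning(self, nuclide):
        fit = h.fit_monoexponential(self.tac([1, 3, 6], [100.0, 0.0, 30.0]), nuclide)
        assert "nonpositive_points_excluded" in fit.flags

    def test_fewer_than_two_usable_points_rejected(self, nuclide):
        with pytest.raises(ValueError, match="usable"):
            h.fit_monoexponential(self.tac([1, 3], [100.0, 0.0]), nuclide)


def _corner():
    m = np.zeros((3, 3), bool)
    m[0, 0] = False
    m[2, 2] = True
    return m
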