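"""Segmentation, recruitment, lipid order φ, condensates, granulosity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvphase import imaging, synth
from guvphase.errors import (
    DivisionByZeroError,
    EmptyMaskError,
    NoForegroundError,
    ParameterError,
    UndefinedIndexError,
)
from guvphase.imaging import ImageChannel, RegionMask
from guvphase.synth import SynthConfig


def _channel(array, px=0.1):
    return ImageChannel(np.asarray(array, dtype=float), px)


class TestSegmentGuv:
    def test_all_zero_image_has_no_foreground(self):
        with pytest.raises(NoForegroundError):
            imaging.segment_guv(_channel(np.zeros((64, 64))))

    def test_noise_free_ring_mask_area_tracks_truth(self, quiet_cfg):
        membrane, _, truth = synth.make_guv_image(quiet_cfg)
        mask = imaging.segment_guv(membrane)
        assert mask.area_um2 == pytest.approx(truth["ring_area_um2"], rel=0.15)

    def test_otsu_mask_invariant_to_additive_offset(self, noisy_cfg):
        membrane, _, _ = synth.make_guv_image(noisy_cfg)
        mask = imaging.segment_guv(membrane)
        shifted = ImageChannel(membrane.intensities + 37.0, membrane.pixel_size_um)
        mask2 = imaging.segment_guv(shifted)
        np.testing.assert_array_equal(mask.flags, mask2.flags)

    def test_mask_translates_with_the_image(self, noisy_cfg):
        membrane, _, _ = synth.make_guv_image(noisy_cfg)
        mask = imaging.segment_guv(membrane)
        rolled = ImageChannel(np.roll(membrane.intensities, (5, -7), axis=(0, 1)),
                              membrane.pixel_size_um)
        mask2 = imaging.segment_guv(rolled)
        # compare away from the wrap seam
        np.testing.assert_array_equal(
            np.roll(mask.flags, (5, -7), axis=(0, 1))[10:-10, 10:-10],
            mask2.flags[10:-10, 10:-10])

    def test_fixed_threshold_mode(self):
        img = np.zeros((32, 32))
        img[10:20, 10:20] = 100.0
        mask = imaging.segment_guv(_channel(img), blur_sigma_px=0.0,
                                   threshold_method="fixed", fixed_value=50.0)
        assert mask.n_pixels == 100


class TestRecruitment:
    def test_uniform_intensity_gives_that_mean(self):
        mask = RegionMask(np.ones((8, 8), dtype=bool), 0.1)
        measure = imaging.quantify_recruitment(_channel(np.full((8, 8), 7.5)), mask)
        assert measure.intensity_per_area == pytest.approx(7.5)
        assert measure.integrated_intensity == pytest.approx(7.5 * 64)

    def test_single_pixel_mask(self):
        img = np.zeros((8, 8))
        img[3, 4] = 42.0
        flags = np.zeros((8, 8), dtype=bool)
        flags[3, 4] = True
        measure = imaging.quantify_recruitment(_channel(img), RegionMask(flags, 0.1))
        assert measure.integrated_intensity == 42.0
        assert measure.intensity_per_area == 42.0

    def test_doubling_coat_doubles_recruitment(self, quiet_cfg):
        membrane, p100, _ = synth.make_guv_image(quiet_cfg, coat_amplitude=100.0)
        _, p200, _ = synth.make_guv_image(quiet_cfg, coat_amplitude=200.0)
        mask = imaging.segment_guv(membrane)
        bg = quiet_cfg.background_level
        m100 = imaging.quantify_recruitment(p100, mask).intensity_per_area - bg
        m200 = imaging.quantify_recruitment(p200, mask).intensity_per_area - bg
        assert m200 == pytest.approx(2.0 * m100, rel=1e-9)

    def test_empty_mask_raises(self):
        mask = RegionMask(np.zeros((8, 8), dtype=bool), 0.1)
        with pytest.raises(EmptyMaskError):
            imaging.quantify_recruitment(_channel(np.ones((8, 8))), mask)


class TestComputePhi:
    def test_identical_windows_give_unity(self):
        img = np.full((16, 16), 5.0)
        mask = RegionMask(np.ones((16, 16), dtype=bool), 0.1)
        assert imaging.compute_phi(_channel(img), _channel(img), mask).phi == 1.0

    def test_double_blue_gives_two(self):
        red = np.full((16, 16), 5.0)
        mask = RegionMask(np.ones((16, 16), dtype=bool), 0.1)
        result = imaging.compute_phi(_channel(2 * red), _channel(red), mask)
        assert result.phi == pytest.approx(2.0)

    def test_zero_red_sum_raises(self):
        mask = RegionMask(np.ones((8, 8), dtype=bool), 0.1)
        with pytest.raises(DivisionByZeroError):
            imaging.compute_phi(_channel(np.ones((8, 8))), _channel(np.zeros((8, 8))), mask)

    def test_synthetic_phi_recovered_at_default_snr(self):
        blue, red, marker, truth = synth.make_pk_image(SynthConfig(seed=11),
                                                       true_phi=1.4)
        mask = imaging.segment_guv(marker)
        result = imaging.compute_phi(blue, red, mask)
        assert result.phi == pytest.approx(truth["true_phi"], rel=0.05)

    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_phi_invariant_to_joint_rescaling(self, scale):
        rng = np.random.default_rng(0)
        blue = rng.uniform(1, 10, (12, 12))
        red = rng.uniform(1, 10, (12, 12))
        mask = RegionMask(np.ones((12, 12), dtype=bool), 0.1)
        phi0 = imaging.compute_phi(_channel(blue), _channel(red), mask).phi
        phi1 = imaging.compute_phi(_channel(scale * blue), _channel(scale * red), mask).phi
        assert phi1 == pytest.approx(phi0, rel=1e-9)

    def test_ratio_map_zeroed_outside_mask(self):
        blue = np.full((8, 8), 4.0)
        red = np.full((8, 8), 2.0)
        flags = np.zeros((8, 8), dtype=bool)
        flags[2:6, 2:6] = True
        result = imaging.compute_phi(_channel(blue), _channel(red),
                                     RegionMask(flags, 0.1))
        assert np.all(result.ratio_map[~flags] == 0)
        assert np.all(result.ratio_map[flags] == 2.0)


class TestComputePhiLive:
    def _scene(self, phis=(1.2, 1.6), bg=(0.0, 0.0)):
        blue = np.full((32, 32), bg[0])
        red = np.full((32, 32), bg[1])
        regions = []
        for i, phi in enumerate(phis):
            flags = np.zeros((32, 32), dtype=bool)
            flags[2 + 10 * i: 8 + 10 * i, 4:12] = True
            red[flags] = 50.0 + bg[1]
            blue[flags] = 50.0 * phi + bg[0]
            regions.append(RegionMask(flags, 0.1))
        bg_flags = np.zeros((32, 32), dtype=bool)
        bg_flags[28:, 28:] = True
        return (_channel(blue), _channel(red), regions, RegionMask(bg_flags, 0.1))

    def test_zero_background_matches_compute_phi(self):
        blue, red, regions, bg_region = self._scene()
        live = imaging.compute_phi_live(blue, red, regions, bg_region)
        for region, result in zip(regions, live):
            plain = imaging.compute_phi(blue, red, region)
            assert result.phi == pytest.approx(plain.phi, rel=1e-12)

    def test_uniform_offset_cancels(self):
        ref = imaging.compute_phi_live(*self._scene(bg=(0.0, 0.0)))
        off = imaging.compute_phi_live(*self._scene(bg=(13.0, 13.0)))
        for a, b in zip(ref, off):
            assert b.phi == pytest.approx(a.phi, rel=1e-9)

    def test_two_region_truth_recovered(self):
        live = imaging.compute_phi_live(*self._scene(phis=(1.2, 1.6)))
        assert live[0].phi == pytest.approx(1.2, rel=0.05)
        assert live[1].phi == pytest.approx(1.6, rel=0.05)

    def test_dark_region_flagged_invalid_not_dropped(self):
        blue, red, regions, bg_region = self._scene(phis=(1.2, 1.6))
        dark = np.zeros((32, 32), dtype=bool)
        dark[20:24, 20:24] = True  # no signal above background there
        results = imaging.compute_phi_live(blue, red, regions + [RegionMask(dark, 0.1)],
                                           bg_region)
        assert len(results) == 3
        assert not results[2].valid
        assert np.isnan(results[2].phi)

    def test_overlapping_background_rejected(self):
        blue, red, regions, _ = self._scene()
        with pytest.raises(ParameterError):
            imaging.compute_phi_live(blue, red, regions, regions[0])


class TestDetectCondensates:
    def test_blank_field_gives_empty_list(self):
        assert imaging.detect_condensates(_channel(np.full((32, 32), 3.0))) == []

    def test_count_and_areas_exact_on_noise_free_field(self):
        cfg = SynthConfig(seed=5, noise_sd=0.0)
        field, truth = synth.make_condensate_field(cfg, n=30, area_um2_mean=0.6)
        found = imaging.detect_condensates(field)
        assert len(found) == 30
        assert sum(c.area_um2 for c in found) == pytest.approx(
            sum(truth["areas_um2"]), abs=1e-9)
        px_area = cfg.pixel_size_um ** 2
        for c in found:
            assert abs(c.area_um2 - 0.6) <= px_area

    def test_overlapping_disks_merge_into_one_component(self):
        img = np.zeros((32, 32))
        rows, cols = np.indices((32, 32))
        img[(rows - 15) ** 2 + (cols - 12) ** 2 <= 25] = 100.0
        img[(rows - 15) ** 2 + (cols - 18) ** 2 <= 25] = 100.0
        found = imaging.detect_condensates(_channel(img))
        assert len(found) == 1

    def test_min_area_filter(self):
        cfg = SynthConfig(seed=5, noise_sd=0.0)
        field, _ = synth.make_condensate_field(cfg, n=10, area_um2_mean=0.6)
        assert imaging.detect_condensates(field, min_area_um2=1.0) == []


class TestGranulosity:
    def test_constant_image_has_zero_index(self):
        result = imaging.granulosity_index(_channel(np.full((64, 64), 5.0)), 6.0)
        assert result.index == pytest.approx(0.0, abs=1e-12)

    @given(alpha=st.floats(min_value=0.05, max_value=40.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, alpha):
        rng = np.random.default_rng(2)
        img = 20 + 5 * rng.random((64, 64))
        g1 = imaging.granulosity_index(_channel(img), 6.0).index
        g2 = imaging.granulosity_index(_channel(alpha * img), 6.0).index
        assert g2 == pytest.approx(g1, rel=1e-9)

    def test_fft_route_matches_dft_matrix_oracle(self, rng):
        """The FFT high-pass agrees with an explicit DFT-matrix evaluation
        of the same filter to 1e-6 relative on 64x64 images."""
        img = 50 + 10 * rng.random((64, 64))
        ours = imaging.highpass_filter(img, 6.0)
        n = 64
        w = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        spectrum = w @ img @ w
        f = np.fft.fftfreq(n) * n
        keep = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2) >= 6.0
        keep[0, 0] = True
        oracle = ((w.conj() @ (spectrum * keep) @ w.conj()) / n**2).real
        assert np.abs(ours - oracle).max() <= 1e-6 * np.abs(oracle).max()

    def test_condensate_rich_field_beats_uniform_field(self):
        cfg = SynthConfig(seed=6, noise_sd=0.0)
        field, _ = synth.make_condensate_field(cfg, n=30, area_um2_mean=0.6)
        uniform = np.full(field.shape, field.intensities.mean())
        g_rich = imaging.granulosity_index(field, 8.0).index
        g_flat = imaging.granulosity_index(_channel(uniform), 8.0).index
        assert g_rich > g_flat

    def test_monotone_in_highfrequency_texture_amplitude(self):
        rng = np.random.default_rng(9)
        texture = rng.normal(size=(64, 64))
        texture -= texture.mean()
        base = np.full((64, 64), 50.0)
        last = -1.0
        for amp in (0.0, 1.0, 3.0, 9.0):
            img = np.clip(base + amp * texture, 0, None)
            g = imaging.granulosity_index(_channel(img), 6.0).index
            assert g >= last
            last = g

    def test_negative_mean_after_background_subtraction_raises(self):
        with pytest.raises(UndefinedIndexError):
            imaging.granulosity_index(_channel(np.full((64, 64), 5.0)), 6.0,
                                      background=10.0)
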