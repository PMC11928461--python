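"""IR preprocessing, second-derivative peak calling, amide-I fractions."""

import numpy as np
import pytest

from guvphase import spectra as sp
from guvphase import synth
from guvphase.errors import NoPeakError, NoSignalError, ParameterError
from guvphase.imaging import ImageChannel
from guvphase.spectra import Spectrum
from guvphase.synth import Band, SynthConfig


def _pipeline(spectrum, mode="afmir"):
    return sp.second_derivative(sp.preprocess(spectrum, mode), mode)


def _lorentzian_spectrum(cfg, centre, fwhm=20.0, mode="afmir"):
    spec, _ = synth.make_spectrum(cfg, bands=[Band(centre, fwhm, 1.0, "lorentzian")],
                                  instrument=mode, noise_sd=0.0)
    return spec


class TestPreprocess:
    def test_constant_spectrum_unchanged_up_to_normalization(self):
        grid = np.arange(1400.0, 1795.0, 2.0)
        out = sp.preprocess(Spectrum(grid, np.full(grid.shape, 3.0)), "afmir")
        np.testing.assert_allclose(out.absorbance, 1.0, atol=1e-12)

    @pytest.mark.parametrize("mode", ["afmir", "ftir"])
    def test_normalized_maximum_is_one(self, quiet_cfg, mode):
        spec, _ = synth.make_spectrum(quiet_cfg, phase="liquid", instrument=mode)
        out = sp.preprocess(spec, mode)
        assert out.absorbance.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["afmir", "ftir"])
    def test_smoothing_preserves_symmetric_peak_position(self, quiet_cfg, mode):
        spec = _lorentzian_spectrum(quiet_cfg, 1746.0, mode=mode)
        out = sp.preprocess(spec, mode)
        idx = np.argmax(out.absorbance)
        assert abs(out.wavenumbers_cm1[idx] - 1746.0) <= spec.step_cm1

    def test_too_few_points_raises(self):
        grid = np.arange(1400.0, 1795.0, 2.0)[:5]
        with pytest.raises(ParameterError):
            sp.preprocess(Spectrum(grid, np.ones(5)), "afmir")


class TestSecondDerivative:
    def test_quadratic_gives_constant_second_derivative(self):
        """Order-2 SG derivatives are exact on polynomials of degree 2."""
        grid = np.arange(1400.0, 1795.0, 2.0)
        a = 3e-4
        spec = Spectrum(grid, a * (grid - 1600.0) ** 2, instrument="ftir")
        d2 = sp.second_derivative(spec, "ftir")
        interior = slice(6, -6)
        np.testing.assert_allclose(d2.absorbance[interior], 2 * a, rtol=1e-8)

    def test_lorentzian_minimum_at_band_centre(self, quiet_cfg):
        d2 = _pipeline(_lorentzian_spectrum(quiet_cfg, 1745.0))
        idx = np.argmin(d2.absorbance)
        assert abs(d2.wavenumbers_cm1[idx] - 1745.0) <= d2.step_cm1

    def test_agrees_with_finite_difference_oracle(self, quiet_cfg):
        """SG second derivative tracks a central finite-difference oracle
        within 2% (of the oracle maximum) on a smooth broad band."""
        spec, _ = synth.make_spectrum(quiet_cfg, bands=[Band(1600.0, 80.0, 1.0, "gaussian")],
                                      instrument="ftir", noise_sd=0.0)
        pre = sp.preprocess(spec, "ftir")
        d2 = sp.second_derivative(pre, "ftir")
        oracle = np.gradient(np.gradient(pre.absorbance, pre.wavenumbers_cm1),
                             pre.wavenumbers_cm1)
        scale = np.abs(oracle).max()
        mask = np.abs(oracle) > 0.1 * scale
        assert np.abs(d2.absorbance[mask] - oracle[mask]).max() <= 0.02 * scale


class TestLocateCoPeak:
    def test_liquid_preset_at_1730_with_20cm_width(self, quiet_cfg):
        spec, _ = synth.make_spectrum(quiet_cfg, phase="liquid")
        peak = sp.locate_co_peak(_pipeline(spec))
        assert peak.position_cm1 == pytest.approx(1730.0, abs=spec.step_cm1)
        assert peak.width_cm1 == pytest.approx(20.0, abs=2.0)

    def test_gel_minus_liquid_shift_is_8(self, quiet_cfg):
        liq, _ = synth.make_spectrum(quiet_cfg, phase="liquid")
        gel, _ = synth.make_spectrum(quiet_cfg, phase="gel")
        shift = sp.peak_shift(_pipeline(liq), _pipeline(gel))
        assert shift == pytest.approx(8.0, abs=liq.step_cm1)

    def test_shift_is_antisymmetric_and_zero_on_self(self, quiet_cfg):
        liq, _ = synth.make_spectrum(quiet_cfg, phase="liquid")
        gel, _ = synth.make_spectrum(quiet_cfg, phase="gel")
        dl, dg = _pipeline(liq), _pipeline(gel)
        assert sp.peak_shift(dl, dl) == 0.0
        assert sp.peak_shift(dl, dg) == pytest.approx(-sp.peak_shift(dg, dl), abs=1e-9)

    def test_off_grid_centre_sweep_refined_to_half_step(self, quiet_cfg):
        """Parabolic refinement keeps the localization error below half a
        grid step across the analysis window."""
        for centre in np.linspace(1712.3, 1748.7, 9):
            peak = sp.locate_co_peak(_pipeline(_lorentzian_spectrum(quiet_cfg, centre)))
            assert abs(peak.position_cm1 - centre) <= 1.0

    def test_position_invariant_to_rescaling(self, quiet_cfg):
        d2 = _pipeline(_lorentzian_spectrum(quiet_cfg, 1733.0))
        scaled = Spectrum(d2.wavenumbers_cm1, 7.3 * d2.absorbance, d2.instrument)
        assert sp.locate_co_peak(scaled).position_cm1 == \
            pytest.approx(sp.locate_co_peak(d2).position_cm1, abs=1e-12)

    def test_no_band_in_window_raises(self, quiet_cfg):
        spec, _ = synth.make_spectrum(quiet_cfg, bands=[Band(1450.0, 20.0, 1.0)])
        with pytest.raises(NoPeakError):
            sp.locate_co_peak(_pipeline(spec))


class TestAmideFractions:
    def test_single_band_inside_alpha_window_is_pure_alpha(self, quiet_cfg):
        spec, _ = synth.make_spectrum(quiet_cfg, bands=[Band(1657.0, 3.0, 1.0, "gaussian")],
                                      instrument="ftir", noise_sd=0.0)
        fractions = sp.amide_fractions(spec).fractions
        assert fractions["alpha_helix"] == pytest.approx(1.0, abs=1e-3)

    def test_mixture_beta_fraction_within_five_points(self, quiet_cfg):
        """A 30% intermolecular-beta / 70% alpha mixture (15 cm-1 bands)
        integrates to a beta fraction within 5 points of truth despite
        band overlap into neighbouring windows."""
        sigma = 15.0 / 2.354820045
        amp = 1.0 / (sigma * np.sqrt(2 * np.pi))
        bands = [Band(1620.0, 15.0, 0.30 * amp, "gaussian"),
                 Band(1655.0, 15.0, 0.70 * amp, "gaussian")]
        spec, _ = synth.make_spectrum(quiet_cfg, bands=bands, instrument="ftir",
                                      noise_sd=0.0)
        fractions = sp.amide_fractions(sp.preprocess(spec, "ftir")).fractions
        assert abs(fractions["intermolecular_beta"] - 0.30) <= 0.05

    def test_fractions_sum_to_one_and_ignore_evaluation_order(self, quiet_cfg):
        spec, _ = synth.make_amide_spectrum(quiet_cfg, 0.12, noise_sd=0.0)
        pre = sp.preprocess(spec, "ftir")
        result = sp.amide_fractions(pre)
        assert sum(result.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        reordered = dict(reversed(list(sp.AMIDE_SUBBANDS_CM1.items())))
        result2 = sp.amide_fractions(pre, subbands=reordered)
        for name in result.fractions:
            assert result2.fractions[name] == pytest.approx(result.fractions[name])

    def test_no_signal_raises(self):
        grid = np.arange(1400.0, 1795.0, 2.0)
        with pytest.raises(NoSignalError):
            sp.amide_fractions(Spectrum(grid, np.zeros(grid.shape)))


class TestRatioMap:
    def test_equal_maps_give_unity(self):
        a = ImageChannel(np.full((8, 8), 3.0), 0.1)
        result = sp.protein_lipid_ratio_map(a, a, floor=0.5)
        assert np.all(result.valid)
        np.testing.assert_allclose(result.ratio, 1.0)

    def test_zero_lipid_pixel_flagged_invalid_not_infinite(self):
        lipid = np.full((4, 4), 2.0)
        lipid[1, 1] = 0.0
        result = sp.protein_lipid_ratio_map(ImageChannel(np.ones((4, 4)), 0.1),
                                            ImageChannel(lipid, 0.1), floor=0.0)
        assert not result.valid[1, 1]
        assert np.isnan(result.ratio[1, 1])
        assert np.isfinite(result.ratio[result.valid]).all()

    def test_coated_half_recovered_by_thresholding(self):
        lipid = np.full((16, 16), 4.0)
        protein = np.full((16, 16), 4.0)
        protein[:, 8:] = 8.0  # protein-coated half at 2x ratio
        result = sp.protein_lipid_ratio_map(ImageChannel(protein, 0.1),
                                            ImageChannel(lipid, 0.1), floor=0.5)
        recovered = result.ratio > 1.5
        expected = np.zeros((16, 16), dtype=bool)
        expected[:, 8:] = True
        np.testing.assert_array_equal(recovered, expected)
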