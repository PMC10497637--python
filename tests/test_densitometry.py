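"""Wedge calibration, gray-to-density conversion, band detection."""

import numpy as np
import pytest

from coralcarb import densitometry as dens
from coralcarb import synthetic as syn
from coralcarb.densitometry import CalibrationError, NoCompleteBandError
from coralcarb.radiograph import Radiograph, WedgeStep

STEPS_WITH_SLAB = tuple(round(0.1 * i, 1) for i in range(1, 12))


def make_phantom(seed=11, **kw):
    defaults = dict(noise_sd=0.0)
    defaults.update(kw)
    return syn.generate_radiograph(syn.RadiographPhantomParams(**defaults), seed=seed)


class TestCalibration:
    def test_curve_is_monotone_and_anchored_at_air(self, noiseless_phantom):
        rad, gt = noiseless_phantom
        curve = dens.build_calibration(rad)
        assert (np.diff(curve.grays) > 0).all()
        assert (np.diff(curve.areals) > 0).all()
        air_gray = rad.image[rad.background_mask].mean()
        assert dens.gray_to_density(air_gray, curve) == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_error_at_most_one_gray_level(self, noiseless_phantom):
        rad, gt = noiseless_phantom
        curve = dens.build_calibration(rad)
        # convert each wedge step's exact gray back: must hit 2.83*thickness
        for s in rad.wedge_steps:
            g = rad.image[s.mask].mean()
            areal = curve.areal_density(g)
            back_gray = gt.air_gray + gt.gray_per_areal * areal
            assert abs(back_gray - g) <= 1.0

    def test_degenerate_equal_step_grays_error(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        img = rad.image.copy()
        s0, s1 = rad.wedge_steps[0], rad.wedge_steps[1]
        img[s1.mask] = img[s0.mask][0]
        broken = Radiograph(
            image=img, pixel_size_cm=rad.pixel_size_cm, bit_depth=rad.bit_depth,
            slab_thickness_cm=rad.slab_thickness_cm, wedge_density=rad.wedge_density,
            wedge_steps=rad.wedge_steps, slab_mask=rad.slab_mask,
            background_mask=rad.background_mask, track=rad.track,
        )
        with pytest.raises(CalibrationError, match="monotone"):
            dens.build_calibration(broken)

    def test_missing_background_region_errors(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        broken = Radiograph(
            image=rad.image, pixel_size_cm=rad.pixel_size_cm, bit_depth=rad.bit_depth,
            slab_thickness_cm=rad.slab_thickness_cm, wedge_density=rad.wedge_density,
            wedge_steps=rad.wedge_steps, slab_mask=rad.slab_mask,
            background_mask=np.zeros_like(rad.background_mask), track=rad.track,
        )
        with pytest.raises(CalibrationError, match="background"):
            dens.build_calibration(broken)

    def test_gray_at_slab_thickness_step_converts_to_wedge_density(self):
        rad, _ = make_phantom(wedge_steps_cm=STEPS_WITH_SLAB)
        curve = dens.build_calibration(rad)
        step = next(s for s in rad.wedge_steps if s.thickness_cm == 0.9)
        g = rad.image[step.mask].mean()
        assert dens.gray_to_density(g, curve) == pytest.approx(2.83, abs=0.01)

    def test_gray_midway_between_air_and_slab_step_is_half_density(self):
        rad, _ = make_phantom(wedge_steps_cm=STEPS_WITH_SLAB)
        curve = dens.build_calibration(rad)
        step = next(s for s in rad.wedge_steps if s.thickness_cm == 0.9)
        air = rad.image[rad.background_mask].mean()
        mid = (air + rad.image[step.mask].mean()) / 2.0
        assert dens.gray_to_density(mid, curve) == pytest.approx(1.415, abs=0.01)

    def test_extrapolation_is_clamped_nonnegative(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        curve = dens.build_calibration(rad)
        assert dens.gray_to_density(0, curve) >= 0.0
        top = dens.gray_to_density(rad.gray_max, curve)
        assert top == pytest.approx(curve.areals[-1] / curve.slab_thickness_cm)


class TestDensityProfile:
    def test_constant_phantom_gives_flat_profile(self):
        rad, gt = make_phantom(
            band_profile=lambda x: np.full_like(np.asarray(x, dtype=float), 1.2)
        )
        curve = dens.build_calibration(rad)
        prof = dens.extract_density_profile(rad, curve, 3)
        assert np.abs(prof.density - 1.2).max() < 0.01

    def test_sinusoid_profile_hits_expected_extremes(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        curve = dens.build_calibration(rad)
        prof = dens.extract_density_profile(rad, curve, 5)
        assert prof.density.max() == pytest.approx(1.8, abs=0.02)
        assert prof.density.min() == pytest.approx(1.0, abs=0.02)

    def test_track_width_is_irrelevant_without_noise(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        curve = dens.build_calibration(rad)
        p1 = dens.extract_density_profile(rad, curve, 1)
        p5 = dens.extract_density_profile(rad, curve, 5)
        assert np.array_equal(p1.density, p5.density)

    def test_track_leaving_slab_errors(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        curve = dens.build_calibration(rad)
        with pytest.raises(ValueError, match="exits the slab"):
            dens.extract_density_profile(rad, curve, track_width=200)

    def test_positions_start_at_zero_and_increase(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        curve = dens.build_calibration(rad)
        prof = dens.extract_density_profile(rad, curve, 5)
        assert prof.positions_cm[0] == 0.0
        assert (np.diff(prof.positions_cm) > 0).all()


class TestBandDetection:
    def test_sinusoid_yields_four_bands_with_expected_values(self, noiseless_phantom):
        rad, gt = noiseless_phantom
        curve = dens.build_calibration(rad)
        prof = dens.extract_density_profile(rad, curve, 5)
        bands = dens.detect_annual_bands(prof)
        assert len(bands.table) == 4
        np.testing.assert_allclose(bands.extensions, 0.8, atol=0.01)
        np.testing.assert_allclose(bands.densities, 1.4, atol=0.02)
        assert bands.table.band_index.tolist() == [1, 2, 3, 4]

    def test_monotone_profile_has_no_complete_band(self):
        rad, _ = make_phantom(band_profile=lambda x: 1.0 + 0.3 * np.asarray(x, dtype=float))
        curve = dens.build_calibration(rad)
        prof = dens.extract_density_profile(rad, curve, 5)
        with pytest.raises(NoCompleteBandError):
            dens.detect_annual_bands(prof)

    def test_noisy_boundaries_within_two_pixels_of_truth(self):
        rad, gt = make_phantom(noise_sd=2.0, seed=31)
        curve = dens.build_calibration(rad)
        prof = dens.extract_density_profile(rad, curve, 5)
        bands = dens.detect_annual_bands(prof)
        detected = bands.boundaries_cm
        true = gt.band_boundaries_cm
        assert len(detected) == len(true)
        assert np.abs(detected - true).max() <= 2 * rad.pixel_size_cm + 1e-12

    def test_extension_weighted_density_mean_conserves_profile_mean(self, noiseless_phantom):
        rad, _ = noiseless_phantom
        curve = dens.build_calibration(rad)
        prof = dens.extract_density_profile(rad, curve, 5)
        bands = dens.detect_annual_bands(prof)
        w = bands.extensions
        weighted = (bands.densities * w).sum() / w.sum()
        lo = np.searchsorted(prof.positions_cm, bands.table.start_cm.iloc[0])
        hi = np.searchsorted(prof.positions_cm, bands.table.end_cm.iloc[-1])
        assert weighted == pytest.approx(prof.density[lo:hi].mean(), abs=1e-6)

    @pytest.mark.parametrize("delta", [0.1, 0.3])
    def test_raising_true_density_raises_every_annual_density(self, delta):
        def profile(shift):
            return lambda x: 1.2 + shift + 0.3 * np.sin(
                2 * np.pi * np.asarray(x, dtype=float) / 0.8
            )

        out = []
        for shift in (0.0, delta):
            rad, _ = syn.generate_radiograph(
                syn.RadiographPhantomParams(band_profile=profile(shift), noise_sd=0.0), seed=5
            )
            curve = dens.build_calibration(rad)
            prof = dens.extract_density_profile(rad, curve, 5)
            out.append(dens.detect_annual_bands(prof).densities)
        assert (out[1] > out[0]).all()
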