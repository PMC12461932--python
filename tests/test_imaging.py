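"""Droplet image quantification: center, profiles, calibration, metrics."""

import numpy as np
import pytest
from scipy import ndimage

from interphase.datatypes import CalibrationCurve, DiameterProfile, DropletImage
from interphase.imaging import (
    DropletAnalyzer,
    analyze_droplet,
    average_profile,
    calibrate,
    detect_center,
    extract_profiles,
    measure_droplet,
    summarize_emulsion,
    to_concentration,
)
from interphase.synthetic import gen_calibration_standards, gen_droplet_image


class TestDetectCenter:
    def test_known_center_recovered(self, clean_droplet):
        image, truth = clean_droplet
        row, col = detect_center(image)
        assert row == pytest.approx(truth["center_row_px"], abs=0.5)
        assert col == pytest.approx(truth["center_col_px"], abs=0.5)

    def test_translation_equivariance(self):
        image, truth = gen_droplet_image(noise_model="none", margin_um=2.5)
        shifted = DropletImage(
            np.roll(np.roll(image.intensity, 3, axis=0), 5, axis=1),
            image.pixel_size_um,
        )
        r0, c0 = detect_center(image)
        r1, c1 = detect_center(shifted)
        assert (r1 - r0, c1 - c0) == (pytest.approx(3, abs=1e-6),
                                      pytest.approx(5, abs=1e-6))

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            detect_center(DropletImage(np.full((32, 32), 7.0), 0.1))

    def test_border_touching_ring_warned(self):
        image, _ = gen_droplet_image(noise_model="none", margin_um=0.05)
        with pytest.warns(UserWarning, match="border"):
            detect_center(image)


class TestExtractProfiles:
    def test_symmetric_droplet_profiles_agree_across_angles(self, clean_droplet):
        image, truth = clean_droplet
        center = (truth["center_row_px"], truth["center_col_px"])
        profs = extract_profiles(image, center)
        peak = np.nanmax(profs.profiles)
        spread = np.nanmax(np.nanstd(profs.profiles, axis=0))
        assert spread < 0.01 * peak

    def test_few_angle_average_matches_many_angle_average(self, clean_droplet):
        # symmetry-reduction oracle: 4 angles suffice for a symmetric image
        image, truth = clean_droplet
        center = (truth["center_row_px"], truth["center_col_px"])
        avg4 = average_profile(extract_profiles(image, center, n_angles=4))
        avg360 = average_profile(extract_profiles(image, center, n_angles=360))
        peak = np.nanmax(avg360.values)
        assert np.nanmax(np.abs(avg4.values - avg360.values)) < 0.01 * peak

    def test_anisotropic_pattern_seen_only_along_its_angle(self):
        img = np.zeros((41, 41))
        img[20, :] = 100.0  # bright horizontal line through the center
        image = DropletImage(img, 0.1)
        profs = extract_profiles(image, (20.0, 20.0), n_angles=4, half_length=1.5)
        at_0 = profs.profiles[0]  # along the line
        at_90 = profs.profiles[1]  # perpendicular: background except center
        assert np.nanmin(at_0) == pytest.approx(100.0)
        off_center = np.abs(profs.positions_um) > 0.2
        assert np.nanmax(np.abs(at_90[off_center])) < 1e-6

    def test_center_outside_image_rejected(self, clean_droplet):
        image, _ = clean_droplet
        with pytest.raises(ValueError, match="outside"):
            extract_profiles(image, (-5.0, 10.0))

    def test_requested_overlength_truncates_with_flag(self, clean_droplet):
        image, truth = clean_droplet
        center = (truth["center_row_px"], truth["center_col_px"])
        profs = extract_profiles(image, center, half_length=20.0)
        assert profs.truncated
        assert np.isnan(profs.profiles).any()


class TestAverageProfile:
    def test_average_of_identical_profiles_is_any_one(self, clean_droplet):
        image, truth = clean_droplet
        center = (truth["center_row_px"], truth["center_col_px"])
        profs = extract_profiles(image, center, n_angles=8)
        avg = average_profile(profs)
        np.testing.assert_allclose(
            avg.values, profs.profiles[0], atol=0.01 * np.nanmax(avg.values)
        )

    def test_pointwise_mean_of_two_profiles(self):
        from interphase.datatypes import RadialProfileSet

        pos = np.linspace(-1, 1, 21)
        a, b = np.sin(pos), np.cos(pos)
        profs = RadialProfileSet(pos, np.array([0.0, 90.0]), np.vstack([a, b]))
        np.testing.assert_allclose(average_profile(profs).values, (a + b) / 2.0)

    def test_peak_matches_gain_times_concentration(self, clean_droplet):
        image, truth = clean_droplet
        center = (truth["center_row_px"], truth["center_col_px"])
        avg = average_profile(extract_profiles(image, center))
        assert np.nanmax(avg.values) == pytest.approx(
            truth["gain"] * truth["peak_conc"], rel=0.02
        )


class TestCalibration:
    def test_two_point_exact(self):
        curve = calibrate([(0.0, 0.0), (1.0, 100.0)])
        assert (curve.gain, curve.offset) == (pytest.approx(100.0),
                                              pytest.approx(0.0))

    def test_noise_free_standards_round_trip(self):
        pairs, truth = gen_calibration_standards(
            np.linspace(0, 2, 8), gain=150.0, offset=12.0, noise_sd=0.0
        )
        curve = calibrate(pairs)
        assert curve.gain == pytest.approx(truth["gain"], rel=1e-12)
        assert curve.offset == pytest.approx(truth["offset"], abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_flat_intensities_unusable(self):
        with pytest.raises(ValueError, match="unusable"):
            calibrate([(0.0, 50.0), (1.0, 50.0), (2.0, 50.0)])

    def test_degenerate_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            calibrate([(1.0, 10.0), (1.0, 20.0)])

    def test_offset_maps_to_zero_concentration(self):
        curve = CalibrationCurve(gain=100.0, offset=7.0, r_squared=1.0, n_standards=2)
        profile = DiameterProfile(
            np.array([-0.1, 0.0, 0.1]), np.array([7.0, 7.0, 7.0]), np.ones(3, int)
        )
        conc = to_concentration(profile, curve)
        np.testing.assert_allclose(conc.values, 0.0)
        assert conc.units == "g_per_L"

    def test_negative_preclip_values_reported_in_flag(self):
        curve = CalibrationCurve(gain=100.0, offset=10.0, r_squared=1.0, n_standards=2)
        profile = DiameterProfile(
            np.array([-0.1, 0.0, 0.1, 0.2]),
            np.array([0.0, 5.0, 20.0, 30.0]),
            np.ones(4, int),
        )
        conc = to_concentration(profile, curve)
        assert conc.clip_fraction == pytest.approx(0.5)
        assert np.all(conc.values >= 0)


class TestMeasureDroplet:
    def test_noise_free_preset_recovery(self, clean_droplet, calibration):
        image, truth = clean_droplet
        m = analyze_droplet(image, calibration)
        px = truth["pixel_size"]
        assert m.diameter_um == pytest.approx(truth["diameter"], abs=px)
        assert m.interface_conc_g_per_L == pytest.approx(truth["peak_conc"], rel=0.02)
        assert m.interface_thickness_um == pytest.approx(truth["ring_width"], abs=px)
        assert m.bulk_conc_g_per_L == pytest.approx(truth["bulk_conc"], rel=0.05)

    def test_symmetric_profile_has_equal_side_thicknesses(self, clean_droplet,
                                                          calibration):
        image, truth = clean_droplet
        m = analyze_droplet(image, calibration)
        assert abs(m.thickness_left_um - m.thickness_right_um) <= truth["pixel_size"]

    def test_peak_at_reference_level_gives_zero_thickness_with_flag(self):
        pos = np.linspace(-3.0, 3.0, 61)
        vals = 0.5 * np.exp(-0.5 * ((np.abs(pos) - 2.0) / 0.3) ** 2) + 1e-4
        profile = DiameterProfile(pos, np.minimum(vals, 0.5),
                                  np.ones(61, int), units="g_per_L")
        m = measure_droplet(profile)
        assert m.interface_thickness_um == 0.0
        assert any("reference level" in f for f in m.flags)

    def test_uncalibrated_profile_rejected(self, clean_droplet):
        image, truth = clean_droplet
        center = (truth["center_row_px"], truth["center_col_px"])
        raw = average_profile(extract_profiles(image, center))
        with pytest.raises(ValueError, match="calibrated"):
            measure_droplet(raw)

    def test_featureless_profile_has_no_resolvable_interface(self):
        pos = np.linspace(-3.0, 3.0, 61)
        profile = DiameterProfile(pos, np.full(61, 0.7), np.ones(61, int),
                                  units="g_per_L")
        with pytest.raises(ValueError, match="no resolvable interface"):
            measure_droplet(profile)


class TestRotationInvariance:
    def test_metrics_stable_under_image_rotation(self, calibration):
        image, truth = gen_droplet_image(noise_model="none", margin_um=2.5)
        base = analyze_droplet(image, calibration)
        px = truth["pixel_size"]
        for angle in (7.0, 90.0, 33.0):
            rotated = DropletImage(
                np.clip(
                    ndimage.rotate(image.intensity, angle, reshape=False, order=3),
                    0.0, None,
                ),
                image.pixel_size_um,
            )
            m = analyze_droplet(rotated, calibration)
            assert m.diameter_um == pytest.approx(base.diameter_um, abs=px)
            assert m.interface_thickness_um == pytest.approx(
                base.interface_thickness_um, abs=px
            )
            assert m.interface_conc_g_per_L == pytest.approx(
                base.interface_conc_g_per_L, rel=0.02
            )

    def test_half_and_full_turn_averages_agree(self, clean_droplet, calibration):
        # each diameter at angle theta duplicates theta + 180 degrees
        image, truth = clean_droplet
        a180 = DropletAnalyzer(n_angles=180).fit(image, calibration).profile_
        a360 = DropletAnalyzer(n_angles=360).fit(image, calibration).profile_
        peak = np.nanmax(a360.values)
        assert np.nanmax(np.abs(a180.values - a360.values)) < 0.01 * peak


class TestSummarize:
    def test_single_droplet_summary(self, clean_droplet, calibration):
        image, _ = clean_droplet
        m = analyze_droplet(image, calibration)
        summary = summarize_emulsion([m])
        assert summary.n_droplets == 1
        assert summary.table.loc["diameter_um", "mean"] == m.diameter_um
        assert summary.table.loc["diameter_um", "sd"] == 0.0
        assert any("n=1" in f for f in summary.flags)

    def test_sampled_diameters_match_sampling_theory(self, calibration):
        # summary mean within 3 standard errors of the generating mean
        rng = np.random.default_rng(5)
        mean_d, sd_d, n = 5.17, 1.78, 100
        diameters = np.clip(rng.normal(mean_d, sd_d, n), 2.6, None)
        metrics = []
        for d in diameters:
            image, _ = gen_droplet_image(
                diameter=float(d), noise_model="none", margin_um=1.0,
                seed=int(rng.integers(2**31)),
            )
            metrics.append(analyze_droplet(image, calibration))
        summary = summarize_emulsion(metrics)
        se = np.std(diameters, ddof=1) / np.sqrt(n)
        assert abs(
            summary.table.loc["diameter_um", "mean"] - np.mean(diameters)
        ) < 3 * se

    def test_mean_invariant_under_duplication(self, clean_droplet, calibration):
        image, _ = clean_droplet
        m = analyze_droplet(image, calibration)
        once = summarize_emulsion([m])
        twice = summarize_emulsion([m, m])
        assert twice.table["mean"].equals(once.table["mean"])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="no droplets"):
            summarize_emulsion([])
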