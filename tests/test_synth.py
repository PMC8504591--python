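import numpy as np
import pytest

import slitfield as sf
from slitfield.errors import ConfigurationError
from slitfield.synth import expected_profile, field_edge_at_foil, foil_to_image


class TestPenumbra:
    def test_point_focal_spot_gives_zero(self, chest_geom):
        assert sf.penumbra_width(chest_geom, 0.0) == 0.0

    def test_linear_in_focal_spot_size(self, chest_geom):
        w1 = sf.penumbra_width(chest_geom, 0.35)
        assert sf.penumbra_width(chest_geom, 0.70) == pytest.approx(2 * w1)
        assert w1 > 0

    def test_ray_sampling_oracle(self, chest_geom):
        """Monte Carlo check: project boundary rays from 1e4 points across the
        focal spot through the slit; the 10-90% spread of the projected edge
        equals 0.8x the geometric penumbra width (uniform focal spot)."""
        f = 0.35
        x_fov = -7.68
        rng = np.random.default_rng(11)
        s = chest_geom.x_source + f * (rng.random(10_000) - 0.5)
        # field-edge position at the foil plane for each source point, with
        # the boundary anchored at the detector plane
        u = x_fov + (s - x_fov) * chest_geom.y_foil / chest_geom.y_source
        p = np.array([foil_to_image(chest_geom, ui) for ui in u])
        spread_10_90 = np.percentile(p, 90) - np.percentile(p, 10)
        expected = 0.8 * sf.penumbra_width(chest_geom, f)
        assert spread_10_90 == pytest.approx(expected, rel=0.05)


class TestExpectedImage:
    def test_region_means_before_noise(self, scenario_factory):
        """The noise-free image reproduces the analytic region means."""
        cfg = scenario_factory()
        pos, mean, audit = expected_profile(cfg)
        cam_lo, cam_hi = audit.camera_span_mm
        levels = audit.region_means_adu
        # outside the camera, before its leading edge
        outside = mean[pos < cam_lo - 1]
        np.testing.assert_allclose(outside, levels["outside_camera"])
        # in-camera baseline beyond the fluorescence band
        baseline = mean[(pos > audit.x_edge_true + 2) & (pos < cam_hi)]
        np.testing.assert_allclose(baseline, levels["camera_baseline"])
        # plateau inside the band, away from both flanks
        plateau = mean[(pos > audit.band_mm[0] + 3) & (pos < audit.x_edge_true - 3)]
        np.testing.assert_allclose(plateau, levels["plateau"])
        # lead-covered strip behind the camera
        lead = mean[(pos > cam_hi + 0.1) & (pos < cam_hi + 40)]
        np.testing.assert_allclose(lead, levels["lead_plate"])

    def test_flank_foot_sits_at_true_edge(self, scenario_factory):
        cfg = scenario_factory()
        pos, mean, audit = expected_profile(cfg)
        baseline = audit.region_means_adu["camera_baseline"]
        above = pos[mean > baseline + 1e-6]
        inside_band = above[(above > audit.band_mm[0]) & (above < audit.camera_span_mm[1])]
        assert inside_band.max() == pytest.approx(audit.x_edge_true, abs=0.08)

    def test_offset_region_mean_matches_detector_offset(self, scenario_factory):
        """The lead-covered region averages to the 50 ADU offset within 1%
        over more than 1e4 pixels."""
        image, audit = sf.render_scene(scenario_factory(seed=2))
        pos = np.arange(image.pixels.shape[1]) * image.pixel_pitch_mm
        cam_hi = audit.camera_span_mm[1]
        region = image.pixels[:, (pos > cam_hi + 0.5) & (pos < cam_hi + 40)]
        assert region.size > 10_000
        assert region.mean() == pytest.approx(50.0, rel=0.01)

    def test_pixels_clipped_to_bit_depth(self, scenario_factory):
        cfg = scenario_factory(direct_beam_adu=30000.0, seed=4)
        image, _ = sf.render_scene(cfg)
        assert image.pixels.max() <= 16383

    def test_audit_consistent_with_inverse_formula(self, chest_geom,
                                                   scenario_factory):
        _, audit = sf.render_scene(scenario_factory(x_fov_true=-5.5))
        assert audit.x_edge_true == pytest.approx(
            sf.invert_fov_boundary(chest_geom, -5.5), abs=1e-9
        )

    def test_edge_outside_image_rejected(self, scenario_factory):
        with pytest.raises(ConfigurationError):
            sf.render_scene(scenario_factory(x_fov_true=-120.0))

    def test_level_ordering_enforced(self, scenario_factory):
        with pytest.raises(ConfigurationError):
            scenario_factory(plateau_adu=90.0)  # below background


class TestRenderScene:
    def test_seeded_determinism(self, scenario_factory):
        a, _ = sf.render_scene(scenario_factory(seed=42))
        b, _ = sf.render_scene(scenario_factory(seed=42))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self, scenario_factory):
        a, _ = sf.render_scene(scenario_factory(seed=1))
        b, _ = sf.render_scene(scenario_factory(seed=2))
        assert np.any(a.pixels != b.pixels)

    def test_recovery_of_true_boundary(self, chest_geom, scenario_factory):
        image, _ = sf.render_scene(scenario_factory(x_fov_true=-7.68, seed=42))
        result = sf.measure_field(image, chest_geom)
        truth = sf.invert_fov_boundary(chest_geom, -7.5)
        # the example contract: the measured edge lies within 0.5 mm of the
        # edge the inverse formula predicts for the rendered truth
        assert result.measurement.x_edge == pytest.approx(
            sf.invert_fov_boundary(chest_geom, -7.68), abs=0.5
        )
        assert abs(truth - result.measurement.x_edge) < 2.0  # sanity on scale

    def test_binning_halves_shape_and_doubles_pitch(self, scenario_factory):
        cfg = scenario_factory(binning=2, seed=6)
        image, _ = sf.render_scene(cfg)
        assert image.pixels.shape == (300, 1024)
        assert image.pixel_pitch_mm == pytest.approx(0.14)

    def test_binned_scene_still_measurable(self, chest_geom, scenario_factory):
        image, _ = sf.render_scene(scenario_factory(binning=2, seed=6))
        result = sf.measure_field(image, chest_geom,
                                  sf.ProfileConfig(roi_width=250))
        assert result.measurement.x_fov == pytest.approx(-7.68, abs=0.5)

    def test_plateau_snr_improves_recovery(self, chest_geom, scenario_factory):
        """Mean recovery error shrinks (statistically) as the fluorescence
        contrast over the in-camera baseline grows."""
        def mean_abs_error(plateau_adu):
            errs = []
            for seed in range(10):
                cfg = scenario_factory(plateau_adu=plateau_adu, seed=seed)
                image, _ = sf.render_scene(cfg)
                r = sf.measure_field(image, chest_geom,
                                     sf.ProfileConfig(roi_width=30))
                errs.append(abs(r.measurement.x_fov + 7.68))
            return np.mean(errs)

        assert mean_abs_error(125.0) > mean_abs_error(200.0)


class TestArtifactsAndProfileSets:
    def test_foil_end_step_adds_intensity_rise(self, chest_geom):
        base = sf.ScenarioConfig(geom=chest_geom, x_fov_true=-7.68,
                                 foil_extent_mm=(10.0, 60.0), seed=9)
        stepped = sf.ScenarioConfig(geom=chest_geom, x_fov_true=-7.68,
                                    foil_extent_mm=(10.0, 60.0), seed=9,
                                    foil_end_step=True)
        _, mean_a, audit = expected_profile(base)
        pos, mean_b, _ = expected_profile(stepped)
        foil_end = foil_to_image(chest_geom, 10.0)
        beyond = (pos > foil_end + 1) & (pos < audit.camera_span_mm[1])
        before = (pos > audit.x_edge_true + 1) & (pos < foil_end - 1)
        assert np.all(mean_b[beyond] > mean_a[beyond])
        np.testing.assert_allclose(mean_b[before], mean_a[before])

    def test_direct_slit_transmission_bump(self, chest_geom, scenario_factory):
        pos, plain, _ = expected_profile(scenario_factory())
        _, bumped, _ = expected_profile(
            scenario_factory(direct_slit_transmission=True))
        at_slit = np.abs(pos - chest_geom.x_slit) < 0.5
        assert np.all(bumped[at_slit] > plain[at_slit])

    def test_profile_flanks_displaced_by_predicted_shift(self, chest_geom,
                                                         scenario_factory):
        """Two views differing only in the true boundary produce flanks
        displaced by the shift the boundary formula predicts."""
        cfg_a = scenario_factory(x_fov_true=-7.68, seed=3)
        cfg_b = scenario_factory(x_fov_true=-12.68, seed=3)
        profs = sf.render_profile_set([cfg_a, cfg_b])
        fits = [sf.fit_edge(p, sf.ProfileConfig()) for p in profs]
        predicted = (sf.invert_fov_boundary(chest_geom, -12.68)
                     - sf.invert_fov_boundary(chest_geom, -7.68))
        assert fits[1].x_edge - fits[0].x_edge == pytest.approx(predicted, abs=0.15)

    def test_profile_set_is_deterministic_and_normalized(self, scenario_factory):
        cfgs = [scenario_factory(seed=8), scenario_factory(seed=8)]
        a, b = sf.render_profile_set(cfgs)
        np.testing.assert_array_equal(a.raw, b.raw)
        lo, hi = a.camera_window
        in_window = (a.positions_mm >= lo) & (a.positions_mm <= hi)
        assert a.normalized[in_window].min() == pytest.approx(1.0)

    def test_profile_set_requires_shared_side(self, chest_geom, right_geom):
        cfgs = [
            sf.ScenarioConfig(geom=chest_geom, x_fov_true=-7.68),
            sf.ScenarioConfig(geom=right_geom, x_fov_true=-8.97),
        ]
        with pytest.raises(ConfigurationError):
            sf.render_profile_set(cfgs)
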