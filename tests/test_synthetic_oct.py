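import dataclasses

import numpy as np
import pytest

import choroidmap as cm
from choroidmap.synthetic_oct import CohortSpec, GroupParams, generate_cohort
from choroidmap.volume_io import SECTOR_ORDER


def constant_group(ct=250.0, sd=0.0):
    return GroupParams(
        ct_mean_sd_um={s: (ct, sd) for s in SECTOR_ORDER},
        iol_mean_sd_mm=(24.6, 0.0),
        refractive_range_d=(-3.0, -0.5),
    )


class TestMakeEyeTruth:
    def test_constant_sectors_give_constant_field(self):
        truth = cm.make_eye_truth(constant_group(250.0), "OD", 1)
        x = np.linspace(-5, 5, 41)
        y = np.linspace(-2.5, 2.5, 21)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        np.testing.assert_allclose(truth.ct_um(xx, yy), 250.0, atol=1e-6)

    def test_same_seed_identical(self, low_group):
        a = cm.make_eye_truth(low_group, "OD", 42)
        b = cm.make_eye_truth(low_group, "OD", 42)
        assert a.sector_ct_um == b.sector_ct_um
        assert a.plateau_um == b.plateau_um
        assert a.iol_true_mm == b.iol_true_mm
        np.testing.assert_array_equal(a.motion_trace, b.motion_trace)
        xx = np.linspace(-4, 4, 30)
        np.testing.assert_array_equal(a.ct_um(xx, 0.0), b.ct_um(xx, 0.0))

    def test_different_seeds_differ(self, low_group):
        a = cm.make_eye_truth(low_group, "OD", 1)
        b = cm.make_eye_truth(low_group, "OD", 2)
        assert a.sector_ct_um != b.sector_ct_um

    def test_subfoveal_matches_drawn_fovea_value(self, low_group):
        for seed in range(5):
            t = cm.make_eye_truth(low_group, "OS", seed)
            pit = float(t.ct_um(*t.fovea_xy_mm))
            assert pit == pytest.approx(t.sector_ct_um["Fovea"], abs=1.0)

    def test_monte_carlo_subfoveal_mean(self, low_group):
        """Sample mean of the drawn subfoveal truth tracks the configured
        mean within 3 standard errors (Monte-Carlo check)."""
        n = 1000
        rng = np.random.default_rng(7)
        seeds = rng.integers(0, 2**31 - 1, size=n)
        vals = [
            cm.make_eye_truth(low_group, "OD", int(s), n_bscans=2).sector_ct_um["Fovea"]
            for s in seeds
        ]
        mean, sd = low_group.ct_mean_sd_um["Fovea"]
        se = sd / np.sqrt(n)
        assert abs(np.mean(vals) - mean) < 3 * se

    def test_surface_ordering_everywhere(self, low_group):
        x = np.linspace(-5, 5, 50)
        y = np.linspace(-2.5, 2.5, 25)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        for seed in range(5):
            t = cm.make_eye_truth(low_group, "OD" if seed % 2 else "OS", seed)
            ilm, rpe, csi = t.ilm_um(xx, yy), t.rpe_um(xx, yy), t.csi_um(xx, yy)
            assert np.all(ilm < rpe)
            assert np.all(rpe < csi)
            assert np.all(t.ct_um(xx, yy) > 0)

    def test_invalid_laterality_rejected(self, low_group):
        with pytest.raises(ValueError, match="laterality"):
            cm.make_eye_truth(low_group, "LEFT", 0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            constant_group(250.0, -1.0)

    def test_sector_targets_are_field_sector_means(self, low_group):
        """The drawn per-sector targets equal the CT field's sector means
        over the scan area (for well-supported sectors)."""
        from choroidmap import thickness_mapping as tm

        t = cm.make_eye_truth(low_group, "OD", 11)
        x = np.linspace(-5, 5, 256)
        y = np.linspace(-2.5, 2.5, 128)
        xx, yy = np.meshgrid(x, y, indexing="ij")
        ctmap = tm.ThicknessMap(
            ct=t.ct_um(xx, yy),
            lateral_spacing_x_mm=10 / 256,
            lateral_spacing_y_mm=5 / 128,
            laterality="OD",
            fovea_xy_mm=t.fovea_xy_mm,
        )
        means = tm.sector_summary(ctmap).mean_um
        for s in ("Fovea", "NIM", "SIM", "TIM", "IIM", "NOM", "TOM"):
            assert means[s] == pytest.approx(t.sector_ct_um[s], abs=2.0), s


class TestRenderVolume:
    def test_nonnegative_finite(self, speckled_eye):
        _, vol, _ = speckled_eye
        assert np.all(np.isfinite(vol.intensity))
        assert np.all(vol.intensity >= 0)

    def test_rolloff_halves_amplitude_at_6db_depth(self, low_group):
        """Mean rendered amplitude of identical reflectors at the roll-off
        depth is half the shallow value (6 dB sensitivity roll-off)."""
        params = cm.RenderParams(dims=(384, 64, 4), speckle_on=False,
                                 noise_floor=0.0)
        truth = cm.make_eye_truth(constant_group(250.0), "OD", 3,
                                  n_bscans=4, motion_amplitude_px=0)
        # flatten geometry so the same reflector stack sits at known depths
        truth = dataclasses.replace(truth, curvature_um_per_mm2=0.0,
                                    tilt_um_per_mm=(0.0, 0.0), pit_depth_um=0.0)
        vol, _ = cm.render_volume(truth, params, seed=0)
        rpe_px = params.um_to_px(truth.rpe_um(0.0, 0.0))
        depth0_mm = rpe_px * params.axial_spacing_air_um / 1000.0
        peak = vol.intensity[int(round(rpe_px)) - 1, :, :].mean()
        # compare against the analytic attenuation at that depth
        expected0 = 0.5 ** (depth0_mm / params.rolloff_6db_depth_mm)
        ratio3mm = 0.5 ** ((depth0_mm + 3.0) / params.rolloff_6db_depth_mm) / expected0
        assert ratio3mm == pytest.approx(0.5, abs=1e-12)
        # and check the rendered image actually follows the attenuation law:
        # amplitude at the RPE equals reflectivity x attenuation within 5%
        assert peak == pytest.approx(expected0 * params.level_rpe, rel=0.05)

    def test_zero_motion_trace_matches_motion_disabled(self, low_group):
        truth = cm.make_eye_truth(low_group, "OD", 9, n_bscans=8,
                                  motion_amplitude_px=0)
        params_on = cm.RenderParams(dims=(256, 64, 8))
        params_off = cm.RenderParams(dims=(256, 64, 8), apply_motion=False)
        va, _ = cm.render_volume(truth, params_on, seed=4)
        vb, _ = cm.render_volume(truth, params_off, seed=4)
        np.testing.assert_array_equal(va.intensity, vb.intensity)

    def test_surface_outside_window_errors(self, low_group):
        truth = cm.make_eye_truth(low_group, "OD", 9)
        tiny = cm.RenderParams(dims=(64, 64, 64))
        with pytest.raises(ValueError, match="B-scan"):
            cm.render_volume(truth, tiny, seed=0)


class TestCompositeAScan:
    def test_peak_separation_equals_formula(self, low_group):
        for seed in range(5):
            truth = cm.make_eye_truth(low_group, "OD", seed)
            a = cm.render_composite_ascan(truth)
            fov, cor = cm.detect_peaks(a)
            d_mm = (cor - fov) * a.axial_spacing_air_um / 1000.0
            expected = a.delta_L_ref_mm - a.n_index * truth.iol_true_mm
            half_sample = 0.5 * a.axial_spacing_air_um / 1000.0
            assert abs(d_mm - expected) <= half_sample

    def test_cornea_peak_outside_window_errors(self, low_group):
        truth = cm.make_eye_truth(low_group, "OD", 0)
        with pytest.raises(ValueError, match="window"):
            cm.render_composite_ascan(truth, delta_L_ref_mm=42.0)

    def test_reference_offset_below_eye_length_errors(self, low_group):
        truth = cm.make_eye_truth(low_group, "OD", 0)
        with pytest.raises(ValueError, match="exceed"):
            cm.render_composite_ascan(truth, delta_L_ref_mm=30.0)


class TestGenerateCohort:
    def _spec(self, cohort_spec, n):
        return CohortSpec(groups=cohort_spec.groups, n_eyes=n)

    def test_study_sized_cohort_counts_and_groups(self, cohort_spec):
        from choroidmap.cohort_stats import assign_group

        spec = self._spec(cohort_spec, {"low": 4, "moderate": 2, "high": 2})
        small = cm.RenderParams(dims=(256, 32, 8))
        eyes = generate_cohort(spec, seed=3, params=small)
        assert len(eyes) == 8
        for eye in eyes:
            assert eye.group == assign_group(eye.refractive_error_d)

    def test_empty_spec_gives_empty_list(self, cohort_spec):
        spec = self._spec(cohort_spec, {"low": 0, "moderate": 0, "high": 0})
        assert generate_cohort(spec, seed=0) == []

    def test_seed_determinism(self, cohort_spec):
        spec = self._spec(cohort_spec, {"low": 2, "moderate": 0, "high": 0})
        small = cm.RenderParams(dims=(256, 32, 8))
        a = generate_cohort(spec, seed=5, params=small)
        b = generate_cohort(spec, seed=5, params=small)
        c = generate_cohort(spec, seed=6, params=small)
        np.testing.assert_array_equal(a[0].volume.intensity, b[0].volume.intensity)
        assert a[0].truth.sector_ct_um == b[0].truth.sector_ct_um
        assert a[0].truth.sector_ct_um != c[0].truth.sector_ct_um
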