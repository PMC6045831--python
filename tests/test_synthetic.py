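"""Phantom geometry, analytic area oracle, rater/device simulation, study generation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from onhrel.metrics import cross_sectional_area
from onhrel.segmentation import fit_boundary
from onhrel.synthetic import (
    DeviceModel,
    PhantomSpec,
    RaterModel,
    analytic_area,
    default_device_models,
    default_phantom_specs,
    generate_study,
    phantom_truth,
    simulate_device,
    simulate_rater,
    subseed,
    truth_scan,
)

ZERO_NOISE = dict(
    axial_noise_sd=0.0,
    margin_noise_sd=0.0,
    interpretation_sd=0.0,
    boundary_bias_sd=0.0,
    point_jitter_sd=0.0,
)


class TestPhantomTruth:
    def test_flat_ilm_without_swelling(self):
        spec = PhantomSpec(bump_amplitude=0.0)
        y_ilm, _ = phantom_truth(spec, np.linspace(spec.x_min, spec.x_max, 50))
        np.testing.assert_allclose(y_ilm, spec.baseline_ilm_depth)

    def test_peak_elevation_at_center(self):
        spec = PhantomSpec(bump_amplitude=200.0)
        y_ilm, _ = phantom_truth(spec, np.array([spec.center_x]))
        assert y_ilm[0] == spec.baseline_ilm_depth - 200.0

    def test_symmetry_about_center(self):
        spec = PhantomSpec(bump_amplitude=350.0, bump_sigma=600.0)
        d = np.linspace(0, spec.scan_half_width, 25)
        left, _ = phantom_truth(spec, spec.center_x - d)
        right, _ = phantom_truth(spec, spec.center_x + d)
        np.testing.assert_allclose(left, right)

    def test_bm_undefined_in_gap(self):
        spec = PhantomSpec()
        _, y_bm = phantom_truth(
            spec, np.array([spec.center_x, spec.center_x + spec.bm_gap_half_width + 1])
        )
        assert np.isnan(y_bm[0]) and y_bm[1] == spec.bm_depth

    def test_outside_scan_rejected(self):
        spec = PhantomSpec()
        with pytest.raises(ValueError, match="outside"):
            phantom_truth(spec, np.array([spec.x_max + 10.0]))


class TestAnalyticArea:
    def test_rectangle_only_when_not_swollen(self):
        spec = PhantomSpec(baseline_ilm_depth=100.0, bump_amplitude=0.0, bm_depth=400.0)
        assert analytic_area(spec, 2.85) == pytest.approx(1.71)

    def test_amplitude_to_zero_limit_recovers_rectangle(self):
        base = analytic_area(PhantomSpec(bump_amplitude=0.0), 2.85)
        eps = analytic_area(PhantomSpec(bump_amplitude=1e-6), 2.85)
        assert eps == pytest.approx(base, abs=1e-8)

    def test_matches_numerical_quadrature(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            spec = PhantomSpec(
                baseline_ilm_depth=rng.uniform(600, 1000),
                bump_amplitude=rng.uniform(0, 500),
                bump_sigma=rng.uniform(500, 1000),
                bm_depth=rng.uniform(1050, 1400),
                bm_gap_half_width=rng.uniform(700, 1100),
            )
            hw = rng.uniform(1.0, 2.85)

            def integrand(x):
                y_ilm, _ = phantom_truth(spec, np.array([x]))
                return spec.bm_depth - y_ilm[0]

            num, _ = quad(
                integrand, spec.center_x - hw * 1000, spec.center_x + hw * 1000, limit=200
            )
            assert analytic_area(spec, hw) == pytest.approx(num / 1e6, rel=1e-6)

    def test_window_wider_than_phantom_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            analytic_area(PhantomSpec(scan_half_width=2000.0, center_x=2000.0), 2.85)


class TestSimulateRater:
    def test_zero_noise_reproduces_truth_at_control_points(self):
        spec = PhantomSpec(bump_amplitude=400.0)
        scan = truth_scan(spec)
        seg = simulate_rater(spec, scan, RaterModel("r1", **ZERO_NOISE), seed=1)
        x_um = seg.ilm.cols * scan.lateral_scale + spec.x_min
        truth, _ = phantom_truth(spec, x_um)
        fitted = fit_boundary(seg.ilm, seg.ilm.cols) * scan.axial_scale
        np.testing.assert_allclose(fitted, truth, atol=1e-9)
        for wing in (seg.bm_left, seg.bm_right):
            np.testing.assert_allclose(wing.rows * scan.axial_scale, spec.bm_depth, atol=1e-9)

    def test_same_seed_is_deterministic(self):
        spec = PhantomSpec(bump_amplitude=300.0)
        scan = truth_scan(spec)
        model = RaterModel("r1", axial_noise_sd=6.0, interpretation_sd=5.0, point_jitter_sd=1.0)
        a = simulate_rater(spec, scan, model, seed=42, bias_seed=7)
        b = simulate_rater(spec, scan, model, seed=42, bias_seed=7)
        assert a == b

    def test_persistent_bias_shared_across_sessions(self):
        spec = PhantomSpec()
        scan = truth_scan(spec)
        model = RaterModel("r1", **{**ZERO_NOISE, "interpretation_sd": 10.0})
        s1 = simulate_rater(spec, scan, model, seed=1, bias_seed=3)
        s2 = simulate_rater(spec, scan, model, seed=2, bias_seed=3)
        # only session noise (zero here) differs: identical boundaries
        np.testing.assert_allclose(s1.ilm.rows, s2.ilm.rows)
        # but the shared bias displaces the ILM from truth
        assert abs(s1.ilm.rows[0] * scan.axial_scale - spec.baseline_ilm_depth) > 1.0

    def test_confusion_offsets_whole_ilm(self):
        spec = PhantomSpec()
        scan = truth_scan(spec)
        model = RaterModel("r1", confusion_prob=1.0, confusion_offset=-40.0, **ZERO_NOISE)
        seg = simulate_rater(spec, scan, model, seed=5)
        np.testing.assert_allclose(
            seg.ilm.rows * scan.axial_scale, spec.baseline_ilm_depth - 40.0, atol=1e-9
        )

    def test_folded_normal_relation_for_independent_raters(self):
        # two raters with placement noise sigma: the pointwise difference is
        # N(0, 2 sigma^2), so the pooled mean absolute ILM difference tends
        # to 2 sigma / sqrt(pi)
        from onhrel.metrics import segmentation_difference

        sigma = 8.0
        specs = (default_phantom_specs() * 3)[:30]
        vals = []
        for i, spec in enumerate(specs):
            scan = truth_scan(spec, scan_id=f"s{i}")
            segs = []
            for rater in ("a", "b"):
                model = RaterModel(rater, **{**ZERO_NOISE, "axial_noise_sd": sigma})
                segs.append(
                    simulate_rater(
                        spec, scan, model,
                        seed=subseed(123, rater, str(i)),
                        bias_seed=subseed(123, "bias", rater, str(i)),
                    )
                )
            vals.append(
                segmentation_difference(segs[0], segs[1], "ILM", scan).mean_abs_diff_um
            )
        expected = 2 * sigma / math.sqrt(math.pi)
        assert abs(np.mean(vals) - expected) / expected < 0.15


class TestSimulateDevice:
    def test_clean_render_puts_band_peaks_at_truth_depths(self):
        spec = PhantomSpec(bump_amplitude=400.0)
        dev = DeviceModel("d", intensity_noise_sd=0.0)
        scan, adj = simulate_device(spec, dev, seed=0)
        y_ilm_truth, _ = phantom_truth(
            adj, adj.x_min + np.arange(scan.n_cols - 1) * dev.lateral_scale
        )
        peak_rows = np.argmax(scan.pixels[:, :-1], axis=0)
        err_px = np.abs(peak_rows * dev.axial_scale - y_ilm_truth) / dev.axial_scale
        # nearest row is within 0.5 px; 8-bit intensity quantisation can tie
        # two neighbouring rows, letting argmax pick the slightly farther one
        assert np.max(err_px) <= 0.6

    def test_axial_offset_shifts_reported_truth_exactly(self):
        spec = PhantomSpec()
        dev = DeviceModel("d", systematic_axial_offset=30.0)
        _, adj = simulate_device(spec, dev, seed=0)
        assert adj.baseline_ilm_depth == spec.baseline_ilm_depth + 30.0
        assert adj.bm_depth == spec.bm_depth + 30.0

    def test_area_invariant_to_common_axial_offset(self):
        # an offset moves ILM and BM together; the enclosed area cannot change
        spec = PhantomSpec(bump_amplitude=300.0)
        model = RaterModel("r", **ZERO_NOISE)
        areas = []
        for off in (0.0, 40.0):
            dev = DeviceModel("d", systematic_axial_offset=off, intensity_noise_sd=0.0)
            scan, adj = simulate_device(spec, dev, seed=0)
            seg = simulate_rater(adj, scan, model, seed=1)
            areas.append(cross_sectional_area(seg, scan).area)
        assert areas[0] == pytest.approx(areas[1], rel=1e-9)

    def test_lateral_miscalibration_scales_the_bump_component(self):
        # stretching the lateral axis by c scales the compact bump integral by
        # ~c while the flat component, integrated over a fixed window, stays put
        spec = PhantomSpec(bump_amplitude=500.0, bump_sigma=600.0)
        model = RaterModel("r", **ZERO_NOISE)
        areas = {}
        for c in (1.0, 1.05):
            dev = DeviceModel("d", lateral_scale_error=c, intensity_noise_sd=0.0)
            scan, adj = simulate_device(spec, dev, seed=0)
            seg = simulate_rater(adj, scan, model, seed=1)
            areas[c] = cross_sectional_area(seg, scan).area
        bump_term = analytic_area(spec) - analytic_area(
            PhantomSpec(
                baseline_ilm_depth=spec.baseline_ilm_depth,
                bump_amplitude=0.0,
                bm_depth=spec.bm_depth,
            )
        )
        assert areas[1.05] - areas[1.0] == pytest.approx(0.05 * bump_term, rel=0.02)

    def test_axial_miscalibration_scales_the_whole_area(self):
        spec = PhantomSpec(bump_amplitude=300.0)
        model = RaterModel("r", **ZERO_NOISE)
        areas = {}
        for c in (1.0, 1.02):
            dev = DeviceModel("d", axial_scale_error=c, intensity_noise_sd=0.0)
            scan, adj = simulate_device(spec, dev, seed=0)
            seg = simulate_rater(adj, scan, model, seed=1)
            areas[c] = cross_sectional_area(seg, scan).area
        assert areas[1.02] / areas[1.0] == pytest.approx(1.02, rel=1e-4)


class TestGenerateStudy:
    def test_file_counts_follow_the_design(self, default_study_manifest):
        # 10 eyes x 3 devices x (3 raters + 1 repeat session) segmentations,
        # 10 x 3 scans
        root = default_study_manifest.parent
        assert len(list(root.glob("*.png"))) == 30
        assert len(list(root.glob("eye*_dev*.json"))) - 30 == 120  # 30 are sidecars

    def test_same_seed_gives_byte_identical_manifest(self, tmp_path, default_study_manifest):
        m2 = generate_study(tmp_path / "again", n_subjects=10, seed=0)
        assert m2.read_bytes() == default_study_manifest.read_bytes()

    def test_truth_areas_span_the_expected_range(self):
        areas = [analytic_area(s) for s in default_phantom_specs()]
        assert min(areas) >= 1.6 and max(areas) <= 3.4
        assert max(areas) - min(areas) > 1.0  # both normal and swollen morphologies

    def test_device_defaults_have_positive_scales(self):
        for dev in default_device_models():
            assert dev.axial_scale > 0 and dev.lateral_scale > 0
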