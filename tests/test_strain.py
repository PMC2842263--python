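"""Tag tracking and circumferential strain: fidelity vs analytic truth."""

import dataclasses

import numpy as np
import pytest

from hcmstrain.phantom import (
    AnnulusDeformation,
    ImagingParams,
    reference_contours,
    render_tagged_series,
)
from hcmstrain.segments import SegmentModel
from hcmstrain.strain import (
    MaterialPointSet,
    StrainCurve,
    analyze_tagged_series,
    circumferential_strain,
    peak_summary,
    strain_rate,
    track_tags,
)
from hcmstrain.timecourse import CardiacTiming, build_strain_timecourse

TIMING = CardiacTiming(950.0, 333.0, 435.0)


def _point_set(positions, times, segment_id=1):
    """Hand-built point set: positions (T, N, 2) mm."""
    n = positions.shape[1]
    return MaterialPointSet(
        ref_points_mm=positions[0],
        trajectories_mm=positions,
        times_ms=times,
        depth_fraction=np.full(n, 0.5),
        segment_id=np.full(n, segment_id),
        depth_band=np.zeros(n, dtype=int),
        valid=np.ones(n, dtype=bool),
        quality=np.ones(n),
    )


class TestTracking:
    def test_static_phantom_trajectories_constant(self, zero_strain_subject):
        imaging = ImagingParams(snr=np.inf, tag_fade_ms=np.inf, matrix=(128, 128))
        series, _ = render_tagged_series(zero_strain_subject, "basal", imaging)
        pts = track_tags(series, reference_contours(series, zero_strain_subject))
        drift = np.linalg.norm(pts.trajectories_mm - pts.trajectories_mm[0], axis=2)
        assert drift.max() < 0.05

    def test_rigid_translation_shared_by_all_trajectories(self, zero_strain_subject):
        imaging = ImagingParams(snr=np.inf, tag_fade_ms=np.inf, matrix=(128, 128))
        series, _ = render_tagged_series(
            zero_strain_subject, "basal", imaging, translation_mm=(3.0, -2.0)
        )
        pts = track_tags(series, reference_contours(series, zero_strain_subject))
        disp = pts.trajectories_mm[-1] - pts.trajectories_mm[0]
        frac = series.frame_times_ms[-1] / zero_strain_subject.cycle_ms
        expected = frac * np.array([3.0, -2.0])
        assert np.abs(disp - expected).max() < 0.15
        model = SegmentModel("basal", series.anchor_angle)
        curves = circumferential_strain(pts, model)
        for c in curves:
            assert np.abs(c.strain_pct).max() < 0.5

    def test_noise_free_accuracy_against_ground_truth(self, tracked_basal,
                                                      carrier_subject):
        series, contours, gt = tracked_basal
        pts = track_tags(series, contours)
        # trajectory error against the analytic forward map
        deform = AnnulusDeformation(carrier_subject, "basal")
        center = np.array(series.center_mm)
        d = pts.ref_points_mm - center
        th = np.arctan2(d[:, 1], d[:, 0])
        R = np.hypot(d[:, 0], d[:, 1])
        sq = 0.0
        for k, t in enumerate(pts.times_ms):
            r_true = deform.material_position(R, th, t)
            truth = center + np.column_stack(
                [r_true * np.cos(th), r_true * np.sin(th)]
            )
            sq += np.mean(
                np.sum((pts.trajectories_mm[k] - truth) ** 2, axis=1)
            )
        rms = np.sqrt(sq / len(pts.times_ms))
        assert rms < 0.5  # mm, the fidelity contract
        assert pts.valid.all()

    def test_points_restricted_to_mid_wall_band(self, tracked_basal):
        series, contours, _ = tracked_basal
        pts = track_tags(series, contours)
        assert np.all((pts.depth_fraction >= 0.25) & (pts.depth_fraction <= 0.75))

    def test_missing_contours_rejected(self, tracked_basal):
        series, contours, _ = tracked_basal
        with pytest.raises(ValueError, match="epi"):
            track_tags(series, {"endo": contours["endo"]})


class TestStrainComputation:
    def test_chord_shortening_formula(self):
        # two points 5 mm apart shrinking to 4 mm: E = -20 %
        pos = np.array(
            [[[0.0, 0.0], [5.0, 0.0]], [[0.0, 0.0], [4.0, 0.0]]]
        )
        pts = _point_set(pos, np.array([0.0, 100.0]))
        curves = circumferential_strain(pts, SegmentModel("basal"))
        c1 = [c for c in curves if c.segment_id == 1][0]
        assert c1.strain_pct[1] == pytest.approx(-20.0)
        assert c1.strain_pct[0] == 0.0
        for c in curves:
            if c.segment_id != 1:
                assert not c.analyzable

    def test_rigid_rotation_gives_zero_strain(self):
        th = np.linspace(0.1, 0.4, 6)
        ref = np.column_stack([30 * np.cos(th), 30 * np.sin(th)])
        rot = th + 0.3
        cur = np.column_stack([30 * np.cos(rot), 30 * np.sin(rot)])
        pts = _point_set(np.stack([ref, cur]), np.array([0.0, 50.0]))
        c1 = [c for c in circumferential_strain(pts, SegmentModel("basal"))
              if c.segment_id == 1][0]
        assert abs(c1.strain_pct[1]) < 1e-9

    def test_phantom_segment_curves_match_truth(self, tracked_basal,
                                                carrier_subject):
        series, contours, gt = tracked_basal
        curves, summaries = analyze_tagged_series(series, contours,
                                                  carrier_subject.timing)
        for c, s in zip(curves, summaries):
            i = c.segment_id - 1
            true = carrier_subject.strain_curve(c.segment_id).value(c.times_ms)
            assert np.abs(c.strain_pct - true).max() < 1.0  # percent strain
            assert s.peak_scs_pct == pytest.approx(gt.peak_scs_pct[i], abs=1.0)
            assert s.peak_dcsr_pct_s == pytest.approx(gt.peak_dcsr_pct_s[i],
                                                      abs=5.0)
            assert s.peak_dcsr_time_ms > carrier_subject.timing.aortic_closure_ms

    def test_repeated_analysis_is_bit_identical(self, tracked_basal,
                                                carrier_subject):
        series, contours, _ = tracked_basal
        c1, s1 = analyze_tagged_series(series, contours, carrier_subject.timing)
        c2, s2 = analyze_tagged_series(series, contours, carrier_subject.timing)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.strain_pct, b.strain_pct)
        assert [x.peak_dcsr_pct_s for x in s1] == [x.peak_dcsr_pct_s for x in s2]


class TestRateAndPeaks:
    def test_linear_ramp_rate(self):
        t = np.arange(0.0, 201.0, 10.0)
        c = StrainCurve(1, t, -10.0 * t / 200.0)
        r = strain_rate(c, smooth=False)
        assert np.allclose(r, -50.0)

    def test_constant_curve_zero_rate(self):
        t = np.arange(0.0, 100.0, 10.0)
        r = strain_rate(StrainCurve(1, t, np.zeros_like(t)), smooth=True)
        assert not r.any()

    def test_non_monotonic_time_rejected(self):
        t = np.array([0.0, 10.0, 5.0, 20.0])
        with pytest.raises(ValueError):
            strain_rate(StrainCurve(1, t, np.zeros(4)))

    def test_sampled_generator_curve_recovers_dcsr_within_3_percent(self):
        curve = build_strain_timecourse(-20.0, 290.0, 115.0, TIMING)
        for dt, tol in ((14.1, 0.03), (28.2, 0.06)):
            t = np.arange(0.0, TIMING.cycle_ms, dt)
            sc = StrainCurve(1, t, curve.value(t))
            r = strain_rate(sc, smooth=True)
            dia = t > TIMING.aortic_closure_ms
            assert r[dia].max() == pytest.approx(115.0, rel=tol)

    def test_finer_sampling_does_not_worsen_peak_recovery(self):
        curve = build_strain_timecourse(-18.0, 300.0, 95.0, TIMING)

        def err(dt):
            t = np.arange(0.0, TIMING.cycle_ms, dt)
            r = strain_rate(StrainCurve(1, t, curve.value(t)), smooth=True)
            dia = t > TIMING.aortic_closure_ms
            return abs(r[dia].max() - 95.0)

        assert err(14.1) <= err(28.2) + 0.5

    def test_peak_summary_on_constructed_curve(self):
        curve = build_strain_timecourse(-17.8, 290.0, 105.0, TIMING)
        t = np.arange(0.0, TIMING.cycle_ms, 2.0)
        sc = StrainCurve(1, t, curve.value(t))
        s = peak_summary(sc, strain_rate(sc, smooth=False), TIMING)
        assert s.peak_scs_pct == pytest.approx(-17.8, abs=1e-6)
        assert s.peak_dcsr_pct_s == pytest.approx(105.0, rel=0.01)

    def test_zero_curve_zero_peaks(self):
        t = np.arange(0.0, 950.0, 10.0)
        sc = StrainCurve(1, t, np.zeros_like(t))
        s = peak_summary(sc, strain_rate(sc), TIMING)
        assert s.peak_scs_pct == 0.0 and s.peak_dcsr_pct_s == 0.0

    def test_no_diastolic_frames_is_an_error(self):
        t = np.arange(0.0, 300.0, 10.0)  # ends before aortic closure
        sc = StrainCurve(1, t, np.zeros_like(t))
        with pytest.raises(ValueError):
            peak_summary(sc, np.zeros_like(t), TIMING)
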