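"""Morphometry: closed-form oracles and phantom round trips."""

import dataclasses

import numpy as np
import pytest

from hcmstrain.morphometry import (
    ContourError,
    ed_wall_radius,
    ivrt,
    la_analysis,
    lv_volumes,
    morphometry_from_cine,
    segment_thickness,
    sl_ratio,
    wall_thickening,
)
from hcmstrain.cohort import ground_truth
from hcmstrain.phantom import ImagingParams, render_cine_stack
from hcmstrain.segments import SegmentModel
from hcmstrain.timecourse import CardiacTiming, la_volume_curve

TIMING = CardiacTiming(950.0, 333.0, 435.0)


def _circle(r, n=240, center=(0.0, 0.0)):
    a = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(a),
                            center[1] + r * np.sin(a)])


class TestThickness:
    def test_annulus_thickness_exact(self):
        st = segment_thickness(_circle(31.0), _circle(25.0), SegmentModel("basal"))
        assert st.analyzable.all()
        assert np.allclose(st.mean_mm, 6.0, atol=1e-3)
        assert np.allclose(st.max_chord_mm, 6.0, atol=1e-3)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        radii = 25.0 + rng.uniform(-2, 2, 240)
        a = np.linspace(0, 2 * np.pi, 240, endpoint=False)
        endo = np.column_stack([radii * np.cos(a), radii * np.sin(a)])
        epi = np.column_stack([(radii + 6) * np.cos(a), (radii + 6) * np.sin(a)])
        base = segment_thickness(epi, endo, SegmentModel("basal", np.pi / 2))
        phi = 0.7
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rotated = segment_thickness(
            epi @ rot.T, endo @ rot.T, SegmentModel("basal", np.pi / 2 + phi)
        )
        assert np.allclose(base.mean_mm, rotated.mean_mm, atol=0.05)

    def test_phantom_segment_thickness_round_trip(self, carrier_subject):
        sub = dataclasses.replace(
            carrier_subject,
            edwt_mm=np.where(
                np.isin(np.arange(1, 17), (2, 3, 8, 9, 14)), 7.3, 5.0
            ),
        )
        stack = render_cine_stack(sub, ImagingParams())
        gt = ground_truth(sub)
        rec = morphometry_from_cine(stack, sub.subject_id, sub.bsa_m2, sub.timing)
        assert np.nanmax(np.abs(rec.edwt_mm - gt.edwt_mm)) < 0.2

    def test_degenerate_contours_rejected(self):
        with pytest.raises(ContourError):
            segment_thickness(_circle(31.0)[:2], _circle(25.0),
                              SegmentModel("basal"))


class TestScalars:
    def test_wall_thickening_formula_and_round_trip(self):
        assert wall_thickening(5.0, 8.0) == pytest.approx(0.60)
        assert wall_thickening(6.0, 6.0) == 0.0
        # inverse arithmetic round trip
        eswt = 6.1 * (1.0 + 0.65)
        assert eswt == pytest.approx(10.065)
        assert wall_thickening(6.1, eswt) == pytest.approx(0.65)
        with pytest.raises(ValueError):
            wall_thickening(0.0, 5.0)

    def test_sl_ratio(self):
        assert sl_ratio({3: 7.2, 6: 6.0}) == pytest.approx(1.2)
        assert sl_ratio({s: 6.0 for s in range(1, 17)}) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sl_ratio({3: 7.2})  # no lateral segment measured

    def test_ed_wall_radius(self):
        assert ed_wall_radius(_circle(25.0)) == pytest.approx(25.0, abs=0.01)
        assert ed_wall_radius(_circle(25.0, center=(40, -13))) == pytest.approx(
            25.0, abs=0.01
        )
        # ellipse: compare against dense numerical quadrature of the
        # centroid-to-boundary distance over arc length
        a, b = 30.0, 20.0
        tt = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        pts = np.column_stack([a * np.cos(tt), b * np.sin(tt)])
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        expected = np.sum(np.linalg.norm(pts, axis=1) * seg) / seg.sum()
        assert ed_wall_radius(pts) == pytest.approx(expected, rel=1e-3)

    def test_ivrt(self):
        assert ivrt(350.0, 452.0) == 102.0
        assert ivrt(400.0, 400.0) == 0.0
        with pytest.raises(ValueError):
            ivrt(452.0, 350.0)


class TestVolumes:
    def test_ellipsoid_slice_summation_within_2_percent(self):
        # half-ellipsoid cavity a=b=25, c=80 mm, fine slices
        c_ax, r_ax = 80.0, 25.0
        dz = 2.0
        z = np.arange(dz / 2, c_ax, dz)
        endo, epi = {}, {}
        for i, zi in enumerate(z):
            r = r_ax * np.sqrt(1 - (zi / c_ax) ** 2)
            endo[(i, 0)] = _circle(max(r, 1e-3))
            epi[(i, 0)] = _circle(max(r, 1e-3) + 6.0)
        vols = lv_volumes(endo, epi, dz, 1, list(range(len(z))))
        analytic = 2.0 / 3.0 * np.pi * r_ax**2 * c_ax / 1000.0
        assert vols.lvedv_ml == pytest.approx(analytic, rel=0.02)

    def test_equal_volumes_zero_ef(self):
        endo = {(0, p): _circle(25.0) for p in range(3)}
        epi = {(0, p): _circle(31.0) for p in range(3)}
        v = lv_volumes(endo, epi, 10.0, 3, [0])
        assert v.lvef_pct == 0.0

    def test_missing_slices_reported(self):
        endo = {(0, 0): _circle(25.0)}
        with pytest.raises(ContourError, match="missing"):
            lv_volumes(endo, endo, 10.0, 1, [0, 1])

    def test_phantom_volume_round_trip(self, carrier_subject):
        stack = render_cine_stack(carrier_subject, ImagingParams())
        gt = ground_truth(carrier_subject)
        rec = morphometry_from_cine(stack, carrier_subject.subject_id,
                                    carrier_subject.bsa_m2,
                                    carrier_subject.timing)
        rec.validate()
        assert rec.lvedv_ml_m2 == pytest.approx(gt.lvedv_ml_m2, rel=0.02)
        assert rec.lvesv_ml_m2 == pytest.approx(gt.lvesv_ml_m2, rel=0.02)
        assert rec.lvef_pct == pytest.approx(gt.lvef_pct, abs=1.0)
        assert rec.la_max_ml_m2 == pytest.approx(gt.la_max_ml_m2, rel=0.02)
        assert rec.la_min_ml_m2 == pytest.approx(gt.la_min_ml_m2, rel=0.02)
        assert rec.sl_ratio == pytest.approx(gt.sl_ratio, rel=0.02)


class TestLADecomposition:
    def test_constructed_curve_landmarks_recovered(self):
        v = la_volume_curve(24.0, 56.0, 19.0, 14.0, TIMING)
        la = la_analysis(v.times_ms, v.volumes_ml, TIMING)
        assert la.diastasis_defined
        assert la.la_max_ml == pytest.approx(56.0, abs=0.1)
        assert la.la_min_ml == pytest.approx(24.0, abs=0.1)
        assert la.la_diastasis_ml == pytest.approx(37.0, abs=0.3)
        assert la.la_preA_ml == pytest.approx(38.0, abs=0.3)
        assert la.la_reservoir_ml == pytest.approx(
            la.la_max_ml - la.la_min_ml
        )
        assert la.laef_pct == pytest.approx(
            100 * la.la_active_ml / la.la_preA_ml
        )

    def test_constant_curve_all_derived_volumes_zero(self):
        la = la_analysis(np.linspace(0, 950, 50), np.full(50, 30.0))
        assert la.la_reservoir_ml == la.la_passive_ml == la.la_active_ml == 0.0
        assert not la.diastasis_defined

    def test_short_diastole_flags_diastasis_undefined(self):
        # high heart rate: passive emptying runs straight into the kick
        fast = CardiacTiming(480.0, 170.0, 230.0)
        v = la_volume_curve(24.0, 50.0, 18.0, 12.0, fast)
        la = la_analysis(v.times_ms, v.volumes_ml, fast)
        assert la.la_max_ml == pytest.approx(50.0, abs=0.1)
        # identities still hold even when the plateau is degenerate
        assert la.la_passive_ml == pytest.approx(
            la.la_max_ml - la.la_diastasis_ml
        )
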