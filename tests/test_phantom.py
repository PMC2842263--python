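"""Phantom rendering: incompressibility, scale invariance, determinism."""

import dataclasses

import numpy as np
import pytest

from hcmstrain.phantom import (
    AnnulusDeformation,
    ImagingParams,
    RenderError,
    render_cine_stack,
    render_tagged_series,
)
from hcmstrain.morphometry import _polygon_area
from hcmstrain.timecourse import lv_volume_curve


def test_ring_area_conserved_through_the_cycle(carrier_subject):
    """The tagged-phantom deformation is exactly area-preserving."""
    deform = AnnulusDeformation(carrier_subject, "basal")
    th = np.linspace(0, 2 * np.pi, 4096, endpoint=False)

    def ring_area(t):
        r_en = deform.material_position(np.full_like(th, deform.r_endo0), th, t)
        r_ep = deform.material_position(deform.r_epi0(th), th, t)
        return 0.5 * np.trapezoid(
            np.r_[r_ep**2 - r_en**2, r_ep[0] ** 2 - r_en[0] ** 2],
            np.r_[th, 2 * np.pi],
        )

    a0 = ring_area(0.0)
    for t in np.linspace(0, carrier_subject.cycle_ms, 9):
        assert ring_area(t) == pytest.approx(a0, rel=0.005)


def test_wall_thickening_follows_incompressible_ring_formula(carrier_subject):
    """In the tagged phantom, thickness is h = A/(2 pi r_mid): check the
    rendered wall against the analytic formula at end-systole."""
    deform = AnnulusDeformation(carrier_subject, "basal")
    t_es = carrier_subject.timing.aortic_closure_ms
    th = deform.model.segment_center_angle(deform.model.segment_ids[0])
    lam = float(deform.stretch(np.array([th]), t_es)[0])
    r_en = float(deform.material_position(deform.r_endo0, th, t_es))
    r_ep = float(deform.material_position(float(deform.r_epi0(th)), th, t_es))
    h0 = float(deform.wall_thickness0(th))
    rm0 = deform.r_endo0 + h0 / 2.0
    # area conservation: 2 pi r_mid h constant => h_es = h0 * rm0 / rm_es
    rm_es = lam * rm0
    assert (r_ep - r_en) == pytest.approx(h0 * rm0 / rm_es, rel=0.01)


def test_uniform_strain_scales_midwall_circumference_exactly(carrier_subject):
    sub = dataclasses.replace(carrier_subject, peak_scs_pct=np.full(16, -10.0))
    deform = AnnulusDeformation(sub, "mid")
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    rm0 = deform.r_mid0(th)
    t_es = sub.timing.aortic_closure_ms
    r = deform.material_position(rm0, th, t_es)
    assert np.allclose(r / rm0, 0.90, atol=1e-9)


def test_scale_invariance_of_strain_and_thickening(carrier_subject):
    scaled = dataclasses.replace(
        carrier_subject,
        edwt_mm=1.5 * carrier_subject.edwt_mm,
        endo_radius_mm=1.5 * carrier_subject.endo_radius_mm,
    )
    d1 = AnnulusDeformation(carrier_subject, "basal")
    d2 = AnnulusDeformation(scaled, "basal")
    th = np.linspace(0, 2 * np.pi, 64)
    for t in (100.0, 300.0, 600.0):
        assert np.allclose(d1.stretch(th, t), d2.stretch(th, t), atol=1e-12)


def test_zero_strain_subject_renders_static_frames(zero_strain_subject):
    imaging = ImagingParams(snr=np.inf, tag_fade_ms=np.inf)
    series, gt = render_tagged_series(zero_strain_subject, "basal", imaging)
    assert np.array_equal(series.frames[0], series.frames[-1])
    assert not gt.peak_scs_pct.any()


def test_render_is_deterministic_for_fixed_seed(carrier_subject):
    im = ImagingParams(matrix=(96, 96), snr=20.0)
    s1, _ = render_tagged_series(carrier_subject, "basal", im, seed=9)
    s2, _ = render_tagged_series(carrier_subject, "basal", im, seed=9)
    assert np.array_equal(s1.frames, s2.frames)
    s3, _ = render_tagged_series(carrier_subject, "basal", im, seed=10)
    assert not np.array_equal(s1.frames, s3.frames)


def test_negative_wall_radius_raises_naming_segment(carrier_subject):
    bad = dataclasses.replace(
        carrier_subject,
        peak_scs_pct=np.full(16, -60.0),
        peak_dcsr_pct_s=np.full(16, 400.0),
    )
    with pytest.raises(RenderError, match="segment"):
        render_tagged_series(bad, "basal", ImagingParams(snr=np.inf))


class TestCine:
    def test_twenty_phases_and_determinism(self, carrier_subject):
        stack = render_cine_stack(carrier_subject, ImagingParams())
        phases = {k[1] for k in stack.contours}
        assert phases == set(range(20))
        s2 = render_cine_stack(carrier_subject, ImagingParams())
        for k in stack.contours:
            assert np.array_equal(stack.contours[k], s2.contours[k])

    def test_slice_summation_reproduces_the_volume_curve(self, carrier_subject):
        sub = carrier_subject
        stack = render_cine_stack(sub, ImagingParams())
        curve = lv_volume_curve(
            sub.lvedv_ml_m2 * sub.bsa_m2,
            sub.lvesv_ml_m2 * sub.bsa_m2,
            sub.timing,
            sub.atrial_kick_fraction,
        )
        for p, t in enumerate(stack.phase_times_ms):
            v = sum(
                _polygon_area(stack.contours[(i, p, "lv_endo")])
                for i in stack.lv_slices
            ) * stack.slice_extent_mm / 1000.0
            assert v == pytest.approx(float(curve.value(t)), rel=0.01)

    def test_endo_strictly_inside_epi(self, carrier_subject):
        stack = render_cine_stack(carrier_subject, ImagingParams())
        for i in stack.lv_slices:
            for p in range(stack.n_phases):
                en = np.linalg.norm(stack.contours[(i, p, "lv_endo")], axis=1)
                ep = np.linalg.norm(stack.contours[(i, p, "lv_epi")], axis=1)
                assert np.all(ep > en)
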