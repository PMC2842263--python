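"""Tag tracking and segmental Lagrangian circumferential strain.

Material points seeded on the mid 50 % of the wall at the reference phase
(end-diastole) are tracked through the tagged series by harmonic-phase
tracking: each of the two sinusoidal tag-line families contributes one
spectral harmonic; band-pass filtering around the two harmonic peaks (with a
notch suppressing the anatomy's DC/low-frequency content) yields two complex
images whose phases are material coordinates, invariant to tag fading.  A
point is followed by Newton iteration on the phase-constancy equations from
its position in the previous frame, with the phase Jacobian computed
analytically from the filtered complex images.  Track quality is the local
harmonic magnitude relative to the reference frame; segments losing track
are flagged, never interpolated.

Circumferential Lagrangian strain of a segment is the mean over adjacent
mid-wall point pairs of the percent change in chord length relative to the
reference phase:

    E_cc(t) = 100 * (L(t) - L0) / L0

Shortening is negative.  The strain rate is obtained by central finite
differences of the (optionally 3-point smoothed) strain curve; peak SCS is
the curve minimum and peak DCSR the maximum rate after aortic valve closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy import ndimage

from .phantom import TaggedSeries
from .segments import SegmentModel
from .timecourse import CardiacTiming

__all__ = [
    "MaterialPointSet",
    "StrainCurve",
    "StrainSummary",
    "track_tags",
    "circumferential_strain",
    "strain_rate",
    "peak_summary",
    "analyze_tagged_series",
]

#: wall-depth band (fraction of wall thickness) used for strain: mid 50 %
DEPTH_BAND = (0.25, 0.75)
_SEED_DEPTHS = (0.4, 0.6)
_SEED_ANGLES_PER_SEGMENT = 6


@dataclass
class MaterialPointSet:
    """Tracked mid-wall material points of one tagged slice."""

    ref_points_mm: np.ndarray  # (N, 2), image coords, reference phase
    trajectories_mm: np.ndarray  # (n_frames, N, 2)
    times_ms: np.ndarray
    depth_fraction: np.ndarray  # (N,)
    segment_id: np.ndarray  # (N,)
    depth_band: np.ndarray  # (N,) index into _SEED_DEPTHS
    valid: np.ndarray  # (N,) bool: track kept harmonic magnitude/convergence
    quality: np.ndarray  # (N,) min relative harmonic magnitude along track

    def __post_init__(self) -> None:
        lo, hi = DEPTH_BAND
        if np.any((self.depth_fraction < lo) | (self.depth_fraction > hi)):
            raise ValueError("material points must lie on the mid 50% of the wall")


@dataclass(frozen=True)
class StrainCurve:
    """Circumferential strain (%) of one segment over the cycle."""

    segment_id: int
    times_ms: np.ndarray
    strain_pct: np.ndarray
    analyzable: bool = True

    def __post_init__(self) -> None:
        if self.analyzable:
            if abs(self.strain_pct[0]) > 1e-9:
                raise ValueError("strain at the reference phase must be 0")
            if not np.all(np.isfinite(self.strain_pct)):
                raise ValueError("strain curve contains non-finite values")


@dataclass(frozen=True)
class StrainSummary:
    segment_id: int
    peak_scs_pct: float
    peak_scs_time_ms: float
    peak_dcsr_pct_s: float
    peak_dcsr_time_ms: float
    analyzable: bool = True


# ---------------------------------------------------------------------------
# harmonic-phase tracking


def _harmonic_filters(shape, pixel_spacing_mm, tag_spacing_mm,
                      sigma_frac=0.4, notch_frac=0.5):
    ny, nx = shape
    dy, dx = pixel_spacing_mm
    ky = fftfreq(ny, d=dy)[:, None]
    kx = fftfreq(nx, d=dx)[None, :]
    f0 = 1.0 / tag_spacing_mm
    sig = sigma_frac * f0
    notch = 1.0 - np.exp(-(kx**2 + ky**2) / (2.0 * (notch_frac * f0) ** 2))
    mx = np.exp(-(((kx - f0) ** 2) + ky**2) / (2.0 * sig**2)) * notch
    my = np.exp(-((ky - f0) ** 2 + kx**2) / (2.0 * sig**2)) * notch
    return mx, my


def _sample_complex(h, pos_px):
    re = ndimage.map_coordinates(h.real, pos_px.T, order=1, mode="nearest")
    im = ndimage.map_coordinates(h.imag, pos_px.T, order=1, mode="nearest")
    return re + 1j * im


def _radial_profile(contour_mm: np.ndarray, center: np.ndarray):
    d = contour_mm - center
    ang = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
    rad = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(ang)
    return ang[order], rad[order]


def _radius_at(theta, ang, rad):
    return np.interp(np.mod(theta, 2 * np.pi), ang, rad, period=2 * np.pi)


def track_tags(
    series: TaggedSeries,
    reference_contours: dict,
    quality_threshold: float = 0.2,
    newton_iterations: int = 5,
    max_step_mm: float = 3.0,
) -> MaterialPointSet:
    """Track mid-wall material points through a tagged series.

    Parameters
    ----------
    reference_contours : dict with "endo" and "epi" (N, 2) mm point lists
        delineating the myocardium at the reference phase (frame 0).
    quality_threshold : float
        A point whose local harmonic magnitude falls below this fraction of
        its reference-frame magnitude (corrected for tag fading) loses its
        track and is flagged invalid.
    """
    for key in ("endo", "epi"):
        if key not in reference_contours:
            raise ValueError(f"reference contours missing {key!r}")
    center = np.asarray(series.center_mm, dtype=float)
    ang_en, rad_en = _radial_profile(np.asarray(reference_contours["endo"]), center)
    ang_ep, rad_ep = _radial_profile(np.asarray(reference_contours["epi"]), center)

    model = SegmentModel(series.slice_label, series.anchor_angle)
    seg_ids, depths, bands, pts = [], [], [], []
    for s in model.segment_ids:
        lo, hi = model.sector_bounds(s)
        width = hi - lo
        fr = (np.arange(_SEED_ANGLES_PER_SEGMENT) + 0.5) / _SEED_ANGLES_PER_SEGMENT
        ths = lo + (0.2 + 0.6 * fr) * width  # central 60%: clear of blending
        for bi, depth in enumerate(_SEED_DEPTHS):
            for th in ths:
                re_ = _radius_at(th, ang_en, rad_en)
                rp_ = _radius_at(th, ang_ep, rad_ep)
                r = re_ + depth * (rp_ - re_)
                pts.append(center + r * np.array([np.cos(th), np.sin(th)]))
                seg_ids.append(s)
                depths.append(depth)
                bands.append(bi)
    pts = np.asarray(pts)
    n_pts = len(pts)

    dy, dx = series.pixel_spacing_mm
    ny, nx = series.frames.shape[1:]
    mx, my = _harmonic_filters((ny, nx),
                               series.pixel_spacing_mm, series.tag_spacing_mm)
    # demodulation carriers: interpolating the slowly-varying complex
    # envelope (carrier removed analytically) avoids the phase bias of
    # interpolating an oscillation sampled at ~6 px/period
    k0 = 2.0 * np.pi / series.tag_spacing_mm
    xg = (np.arange(nx) + 0.5) * dx
    yg = (np.arange(ny) + 0.5) * dy
    carrier_x = np.exp(-1j * k0 * xg)[None, :] * np.ones((ny, 1))
    carrier_y = np.exp(-1j * k0 * yg)[:, None] * np.ones((1, nx))

    def harmonics(img):
        F = fft2(img.astype(float))
        return ifft2(F * mx) * carrier_x, ifft2(F * my) * carrier_y

    def to_px(p_mm):  # (N,2) mm (x,y) -> (N,2) px (row,col)
        return np.column_stack([p_mm[:, 1] / dy - 0.5, p_mm[:, 0] / dx - 0.5])

    def phases(hx_env, hy_env, pp, p_mm):
        """Total harmonic phases (carrier restored) at sample points."""
        ex = _sample_complex(hx_env, pp)
        ey = _sample_complex(hy_env, pp)
        return ex, ey, np.column_stack([
            np.angle(ex) + k0 * p_mm[:, 0],
            np.angle(ey) + k0 * p_mm[:, 1],
        ])

    n_frames = series.frames.shape[0]
    hx0, hy0 = harmonics(series.frames[0])
    p0 = to_px(pts)
    ref_x, ref_y, phi0 = phases(hx0, hy0, p0, pts)
    mag0 = np.minimum(np.abs(ref_x), np.abs(ref_y))

    traj = np.empty((n_frames, n_pts, 2))
    traj[0] = pts
    valid = np.ones(n_pts, dtype=bool)
    quality = np.ones(n_pts)
    med0 = float(np.median(np.abs(hx0)) + np.median(np.abs(hy0)))

    for k in range(1, n_frames):
        hx, hy = harmonics(series.frames[k])
        # global tag-fading correction for the quality measure
        fade_scale = (
            float(np.median(np.abs(hx)) + np.median(np.abs(hy))) / med0
        )
        gx_y, gx_x = np.gradient(hx)
        gy_y, gy_x = np.gradient(hy)
        cur = traj[k - 1].copy()
        for _ in range(newton_iterations):
            pp = to_px(cur)
            hvx, hvy, phi = phases(hx, hy, pp, cur)
            m2x = np.maximum(np.abs(hvx) ** 2, 1e-12)
            m2y = np.maximum(np.abs(hvy) ** 2, 1e-12)
            # phase Jacobian (rad/px) = envelope part + carrier part
            jxx = (np.conj(hvx) * _sample_complex(gx_x, pp)).imag / m2x + k0 * dx
            jxy = (np.conj(hvx) * _sample_complex(gx_y, pp)).imag / m2x
            jyx = (np.conj(hvy) * _sample_complex(gy_x, pp)).imag / m2y
            jyy = (np.conj(hvy) * _sample_complex(gy_y, pp)).imag / m2y + k0 * dy
            dphix = np.angle(np.exp(1j * (phi[:, 0] - phi0[:, 0])))
            dphiy = np.angle(np.exp(1j * (phi[:, 1] - phi0[:, 1])))
            det = jxx * jyy - jxy * jyx
            ok = np.abs(det) > 1e-9
            det = np.where(ok, det, 1.0)
            dcol = (jyy * dphix - jxy * dphiy) / det
            drow = (-jyx * dphix + jxx * dphiy) / det
            step = np.column_stack([dcol * dx, drow * dy])
            step = np.clip(step, -max_step_mm, max_step_mm)
            step[~ok | ~valid] = 0.0
            cur = cur - step
        pp = to_px(cur)
        mag = np.minimum(np.abs(_sample_complex(hx, pp)),
                         np.abs(_sample_complex(hy, pp)))
        rel = mag / np.maximum(mag0 * fade_scale, 1e-12)
        quality = np.minimum(quality, rel)
        lost = valid & (rel < quality_threshold)
        valid[lost] = False
        cur[~valid] = traj[k - 1][~valid]
        traj[k] = cur

    # depth fraction at reference
    d = pts - center
    th = np.arctan2(d[:, 1], d[:, 0])
    r = np.hypot(d[:, 0], d[:, 1])
    re_ = _radius_at(th, ang_en, rad_en)
    rp_ = _radius_at(th, ang_ep, rad_ep)
    depth_frac = (r - re_) / np.maximum(rp_ - re_, 1e-9)

    return MaterialPointSet(
        ref_points_mm=pts,
        trajectories_mm=traj,
        times_ms=series.frame_times_ms.astype(float),
        depth_fraction=np.clip(depth_frac, *DEPTH_BAND),
        segment_id=np.asarray(seg_ids),
        depth_band=np.asarray(bands),
        valid=valid,
        quality=quality,
    )


# ---------------------------------------------------------------------------
# strain


def circumferential_strain(points: MaterialPointSet,
                           model: SegmentModel) -> list[StrainCurve]:
    """Per-segment Lagrangian circumferential strain curves.

    Segments with fewer than two valid points in every depth band are
    flagged unanalyzable and excluded from summaries.
    """
    curves = []
    t = points.times_ms
    for s in model.segment_ids:
        pair_strains = []
        for band in np.unique(points.depth_band):
            sel = (
                (points.segment_id == s)
                & (points.depth_band == band)
                & points.valid
            )
            idx = np.where(sel)[0]
            if len(idx) < 2:
                continue
            # order along the circumference
            ref = points.ref_points_mm[idx]
            c = ref.mean(axis=0)
            order = np.argsort(np.arctan2(ref[:, 1] - c[1], ref[:, 0] - c[0]))
            idx = idx[order]
            p = points.trajectories_mm[:, idx, :]  # (T, m, 2)
            seg_len = np.linalg.norm(np.diff(p, axis=1), axis=2)  # (T, m-1)
            l0 = seg_len[0]
            pair_strains.append(100.0 * (seg_len - l0) / l0)
        if not pair_strains:
            curves.append(
                StrainCurve(s, t, np.full_like(t, np.nan, dtype=float), False)
            )
            continue
        e = np.concatenate(pair_strains, axis=1).mean(axis=1)
        e[0] = 0.0  # exact by definition of Lagrangian strain
        curves.append(StrainCurve(s, t, e, True))
    return curves


def strain_rate(curve: StrainCurve, smooth: bool = True) -> np.ndarray:
    """Strain rate (%/s) by central differences; optional 3-point moving
    average of the strain curve before differentiation."""
    t = curve.times_ms
    if len(t) < 3:
        raise ValueError("need at least 3 phases for a strain rate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    e = curve.strain_pct
    if smooth and len(e) >= 3:
        e = np.convolve(e, np.ones(3) / 3.0, mode="same")
        e[0], e[-1] = curve.strain_pct[0], curve.strain_pct[-1]
    return np.gradient(e, t) * 1000.0


def peak_summary(
    curve: StrainCurve,
    rate_pct_s: np.ndarray,
    timing: CardiacTiming,
) -> StrainSummary:
    """Peak systolic circumferential strain (curve minimum) and peak
    diastolic circumferential strain rate (max rate after aortic closure)."""
    if not curve.analyzable:
        return StrainSummary(curve.segment_id, np.nan, np.nan, np.nan, np.nan, False)
    t = curve.times_ms
    if not 0.0 < timing.aortic_closure_ms < t[-1]:
        raise ValueError("aortic closure time outside the sampled cycle")
    dia = t > timing.aortic_closure_ms
    if not dia.any():
        raise ValueError("no diastolic frames after aortic valve closure")
    i_min = int(np.argmin(curve.strain_pct))
    i_dcsr = int(np.where(dia)[0][np.argmax(rate_pct_s[dia])])
    return StrainSummary(
        segment_id=curve.segment_id,
        peak_scs_pct=float(curve.strain_pct[i_min]),
        peak_scs_time_ms=float(t[i_min]),
        peak_dcsr_pct_s=float(rate_pct_s[i_dcsr]),
        peak_dcsr_time_ms=float(t[i_dcsr]),
        analyzable=True,
    )


def analyze_tagged_series(
    series: TaggedSeries,
    reference_contours: dict,
    timing: CardiacTiming,
    smooth: bool = True,
) -> tuple[list[StrainCurve], list[StrainSummary]]:
    """Convenience pipeline: track, strain, summarize one tagged slice."""
    points = track_tags(series, reference_contours)
    model = SegmentModel(series.slice_label, series.anchor_angle)
    curves = circumferential_strain(points, model)
    summaries = [
        peak_summary(c, strain_rate(c, smooth) if c.analyzable
                     else np.full_like(c.times_ms, np.nan), timing)
        for c in curves
    ]
    return curves, summaries
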