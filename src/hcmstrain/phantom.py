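"""Deforming left-ventricular phantom rendering: tagged series and cine stacks.

Tagged short-axis series
------------------------
The myocardium is an annulus deformed by a pure-radial, exactly
area-preserving map driven by the segmental mid-wall circumferential strain
curves: a material point at reference radius R and angle Theta moves to

    r(R, Theta, t) = sqrt(R^2 + c(Theta, t)),    theta = Theta,
    c(Theta, t)    = R_mid(Theta)^2 * (lambda(Theta, t)^2 - 1),

where lambda = 1 + E_cc/100 is the mid-wall circumferential stretch
(interpolated smoothly over angle between segment centres).  The Jacobian of
this map is identically 1, so the ring's cross-sectional area is conserved
exactly at every phase, and the mid-wall material circle's circumference
scales exactly by lambda -- the rendered ground truth is analytic.  A
SPAMM-like grid of two orthogonal sinusoidal tag-line families is imprinted
in material coordinates at the reference phase, advected by the inverse map,
faded monoexponentially, and optionally corrupted by additive Gaussian noise.

Cine stacks
-----------
Cine slices cover the LV cavity (half-ellipsoid taper, slice areas scaled so
slice summation integrates exactly to the subject's LV volume curve) plus a
spherical LA compartment matched to the LA volume curve.  Epicardial contours
follow the sampled per-segment wall-thickness time-course (end-diastolic
thickness to end-systolic thickness at the sampled peak thickening), which
carries the through-plane contribution to wall thickening that the in-plane
tagged deformation cannot represent.  True contours are exported per slice
and phase; downstream morphometry consumes the contours, not the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import GroundTruth, PhantomSubject, ground_truth
from .segments import SEGMENT_IDS, SegmentModel, SLICES
from .timecourse import la_volume_curve, lv_volume_curve

__all__ = [
    "ImagingParams",
    "TaggedSeries",
    "CineStack",
    "AnnulusDeformation",
    "render_tagged_series",
    "render_cine_stack",
]


class RenderError(RuntimeError):
    """Phantom geometry became invalid during rendering."""


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition geometry/timing emulated by the renderer.

    Defaults follow a 1.5 T tagging/cine protocol: 7 mm tag spacing,
    14.1 ms tagged frame interval, 20 cine phases, 5 mm cine slices with
    a 5 mm gap.
    """

    pixel_spacing_mm: tuple[float, float] = (1.2, 1.2)
    matrix: tuple[int, int] = (160, 160)
    tag_spacing_mm: float = 7.0
    frame_interval_ms: float = 14.1
    cine_phases: int = 20
    slice_thickness_mm: float = 5.0
    slice_gap_mm: float = 5.0
    tag_contrast: float = 0.85
    tag_fade_ms: float = 500.0
    snr: float = 20.0  # additive Gaussian; np.inf disables noise
    myo_intensity: float = 1.0
    blood_intensity: float = 1.35
    background_intensity: float = 0.55


@dataclass(frozen=True)
class TaggedSeries:
    """2D+t tagged short-axis acquisition of one slice."""

    frames: np.ndarray  # (n_frames, ny, nx)
    pixel_spacing_mm: tuple[float, float]
    frame_times_ms: np.ndarray
    tag_spacing_mm: float
    slice_label: str
    anchor_angle: float
    noise_sigma: float
    center_mm: tuple[float, float]  # LV centre in image coordinates
    endo_radius_mm: float
    epi_radius_mm: float  # maximal; for seeding trackers

    def __post_init__(self) -> None:
        if self.frames.shape[0] < 2:
            raise ValueError("a tagged series needs at least 2 frames")
        if self.tag_spacing_mm <= max(self.pixel_spacing_mm):
            raise ValueError("tag spacing must exceed the pixel spacing")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValueError("frame times must be strictly increasing")


@dataclass(frozen=True)
class CineStack:
    """Multi-slice 2D+t cine covering LV and LA, with true contours.

    ``contours[(slice_index, phase, structure)]`` is an (N, 2) array of
    ordered [x, y] points in mm; structures are "lv_endo"/"lv_epi" on LV
    slices and "la_endo" on LA slices.
    """

    frames: np.ndarray | None  # (n_slices, n_phases, ny, nx) or None
    pixel_spacing_mm: tuple[float, float]
    phase_times_ms: np.ndarray
    slice_positions_mm: np.ndarray
    slice_thickness_mm: float
    slice_gap_mm: float
    lv_slices: tuple[int, ...]
    la_slices: tuple[int, ...]
    contours: dict
    anchor_angle: float
    slice_rings: dict  # lv slice index -> "basal"|"mid"|"apical"

    @property
    def n_phases(self) -> int:
        return len(self.phase_times_ms)

    @property
    def slice_extent_mm(self) -> float:
        """Per-slice integration extent (thickness + gap) for Simpson."""
        return self.slice_thickness_mm + self.slice_gap_mm


def _interp_periodic(theta, centers, values):
    """Linear periodic interpolation of per-segment values over angle."""
    order = np.argsort(centers)
    c, v = np.asarray(centers)[order], np.asarray(values)[order]
    cp = np.concatenate([c, [c[0] + 2 * np.pi]])
    vp = np.concatenate([v, [v[0]]])
    rel = np.mod(theta - c[0], 2 * np.pi) + c[0]
    return np.interp(rel, cp, vp)


def _blend_periodic(theta, anchor, values, transition_rad):
    """Per-segment plateau profile with C1 smoothstep transitions of full
    width ``transition_rad`` centred on the sector boundaries.  Away from
    the transitions the profile equals the segment value exactly, so sector
    cores carry the prescribed parameters without interpolation bias."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sw = 2.0 * np.pi / n
    u = np.mod(np.asarray(theta, dtype=float) - anchor, 2.0 * np.pi) / sw
    j = np.floor(u - 0.5).astype(int)  # left segment index (may be -1)
    frac = u - 0.5 - j  # in [0, 1): position between centres j and j+1
    w2 = transition_rad / (2.0 * sw)
    x = np.clip((frac - (0.5 - w2)) / (2.0 * w2), 0.0, 1.0)
    smooth = x * x * (3.0 - 2.0 * x)
    vj = values[np.mod(j, n)]
    vj1 = values[np.mod(j + 1, n)]
    return vj + (vj1 - vj) * smooth


class AnnulusDeformation:
    """Area-preserving radial deformation of one short-axis ring.

    Built from a subject's per-segment strain curves for a slice; provides
    the forward material map, the inverse map used by the renderer, and the
    analytic per-angle circumferential stretch.
    """

    #: full angular width (rad) of the smoothstep transition between
    #: neighbouring segments' strain plateaus / wall thickness
    STRAIN_TRANSITION = np.deg2rad(18.0)
    THICKNESS_TRANSITION = np.deg2rad(12.0)

    def __init__(self, subject: PhantomSubject, slice_label: str,
                 anchor_angle: float = np.pi / 2) -> None:
        self.model = SegmentModel(slice_label, anchor_angle)
        seg_ids = self.model.segment_ids
        self.anchor = anchor_angle
        self.centers = np.array(
            [self.model.segment_center_angle(s) for s in seg_ids]
        )
        idx = [s - 1 for s in seg_ids]
        self.edwt = subject.edwt_mm[idx]
        self.curves = [subject.strain_curve(s) for s in seg_ids]
        ring = {"basal": 0, "mid": 1, "apical": 2}[slice_label]
        self.r_endo0 = float(subject.endo_radius_mm[ring])
        self.slice_label = slice_label
        self.subject = subject

    # reference-geometry helpers ------------------------------------------
    def wall_thickness0(self, theta):
        return _blend_periodic(theta, self.anchor, self.edwt,
                               self.THICKNESS_TRANSITION)

    def r_mid0(self, theta):
        return self.r_endo0 + 0.5 * self.wall_thickness0(theta)

    def r_epi0(self, theta):
        return self.r_endo0 + self.wall_thickness0(theta)

    def stretch(self, theta, t_ms: float):
        """Mid-wall circumferential stretch lambda(theta, t); equals the
        segment's prescribed stretch exactly away from sector boundaries."""
        strains = np.array([c.value(t_ms) for c in self.curves], dtype=float)
        return 1.0 + _blend_periodic(theta, self.anchor, strains,
                                     self.STRAIN_TRANSITION) / 100.0

    def _c(self, theta, t_ms: float):
        lam = self.stretch(theta, t_ms)
        rm = self.r_mid0(theta)
        return rm * rm * (lam * lam - 1.0)

    def material_position(self, R, theta, t_ms: float):
        """Forward map: reference polar (R, theta) -> current radius."""
        r2 = np.asarray(R, dtype=float) ** 2 + self._c(theta, t_ms)
        if np.any(r2 <= 0.0):
            bad = np.argmax(r2 <= 0.0)
            seg = self.model.segment_of_angle(np.atleast_1d(theta).ravel()[bad])
            raise RenderError(
                f"negative wall radius in segment {seg} at t={t_ms:.1f} ms"
            )
        return np.sqrt(r2)

    def reference_radius(self, r, theta, t_ms: float):
        """Inverse map: current polar (r, theta) -> reference radius
        (NaN where no tissue preimage exists)."""
        R2 = np.asarray(r, dtype=float) ** 2 - self._c(theta, t_ms)
        return np.sqrt(np.maximum(R2, 0.0))

    def check_validity(self, t_ms: float, n_theta: int = 360) -> None:
        """Raise RenderError if the deformation collapses the endocardium
        (negative wall radius) anywhere at this phase."""
        th = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        r2 = self.r_endo0**2 + self._c(th, t_ms)
        if np.any(r2 <= 0.0):
            seg = self.model.segment_of_angle(th[int(np.argmin(r2))])
            raise RenderError(
                f"negative wall radius in segment {seg} at t={t_ms:.1f} ms"
            )


def _tag_pattern(x_mm, y_mm, spacing: float, contrast: float):
    """Two orthogonal sinusoidal dark-line families (SPAMM grid)."""
    gx = 0.5 * (1.0 + np.cos(2.0 * np.pi * x_mm / spacing))
    gy = 0.5 * (1.0 + np.cos(2.0 * np.pi * y_mm / spacing))
    return (1.0 - contrast * gx) * (1.0 - contrast * gy)


def render_tagged_series(
    subject: PhantomSubject,
    slice_label: str = "basal",
    imaging: ImagingParams | None = None,
    seed: int = 0,
    anchor_angle: float = np.pi / 2,
    translation_mm: tuple[float, float] = (0.0, 0.0),
    rotation_rad: float = 0.0,
) -> tuple[TaggedSeries, GroundTruth]:
    """Render one tagged short-axis series with exact analytic ground truth.

    ``translation_mm``/``rotation_rad`` apply a solid-body motion that grows
    linearly from zero at the reference frame to the given value at
    end-cycle (rigid-motion test phantoms).
    """
    if slice_label not in SLICES:
        raise ValueError(f"unknown slice {slice_label!r}")
    imaging = imaging or ImagingParams()
    deform = AnnulusDeformation(subject, slice_label, anchor_angle)

    ny, nx = imaging.matrix
    dy, dx = imaging.pixel_spacing_mm
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    xs = (np.arange(nx) + 0.5) * dx - cx
    ys = (np.arange(ny) + 0.5) * dy - cy
    X, Y = np.meshgrid(xs, ys)

    n_frames = int(np.floor(subject.cycle_ms / imaging.frame_interval_ms)) + 1
    times = np.arange(n_frames) * imaging.frame_interval_ms
    rng = np.random.default_rng(seed)
    noise_sigma = (
        imaging.myo_intensity / imaging.snr if np.isfinite(imaging.snr) else 0.0
    )

    def _sigmoid(z, w=1.5):
        return 1.0 / (1.0 + np.exp(-z / w))

    frames = np.empty((n_frames, ny, nx), dtype=np.float32)
    for k, t in enumerate(times):
        frac = t / subject.cycle_ms
        tx, ty = frac * translation_mm[0], frac * translation_mm[1]
        phi = frac * rotation_rad
        # undo the rigid motion, then the annulus deformation
        Xr = np.cos(-phi) * (X - tx) - np.sin(-phi) * (Y - ty)
        Yr = np.sin(-phi) * (X - tx) + np.cos(-phi) * (Y - ty)
        r = np.hypot(Xr, Yr)
        theta = np.arctan2(Yr, Xr)
        deform.check_validity(t)
        R = deform.reference_radius(r, theta, t)
        # feathered compartment intensities (blood pool / wall / background);
        # the saturation grid is imprinted across the whole excited slab and
        # advected with the extended deformation field
        w_en = _sigmoid(R - deform.r_endo0)
        w_ep = _sigmoid(R - deform.r_epi0(theta))
        base = (
            imaging.blood_intensity * (1.0 - w_en)
            + imaging.myo_intensity * w_en * (1.0 - w_ep)
            + imaging.background_intensity * w_ep
        )
        fade = np.exp(-t / imaging.tag_fade_ms)
        tag = _tag_pattern(
            R * np.cos(theta), R * np.sin(theta),
            imaging.tag_spacing_mm, imaging.tag_contrast * fade,
        )
        img = base * tag
        if noise_sigma > 0.0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        frames[k] = img

    series = TaggedSeries(
        frames=frames,
        pixel_spacing_mm=(dy, dx),
        frame_times_ms=times,
        tag_spacing_mm=imaging.tag_spacing_mm,
        slice_label=slice_label,
        anchor_angle=anchor_angle,
        noise_sigma=noise_sigma,
        center_mm=(cx, cy),
        endo_radius_mm=deform.r_endo0,
        epi_radius_mm=float(deform.r_epi0(deform.centers).max()),
    )
    return series, ground_truth(subject)


def reference_contours(series: TaggedSeries, subject: PhantomSubject,
                       n_points: int = 180) -> dict:
    """True end-diastolic endo/epicardial contours of a tagged slice, in the
    series' image coordinates (mm) — the delineation a reader would supply."""
    deform = AnnulusDeformation(subject, series.slice_label, series.anchor_angle)
    th = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    cx, cy = series.center_mm
    endo = np.column_stack([cx + deform.r_endo0 * np.cos(th),
                            cy + deform.r_endo0 * np.sin(th)])
    repi = deform.r_epi0(th)
    epi = np.column_stack([cx + repi * np.cos(th), cy + repi * np.sin(th)])
    return {"endo": endo, "epi": epi}


# ---------------------------------------------------------------------------
# cine


def _lv_slice_profile(n_slices: int) -> np.ndarray:
    """Relative endocardial radius taper from base (1.0) toward apex."""
    z = (np.arange(n_slices) + 0.5) / n_slices
    return np.sqrt(np.clip(1.0 - z * z, 0.04, None))


def _circle(radius: float, n: int = 120, center=(0.0, 0.0)) -> np.ndarray:
    a = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(a),
                            center[1] + radius * np.sin(a)])


def render_cine_stack(
    subject: PhantomSubject,
    imaging: ImagingParams | None = None,
    seed: int = 0,
    n_lv_slices: int = 9,
    n_la_slices: int = 5,
    render_pixels: bool = False,
    anchor_angle: float = np.pi / 2,
) -> CineStack:
    """Build the cine stack: true LV endo/epi and LA contours per phase,
    with slice areas scaled so slice summation reproduces the subject's
    volume curves exactly; pixel frames are rendered on request."""
    imaging = imaging or ImagingParams()
    dz = imaging.slice_thickness_mm + imaging.slice_gap_mm
    n_phases = imaging.cine_phases
    times = np.arange(n_phases) * subject.cycle_ms / n_phases

    edv_abs = subject.lvedv_ml_m2 * subject.bsa_m2
    esv_abs = subject.lvesv_ml_m2 * subject.bsa_m2
    lv_curve = lv_volume_curve(edv_abs, esv_abs, subject.timing,
                               subject.atrial_kick_fraction)
    la_curve = la_volume_curve(
        subject.la_min_ml_m2 * subject.bsa_m2,
        subject.la_max_ml_m2 * subject.bsa_m2,
        subject.la_passive_ml_m2 * subject.bsa_m2,
        subject.la_active_ml_m2 * subject.bsa_m2,
        subject.timing,
    )

    # LV slice radii: taper profile scaled so Simpson over (thickness+gap)
    # gives exactly EDV at t=0
    prof = _lv_slice_profile(n_lv_slices)
    scale = np.sqrt(edv_abs * 1000.0 / (np.pi * np.sum(prof**2) * dz))
    lv_r0 = prof * scale
    # LA: spherical cross-sections, same normalization
    zl = np.linspace(-0.8, 0.8, n_la_slices)
    la_prof = np.sqrt(1.0 - zl * zl)
    la_scale = np.sqrt(
        la_curve.value(0.0) * 1000.0 / (np.pi * np.sum(la_prof**2) * dz)
    )
    la_r0 = la_prof * la_scale

    # ring membership of LV slices (basal/mid/apical thirds)
    rings = {}
    for i in range(n_lv_slices):
        frac = (i + 0.5) / n_lv_slices
        rings[i] = "basal" if frac < 1 / 3 else ("mid" if frac < 2 / 3 else "apical")

    # wall thickness: angular interpolation of segment EDWT and thickening
    models = {lbl: SegmentModel(lbl, anchor_angle) for lbl in SLICES}
    thetas = np.linspace(0.0, 2.0 * np.pi, 120, endpoint=False)
    v0, ves = lv_curve.value(0.0), lv_curve.value(subject.timing.aortic_closure_ms)

    contours: dict = {}
    slice_positions = np.arange(n_lv_slices + n_la_slices) * dz
    lv_idx = tuple(range(n_lv_slices))
    la_idx = tuple(range(n_lv_slices, n_lv_slices + n_la_slices))

    for p, t in enumerate(times):
        vfrac = np.sqrt(lv_curve.value(t) / v0)
        contraction = float(np.clip((v0 - lv_curve.value(t)) / (v0 - ves), 0.0, 1.0))
        for i in lv_idx:
            model = models[rings[i]]
            seg = [s - 1 for s in model.segment_ids]
            centers = np.array([model.segment_center_angle(s)
                                for s in model.segment_ids])
            edwt = _blend_periodic(thetas, anchor_angle, subject.edwt_mm[seg],
                                   AnnulusDeformation.THICKNESS_TRANSITION)
            wt = _blend_periodic(thetas, anchor_angle, subject.wall_thickening[seg],
                                 AnnulusDeformation.THICKNESS_TRANSITION)
            r_endo = lv_r0[i] * vfrac
            h = edwt * (1.0 + wt * contraction)
            endo = np.column_stack([r_endo * np.cos(thetas),
                                    r_endo * np.sin(thetas)])
            epi = np.column_stack([(r_endo + h) * np.cos(thetas),
                                   (r_endo + h) * np.sin(thetas)])
            contours[(i, p, "lv_endo")] = endo
            contours[(i, p, "lv_epi")] = epi
        la_frac = np.sqrt(la_curve.value(t) / la_curve.value(0.0))
        for j, i in enumerate(la_idx):
            contours[(i, p, "la_endo")] = _circle(la_r0[j] * la_frac)

    frames = None
    if render_pixels:
        ny, nx = imaging.matrix
        dyy, dxx = imaging.pixel_spacing_mm
        cx, cy = nx * dxx / 2.0, ny * dyy / 2.0
        xs = (np.arange(nx) + 0.5) * dxx - cx
        ys = (np.arange(ny) + 0.5) * dyy - cy
        X, Y = np.meshgrid(xs, ys)
        r = np.hypot(X, Y)
        th = np.arctan2(Y, X)
        rng = np.random.default_rng(seed)
        sigma = imaging.myo_intensity / imaging.snr if np.isfinite(imaging.snr) else 0.0
        n_slices = n_lv_slices + n_la_slices
        frames = np.empty((n_slices, n_phases, ny, nx), dtype=np.float32)
        for p, t in enumerate(times):
            for i in range(n_slices):
                img = np.full((ny, nx), imaging.background_intensity)
                if i in lv_idx:
                    endo = contours[(i, p, "lv_endo")]
                    epi = contours[(i, p, "lv_epi")]
                    re_ = np.interp(np.mod(th, 2 * np.pi),
                                    np.linspace(0, 2 * np.pi, len(endo), endpoint=False),
                                    np.hypot(endo[:, 0], endo[:, 1]), period=2 * np.pi)
                    rp_ = np.interp(np.mod(th, 2 * np.pi),
                                    np.linspace(0, 2 * np.pi, len(epi), endpoint=False),
                                    np.hypot(epi[:, 0], epi[:, 1]), period=2 * np.pi)
                    img[r < re_] = imaging.blood_intensity
                    img[(r >= re_) & (r <= rp_)] = imaging.myo_intensity
                else:
                    la = contours[(i, p, "la_endo")]
                    img[r < np.hypot(la[0, 0], la[0, 1])] = imaging.blood_intensity
                if sigma > 0.0:
                    img = img + rng.normal(0.0, sigma, img.shape)
                frames[i, p] = img

    return CineStack(
        frames=frames,
        pixel_spacing_mm=imaging.pixel_spacing_mm,
        phase_times_ms=times,
        slice_positions_mm=slice_positions,
        slice_thickness_mm=imaging.slice_thickness_mm,
        slice_gap_mm=imaging.slice_gap_mm,
        lv_slices=lv_idx,
        la_slices=la_idx,
        contours=contours,
        anchor_angle=anchor_angle,
        slice_rings=rings,
    )
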