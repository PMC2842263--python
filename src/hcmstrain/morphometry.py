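"""Cine-derived morphometry: wall thickness, SL ratio, LV/LA volumetrics, IVRT.

All measures are computed from contour sets (ordered [x, y] point lists in
mm), never from pixels: wall thickness from radial epi-endo chords, cavity
volumes by slice summation (Simpson) over the slice thickness + gap extent,
LV mass from the myocardial shell volume times 1.05 g/mL, and the left
atrial volume curve decomposed into reservoir, passive (conduit) and active
(booster) emptying volumes via its diastasis plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segments import (
    LATERAL_SEGMENTS,
    SEPTAL_SEGMENTS,
    SegmentModel,
    slice_of_segment,
)
from .timecourse import CardiacTiming

__all__ = [
    "MorphometryRecord",
    "SegmentThickness",
    "LAResult",
    "segment_thickness",
    "wall_thickening",
    "sl_ratio",
    "ed_wall_radius",
    "lv_volumes",
    "la_analysis",
    "ivrt",
    "morphometry_from_cine",
]

MYOCARDIUM_DENSITY_G_ML = 1.05


class ContourError(ValueError):
    """Invalid or unusable contour input."""


# ---------------------------------------------------------------------------
# contour primitives


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return pts.mean(axis=0)
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6.0 * a)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _resample_arclength(pts: np.ndarray, n: int = 720) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ContourError("degenerate contour with zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def _ray_polygon_distance(center: np.ndarray, angles: np.ndarray,
                          pts: np.ndarray) -> np.ndarray:
    """First positive intersection distance of rays from ``center`` with a
    closed polygon; NaN where a ray misses."""
    p1 = pts
    p2 = np.roll(pts, -1, axis=0)
    d1 = p1 - center  # (M, 2)
    e = p2 - p1
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])  # (K, 2)
    # solve center + t*dir = p1 + s*e  for each (ray, edge)
    det = dirs[:, None, 0] * (-e[None, :, 1]) - dirs[:, None, 1] * (-e[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (d1[None, :, 0] * (-e[None, :, 1]) - d1[None, :, 1] * (-e[None, :, 0])) / det
        s = (dirs[:, None, 0] * d1[None, :, 1] - dirs[:, None, 1] * d1[None, :, 0]) / det
    hit = (np.abs(det) > 1e-12) & (s >= 0.0) & (s < 1.0) & (t > 0.0)
    t = np.where(hit, t, np.inf)
    tmin = t.min(axis=1)
    return np.where(np.isfinite(tmin), tmin, np.nan)


# ---------------------------------------------------------------------------
# operations


@dataclass(frozen=True)
class SegmentThickness:
    """Per-segment wall thickness of one short-axis slice."""

    segment_ids: tuple[int, ...]
    mean_mm: np.ndarray
    max_chord_mm: np.ndarray
    analyzable: np.ndarray  # bool per segment (<= 20 % failed chords)


def segment_thickness(
    epi_contour: np.ndarray,
    endo_contour: np.ndarray,
    model: SegmentModel,
    n_chords: int = 100,
    sector_margin: float = 0.15,
) -> SegmentThickness:
    """Mean (and maximal) epi-endo chord length per segment.

    Radial chords are cast from the cavity centroid; chords failing to
    intersect both contours are excluded, and a segment with more than 20 %
    failed chords is flagged unanalyzable.  ``sector_margin`` drops chords
    within that fraction of the sector width of an inter-segment boundary.
    """
    epi = np.asarray(epi_contour, dtype=float)
    endo = np.asarray(endo_contour, dtype=float)
    if len(epi) < 3 or len(endo) < 3:
        raise ContourError("contours need at least 3 points")
    center = _polygon_centroid(endo)
    angles = np.linspace(0.0, 2.0 * np.pi, n_chords, endpoint=False)
    r_en = _ray_polygon_distance(center, angles, endo)
    r_ep = _ray_polygon_distance(center, angles, epi)
    thick = r_ep - r_en
    ok = np.isfinite(thick) & (thick > 0.0)
    seg_of = model.segment_of_angle(angles)
    # keep chords away from the inter-segment boundary zone so the segment
    # statistics are not diluted by the neighbouring segment's wall
    rel = np.mod(angles - model.anchor_angle, 2.0 * np.pi) / model.sector_width
    frac = rel - np.floor(rel)
    core = (frac >= sector_margin) & (frac <= 1.0 - sector_margin)

    ids = model.segment_ids
    mean = np.full(len(ids), np.nan)
    mx = np.full(len(ids), np.nan)
    good = np.zeros(len(ids), dtype=bool)
    for j, s in enumerate(ids):
        m = (seg_of == s) & core
        n_tot = int(m.sum())
        n_ok = int((m & ok).sum())
        if n_tot == 0 or n_ok < 0.8 * n_tot:
            continue
        mean[j] = thick[m & ok].mean()
        mx[j] = thick[m & ok].max()
        good[j] = True
    return SegmentThickness(ids, mean, mx, good)


def wall_thickening(edwt_mm, eswt_mm):
    """(ESWT - EDWT) / EDWT, dimensionless (vectorized)."""
    edwt = np.asarray(edwt_mm, dtype=float)
    if np.any(edwt <= 0):
        raise ValueError("end-diastolic wall thickness must be positive")
    return (np.asarray(eswt_mm, dtype=float) - edwt) / edwt


def sl_ratio(edwt_by_segment: dict[int, float]) -> float:
    """Maximal septal over maximal lateral ED wall thickness.

    ``edwt_by_segment`` maps AHA segment id to that segment's maximal-chord
    EDWT (mm), typically pooled over all analyzed slices; missing segments
    may be absent from the mapping.
    """
    septal = [v for s, v in edwt_by_segment.items()
              if s in SEPTAL_SEGMENTS and np.isfinite(v)]
    lateral = [v for s, v in edwt_by_segment.items()
               if s in LATERAL_SEGMENTS and np.isfinite(v)]
    if not septal or not lateral:
        raise ValueError("need at least one septal and one lateral segment")
    return float(max(septal) / max(lateral))


def ed_wall_radius(endo_contour: np.ndarray, n: int = 720) -> float:
    """Mean distance from the cavity centroid to the (densely resampled)
    endocardial border, mm."""
    endo = _resample_arclength(np.asarray(endo_contour, dtype=float), n)
    center = _polygon_centroid(endo)
    return float(np.linalg.norm(endo - center, axis=1).mean())


@dataclass(frozen=True)
class LVVolumes:
    lvedv_ml: float
    lvesv_ml: float
    sv_ml: float
    lvef_pct: float
    lv_mass_g: float
    volume_curve_ml: np.ndarray  # per phase
    ed_phase: int
    es_phase: int


def lv_volumes(
    endo_by_slice_phase: dict,
    epi_by_slice_phase: dict,
    slice_extent_mm: float,
    n_phases: int,
    lv_slices,
    bsa_m2: float | None = None,
) -> LVVolumes:
    """Slice-summation LV volumes, EF and mass.

    ``endo_by_slice_phase[(slice, phase)]`` are contours; mass uses the
    end-diastolic myocardial shell times 1.05 g/mL (papillary muscles are
    part of the shell in this phantom's contours).  If ``bsa_m2`` is given,
    volumes and mass are indexed to body surface area.
    """
    lv_slices = list(lv_slices)
    missing = [
        (i, p) for p in range(n_phases) for i in lv_slices
        if (i, p) not in endo_by_slice_phase
    ]
    if missing:
        raise ContourError(f"missing LV endocardial contours for {missing[:5]}...")
    vol = np.empty(n_phases)
    for p in range(n_phases):
        areas = [_polygon_area(np.asarray(endo_by_slice_phase[(i, p)]))
                 for i in lv_slices]
        vol[p] = np.sum(areas) * slice_extent_mm / 1000.0  # mm^3 -> mL
    ed = int(np.argmax(vol))
    es = int(np.argmin(vol))
    myo = 0.0
    for i in lv_slices:
        a_ep = _polygon_area(np.asarray(epi_by_slice_phase[(i, ed)]))
        a_en = _polygon_area(np.asarray(endo_by_slice_phase[(i, ed)]))
        myo += (a_ep - a_en) * slice_extent_mm / 1000.0
    mass = myo * MYOCARDIUM_DENSITY_G_ML
    norm = bsa_m2 if bsa_m2 else 1.0
    edv, esv = vol[ed] / norm, vol[es] / norm
    return LVVolumes(
        lvedv_ml=edv,
        lvesv_ml=esv,
        sv_ml=edv - esv,
        lvef_pct=100.0 * (edv - esv) / edv,
        lv_mass_g=mass / norm,
        volume_curve_ml=vol / norm,
        ed_phase=ed,
        es_phase=es,
    )


@dataclass(frozen=True)
class LAResult:
    la_min_ml: float
    la_max_ml: float
    la_diastasis_ml: float
    la_preA_ml: float
    la_reservoir_ml: float
    la_passive_ml: float
    la_active_ml: float
    laef_pct: float
    diastasis_defined: bool


def la_analysis(times_ms: np.ndarray, volume_ml: np.ndarray,
                timing: CardiacTiming | None = None) -> LAResult:
    """Decompose an LA volume curve into its functional volumes.

    Diastasis is the volume at the slope minimum between the passive
    (conduit) emptying rate peak and the active (booster) emptying rate
    peak; the pre-A volume is taken at the onset of atrial contraction
    (last quiescent sample before the active rate peak).  Curves without a
    detectable plateau (e.g. high heart rate) flag the diastasis undefined
    and fall back to the pre-A volume.  LAEF = active emptying / pre-A
    volume.
    """
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(volume_ml, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 samples of the LA volume curve")
    v_max, v_min = float(v.max()), float(v.min())
    if v_max - v_min < 1e-9:  # constant curve: all derived volumes zero
        return LAResult(v_min, v_max, v_max, v_max, 0.0, 0.0, 0.0, 0.0, False)
    i_max = int(np.argmax(v))
    dv = np.gradient(v, t)
    span = t[-1] - t[0]
    # the active (booster) emptying rate peak lives in the final ~30 % of
    # the cycle, the passive (conduit) peak between the volume maximum and
    # that window
    tail_start = t[-1] - 0.30 * span
    tail = np.where((t >= tail_start) & (np.arange(len(t)) > i_max))[0]
    mid = np.where((t < tail_start) & (np.arange(len(t)) > i_max))[0]
    if len(tail) == 0 or len(mid) == 0:
        i_act = i_max + int(np.argmin(dv[i_max:]))
        i_pass = i_act
    else:
        i_act = int(tail[np.argmin(dv[tail])])
        i_pass = int(mid[np.argmin(dv[mid])])
    defined = i_act - i_pass >= 3
    if defined:
        # diastasis: onset of quiescence after the passive-emptying peak;
        # pre-A: last quiescent sample before the active-emptying peak
        win = np.arange(i_pass + 1, i_act)
        quiet = np.abs(dv[win]) <= max(1e-9, 0.20 * abs(dv[i_pass]),
                                       0.20 * abs(dv[i_act]))
        defined = quiet.any()
    if defined:
        i_dia = int(win[quiet][0])
        i_pre = int(win[quiet][-1])
        v_dia, v_pre = float(v[i_dia]), float(v[i_pre])
    else:
        v_dia = v_pre = float(v[i_act])  # no plateau: merge landmarks
    active = v_pre - v_min
    return LAResult(
        la_min_ml=v_min,
        la_max_ml=v_max,
        la_diastasis_ml=v_dia,
        la_preA_ml=v_pre,
        la_reservoir_ml=v_max - v_min,
        la_passive_ml=v_max - v_dia,
        la_active_ml=active,
        laef_pct=100.0 * active / v_pre if v_pre > 0 else np.nan,
        diastasis_defined=bool(defined),
    )


def ivrt(aortic_closure_ms: float, mitral_opening_ms: float) -> float:
    """Isovolumetric relaxation time (ms)."""
    if mitral_opening_ms < aortic_closure_ms:
        raise ValueError("mitral opening precedes aortic closure")
    return float(mitral_opening_ms - aortic_closure_ms)


# ---------------------------------------------------------------------------
# per-subject assembly


@dataclass
class MorphometryRecord:
    """All cine-derived measures of one subject (volumes indexed to BSA)."""

    subject_id: str
    segment_ids: tuple[int, ...]
    edwt_mm: np.ndarray  # (16,)
    eswt_mm: np.ndarray
    thickening: np.ndarray
    edwt_max_chord_mm: np.ndarray
    ed_wall_radius_mm: dict  # slice label -> mm
    sl_ratio: float
    lvedv_ml_m2: float
    lvesv_ml_m2: float
    sv_ml_m2: float
    lvef_pct: float
    lv_mass_g_m2: float
    mass_volume_ratio: float
    la_min_ml_m2: float
    la_max_ml_m2: float
    la_diastasis_ml_m2: float
    la_preA_ml_m2: float
    la_reservoir_ml_m2: float
    la_passive_ml_m2: float
    la_active_ml_m2: float
    laef_pct: float
    ivrt_ms: float
    bsa_m2: float
    diastasis_defined: bool = True

    def validate(self) -> None:
        if not self.lvesv_ml_m2 < self.lvedv_ml_m2:
            raise ValueError("LVESV must be below LVEDV")
        assert abs(self.sv_ml_m2 - (self.lvedv_ml_m2 - self.lvesv_ml_m2)) < 1e-9
        assert abs(
            self.la_reservoir_ml_m2 - (self.la_max_ml_m2 - self.la_min_ml_m2)
        ) < 1e-9
        assert abs(
            self.la_passive_ml_m2 - (self.la_max_ml_m2 - self.la_diastasis_ml_m2)
        ) < 1e-9
        assert abs(
            self.la_active_ml_m2 - (self.la_preA_ml_m2 - self.la_min_ml_m2)
        ) < 1e-9


def morphometry_from_cine(stack, subject_id: str, bsa_m2: float,
                          timing: CardiacTiming) -> MorphometryRecord:
    """Full morphometry of one subject from a rendered cine stack.

    Segmental thickness uses, per ring (basal/mid/apical), the LV slice
    closest to the middle of that ring (the slice best matching the tagging
    planes at 25/50/75 % of the base-apex distance).
    """
    n_phases = stack.n_phases
    endo = {k[:2]: v for k, v in stack.contours.items() if k[2] == "lv_endo"}
    epi = {k[:2]: v for k, v in stack.contours.items() if k[2] == "lv_epi"}
    vols = lv_volumes(endo, epi, stack.slice_extent_mm, n_phases,
                      stack.lv_slices, bsa_m2)

    # representative slice per ring
    ring_slices: dict[str, int] = {}
    for ring in ("basal", "mid", "apical"):
        members = [i for i in stack.lv_slices if stack.slice_rings[i] == ring]
        ring_slices[ring] = members[len(members) // 2]

    edwt = np.full(16, np.nan)
    eswt = np.full(16, np.nan)
    edwt_max = np.full(16, np.nan)
    radius = {}
    for ring, i in ring_slices.items():
        model = SegmentModel(ring, stack.anchor_angle)
        th_ed = segment_thickness(epi[(i, vols.ed_phase)], endo[(i, vols.ed_phase)],
                                  model)
        th_es = segment_thickness(epi[(i, vols.es_phase)], endo[(i, vols.es_phase)],
                                  model)
        for j, s in enumerate(model.segment_ids):
            if th_ed.analyzable[j]:
                edwt[s - 1] = th_ed.mean_mm[j]
                edwt_max[s - 1] = th_ed.max_chord_mm[j]
            if th_es.analyzable[j]:
                eswt[s - 1] = th_es.mean_mm[j]
        radius[ring] = ed_wall_radius(endo[(i, vols.ed_phase)])

    la_curves = {k[:2]: v for k, v in stack.contours.items() if k[2] == "la_endo"}
    la_vol = np.zeros(n_phases)
    for p in range(n_phases):
        areas = [_polygon_area(np.asarray(la_curves[(i, p)]))
                 for i in stack.la_slices]
        la_vol[p] = np.sum(areas) * stack.slice_extent_mm / 1000.0
    la = la_analysis(stack.phase_times_ms, la_vol / bsa_m2, timing)

    ratio = sl_ratio({s: edwt_max[s - 1] for s in range(1, 17)})
    return MorphometryRecord(
        subject_id=subject_id,
        segment_ids=tuple(range(1, 17)),
        edwt_mm=edwt,
        eswt_mm=eswt,
        thickening=wall_thickening(edwt, eswt),
        edwt_max_chord_mm=edwt_max,
        ed_wall_radius_mm=radius,
        sl_ratio=ratio,
        lvedv_ml_m2=vols.lvedv_ml,
        lvesv_ml_m2=vols.lvesv_ml,
        sv_ml_m2=vols.sv_ml,
        lvef_pct=vols.lvef_pct,
        lv_mass_g_m2=vols.lv_mass_g,
        mass_volume_ratio=vols.lv_mass_g / vols.lvedv_ml,
        la_min_ml_m2=la.la_min_ml,
        la_max_ml_m2=la.la_max_ml,
        la_diastasis_ml_m2=la.la_diastasis_ml,
        la_preA_ml_m2=la.la_preA_ml,
        la_reservoir_ml_m2=la.la_reservoir_ml,
        la_passive_ml_m2=la.la_passive_ml,
        la_active_ml_m2=la.la_active_ml,
        laef_pct=la.laef_pct,
        ivrt_ms=timing.ivrt_ms,
        bsa_m2=bsa_m2,
        diastasis_defined=la.diastasis_defined,
    )
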