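"""Synthetic subject cohorts for HCM mutation-carrier vs control studies.

A :class:`GroupSpec` holds per-parameter population distributions for one
study group; the shipped presets (:func:`carrier_group`, :func:`control_group`)
are calibrated so that large-sample means reproduce the printed subject-level
and segmental statistics of the carrier-screening study this package models:
septal-dominant end-diastolic wall-thickness (EDWT) asymmetry with a maximal
septal-to-lateral (SL) ratio of 1.3 in carriers vs 1.1 in controls, reduced
basal peak diastolic circumferential strain rate (DCSR, 98 vs 115 %/s),
depressed basal inferoseptal wall thickening (0.39 vs 0.65), and the left
atrial / left ventricular volumetric profile of the two groups.

Segmental parameters are drawn with a low-rank factor structure: one global
subject factor (overall wall thickness / deformation level), one septal-only
factor (coherent septal remodelling), and independent segment noise.  EDWT is
lognormal (positive, mildly right-skewed; means and SDs are matched exactly);
strain, strain-rate and thickening parameters are Gaussian.  A configurable
negative cross-loading couples wall thickness to peak DCSR (thicker walls
relengthen more slowly).

Only those segment means that the calibration pins are quoted to the printed
precision; the remaining segment means, SDs and factor loadings were chosen
once so the emergent nonlinear statistics (the SL ratio is a ratio of maxima)
land on their calibration values, and are not meant to be re-tuned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .segments import LATERAL_SEGMENTS, SEPTAL_SEGMENTS
from .timecourse import (
    CardiacTiming,
    StrainTimecourse,
    build_strain_timecourse,
    min_feasible_dcsr,
)

__all__ = [
    "ScalarSpec",
    "SegmentFamilySpec",
    "GroupSpec",
    "PhantomSubject",
    "GroundTruth",
    "carrier_group",
    "control_group",
    "sample_cohort",
    "ground_truth",
    "truth_table",
]

_SEPTAL_MASK = np.isin(np.arange(1, 17), SEPTAL_SEGMENTS)
_LATERAL_MASK = np.isin(np.arange(1, 17), LATERAL_SEGMENTS)
_BASAL = slice(0, 6)  # segments 1-6


class ConfigurationError(ValueError):
    """Invalid group-specification parameters."""


@dataclass(frozen=True)
class ScalarSpec:
    """Truncated-normal spec for one subject-level parameter."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"{name}: negative SD {self.sd}")
        if not self.lower <= self.mean <= self.upper:
            raise ConfigurationError(f"{name}: mean outside truncation bounds")


@dataclass(frozen=True)
class SegmentFamilySpec:
    """Distribution of one segmental parameter over the 16 AHA segments.

    For normal families, ``global_load``/``septal_load`` are loadings of the
    shared subject / septal factors on the standardized (per-segment SD)
    scale, with idiosyncratic noise making the total variance unit.

    For lognormal families the loads are absolute log-scale SDs of a
    *common* multiplicative subject factor (and a septal-only factor): a
    truly common factor cancels exactly in thickness ratios, which is what
    keeps the SL-ratio spread realistic.  Per-segment residual log-SDs are
    chosen so each segment's total SD matches ``sds`` (clipped at zero when
    a segment's own SD is smaller than the shared factors); segment means
    are preserved exactly in all cases.
    """

    means: np.ndarray
    sds: np.ndarray
    global_load: float = 0.5
    septal_load: float = 0.0
    distribution: str = "normal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))

    def validate(self, name: str) -> None:
        if self.means.shape != (16,) or self.sds.shape != (16,):
            raise ConfigurationError(f"{name}: need 16 segment means and SDs")
        if np.any(self.sds < 0):
            raise ConfigurationError(f"{name}: negative segment SD")
        if self.global_load < 0 or self.septal_load < 0:
            raise ConfigurationError(f"{name}: negative factor loading")
        if (self.distribution == "normal"
                and self.global_load**2 + self.septal_load**2 > 1.0):
            raise ConfigurationError(f"{name}: factor loadings exceed unit variance")
        if self.distribution not in ("normal", "lognormal"):
            raise ConfigurationError(f"{name}: unknown distribution")
        if self.distribution == "lognormal" and np.any(self.means <= 0):
            raise ConfigurationError(f"{name}: lognormal needs positive means")

    def draw(self, z_global: np.ndarray, z_septal: np.ndarray, rng) -> np.ndarray:
        """Draw (n, 16) values given subject factor vectors of shape (n,)."""
        n = z_global.shape[0]
        g, s = self.global_load, self.septal_load
        if self.distribution == "lognormal":
            cv = np.where(self.means > 0, self.sds / self.means, 0.0)
            s_ln2 = np.log1p(cv * cv)
            fac2 = g * g + s * s * _SEPTAL_MASK
            # the shared factors cannot exceed a segment's own variance:
            # scale them down where needed so total log-variance == s_ln2
            # (and an all-zero-SD spec is exactly degenerate)
            with np.errstate(divide="ignore", invalid="ignore"):
                lam = np.sqrt(np.minimum(1.0, np.where(fac2 > 0, s_ln2 / fac2, 1.0)))
            res = np.sqrt(np.maximum(s_ln2 - lam * lam * fac2, 0.0))
            w = lam * (
                g * z_global[:, None]
                + s * z_septal[:, None] * _SEPTAL_MASK
            ) + res * rng.standard_normal((n, 16))
            return self.means * np.exp(w - 0.5 * s_ln2)
        k = np.sqrt(np.maximum(1.0 - g * g - s * s * _SEPTAL_MASK, 0.0))
        w = (
            g * z_global[:, None]
            + s * z_septal[:, None] * _SEPTAL_MASK
            + k * rng.standard_normal((n, 16))
        )
        return self.means + self.sds * w


@dataclass(frozen=True)
class GroupSpec:
    """Population distributions of one study group (see module docstring)."""

    group_label: str
    # subject-level scalars
    age_years: ScalarSpec
    male_fraction: float
    heart_rate_bpm: ScalarSpec
    systolic_bp_mmhg: ScalarSpec
    diastolic_bp_mmhg: ScalarSpec
    bmi_kg_m2: ScalarSpec
    ivrt_ms: ScalarSpec
    # LA volumes, indexed to BSA (mL/m^2)
    la_min_ml_m2: ScalarSpec
    la_max_ml_m2: ScalarSpec
    la_passive_ml_m2: ScalarSpec
    la_active_ml_m2: ScalarSpec
    # LV volumes/mass, indexed to BSA
    lvedv_ml_m2: ScalarSpec
    lvesv_ml_m2: ScalarSpec
    lv_mass_g_m2: ScalarSpec
    # segmental families
    edwt_mm: SegmentFamilySpec
    peak_scs_pct: SegmentFamilySpec
    peak_dcsr_pct_s: SegmentFamilySpec
    wall_thickening: SegmentFamilySpec
    # correlation controls
    edv_esv_corr: float = 0.8
    la_min_max_corr: float = 0.7
    edwt_dcsr_corr: float = -0.3
    # motion-model extras
    atrial_kick_fraction: ScalarSpec = field(
        default_factory=lambda: ScalarSpec(0.25, 0.04, 0.05, 0.45)
    )
    time_to_peak_fraction: float = 0.85  # of the aortic-closure time
    segment_dropout_prob: float = 0.0

    def validate(self) -> None:
        for name in (
            "age_years", "heart_rate_bpm", "systolic_bp_mmhg", "diastolic_bp_mmhg",
            "bmi_kg_m2", "ivrt_ms", "la_min_ml_m2", "la_max_ml_m2",
            "la_passive_ml_m2", "la_active_ml_m2", "lvedv_ml_m2", "lvesv_ml_m2",
            "lv_mass_g_m2", "atrial_kick_fraction",
        ):
            getattr(self, name).validate(name)
        for name in ("edwt_mm", "peak_scs_pct", "peak_dcsr_pct_s", "wall_thickening"):
            getattr(self, name).validate(name)
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction outside [0, 1]")
        if not 0.0 <= self.segment_dropout_prob < 1.0:
            raise ConfigurationError("segment_dropout_prob outside [0, 1)")
        for c in (self.edv_esv_corr, self.la_min_max_corr, self.edwt_dcsr_corr):
            if not -1.0 < c < 1.0:
                raise ConfigurationError("correlation controls must be in (-1, 1)")
        if np.any(self.peak_scs_pct.means > 0):
            raise ConfigurationError("peak SCS means must be <= 0 (shortening)")
        if np.any(self.peak_dcsr_pct_s.means <= 0):
            raise ConfigurationError("peak DCSR means must be > 0")
        if not (self.la_min_ml_m2.mean < self.la_max_ml_m2.mean):
            raise ConfigurationError("LA min mean must be below LA max mean")
        if not (self.lvesv_ml_m2.mean < self.lvedv_ml_m2.mean):
            raise ConfigurationError("LVESV mean must be below LVEDV mean")


@dataclass(frozen=True)
class PhantomSubject:
    """One synthetic subject: geometry + motion-model parameters.

    Segmental arrays are ordered by AHA segment id 1..16.  All strain
    quantities use the shortening-negative convention; DCSR is positive.
    """

    subject_id: str
    group_label: str
    age_years: float
    male: bool
    height_cm: float
    weight_kg: float
    bsa_m2: float
    heart_rate_bpm: float
    systolic_bp_mmhg: float
    diastolic_bp_mmhg: float
    timing: CardiacTiming  # cycle + valve event times
    time_to_peak_ms: float
    atrial_kick_fraction: float
    edwt_mm: np.ndarray  # (16,)
    peak_scs_pct: np.ndarray  # (16,)
    peak_dcsr_pct_s: np.ndarray  # (16,)
    wall_thickening: np.ndarray  # (16,)
    endo_radius_mm: np.ndarray  # (3,) basal/mid/apical end-diastolic
    lvedv_ml_m2: float
    lvesv_ml_m2: float
    lv_mass_g_m2: float
    la_min_ml_m2: float
    la_max_ml_m2: float
    la_passive_ml_m2: float
    la_active_ml_m2: float
    analyzable: np.ndarray = None  # (16,) bool; breath-hold dropout

    @property
    def ivrt_ms(self) -> float:
        return self.timing.ivrt_ms

    @property
    def cycle_ms(self) -> float:
        return self.timing.cycle_ms

    def strain_curve(self, segment_id: int) -> StrainTimecourse:
        """Analytic E_cc(t) of one segment (1-based AHA id)."""
        i = segment_id - 1
        return build_strain_timecourse(
            peak_scs=float(self.peak_scs_pct[i]),
            time_to_peak_ms=self.time_to_peak_ms,
            dcsr_target=float(self.peak_dcsr_pct_s[i]),
            timing=self.timing,
            atrial_kick_fraction=self.atrial_kick_fraction,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth of one subject (never derived from rendered images)."""

    subject_id: str
    group_label: str
    peak_scs_pct: np.ndarray
    peak_dcsr_pct_s: np.ndarray
    edwt_mm: np.ndarray
    eswt_mm: np.ndarray
    wall_thickening: np.ndarray
    sl_ratio: float
    ed_wall_radius_mm: np.ndarray  # (3,)
    lvedv_ml_m2: float
    lvesv_ml_m2: float
    sv_ml_m2: float
    lvef_pct: float
    lv_mass_g_m2: float
    la_min_ml_m2: float
    la_max_ml_m2: float
    la_reservoir_ml_m2: float
    la_passive_ml_m2: float
    la_active_ml_m2: float
    la_preA_ml_m2: float
    la_diastasis_ml_m2: float
    laef_pct: float
    ivrt_ms: float


def sl_ratio_from_edwt(edwt_mm: np.ndarray) -> float:
    """Maximal septal over maximal lateral EDWT (AHA septal 2,3,8,9,14;
    lateral 5,6,11,12,16)."""
    edwt_mm = np.asarray(edwt_mm, dtype=float)
    return float(edwt_mm[_SEPTAL_MASK].max() / edwt_mm[_LATERAL_MASK].max())


def ground_truth(subject: PhantomSubject) -> GroundTruth:
    """Analytic ground truth derived from the subject's parameters."""
    eswt = subject.edwt_mm * (1.0 + subject.wall_thickening)
    sv = subject.lvedv_ml_m2 - subject.lvesv_ml_m2
    preA = subject.la_min_ml_m2 + subject.la_active_ml_m2
    dia = subject.la_max_ml_m2 - subject.la_passive_ml_m2
    return GroundTruth(
        subject_id=subject.subject_id,
        group_label=subject.group_label,
        peak_scs_pct=subject.peak_scs_pct.copy(),
        peak_dcsr_pct_s=subject.peak_dcsr_pct_s.copy(),
        edwt_mm=subject.edwt_mm.copy(),
        eswt_mm=eswt,
        wall_thickening=subject.wall_thickening.copy(),
        sl_ratio=sl_ratio_from_edwt(subject.edwt_mm),
        ed_wall_radius_mm=subject.endo_radius_mm.copy(),
        lvedv_ml_m2=subject.lvedv_ml_m2,
        lvesv_ml_m2=subject.lvesv_ml_m2,
        sv_ml_m2=sv,
        lvef_pct=100.0 * sv / subject.lvedv_ml_m2,
        lv_mass_g_m2=subject.lv_mass_g_m2,
        la_min_ml_m2=subject.la_min_ml_m2,
        la_max_ml_m2=subject.la_max_ml_m2,
        la_reservoir_ml_m2=subject.la_max_ml_m2 - subject.la_min_ml_m2,
        la_passive_ml_m2=subject.la_passive_ml_m2,
        la_active_ml_m2=subject.la_active_ml_m2,
        la_preA_ml_m2=preA,
        la_diastasis_ml_m2=dia,
        laef_pct=100.0 * subject.la_active_ml_m2 / preA,
        ivrt_ms=subject.ivrt_ms,
    )


# ---------------------------------------------------------------------------
# presets


def _seg(basal, mid, apical):
    """Assemble a 16-vector from per-slice sextets/quartet."""
    return np.array(list(basal) + list(mid) + list(apical), dtype=float)


def carrier_group() -> GroupSpec:
    """Paper-calibrated HCM mutation-carrier group."""
    return GroupSpec(
        group_label="carrier",
        age_years=ScalarSpec(38.0, 13.2, 18.0, 75.0),
        male_fraction=11.0 / 28.0,
        heart_rate_bpm=ScalarSpec(63.0, 9.0, 42.0, 95.0),
        systolic_bp_mmhg=ScalarSpec(115.0, 12.0, 80.0, 160.0),
        diastolic_bp_mmhg=ScalarSpec(66.0, 10.0, 40.0, 100.0),
        bmi_kg_m2=ScalarSpec(22.9, 2.6, 16.0, 32.0),
        ivrt_ms=ScalarSpec(102.0, 18.0, 45.0, 160.0),
        la_min_ml_m2=ScalarSpec(24.0, 6.7, 8.0, 48.0),
        la_max_ml_m2=ScalarSpec(56.0, 11.7, 25.0, 95.0),
        la_passive_ml_m2=ScalarSpec(19.0, 4.6, 4.0, 36.0),
        la_active_ml_m2=ScalarSpec(14.0, 4.8, 2.0, 30.0),
        lvedv_ml_m2=ScalarSpec(96.0, 13.2, 55.0, 140.0),
        lvesv_ml_m2=ScalarSpec(38.0, 7.3, 16.0, 62.0),
        lv_mass_g_m2=ScalarSpec(99.0, 24.2, 40.0, 175.0),
        # EDWT: basal septal/inferior elevation; the common subject factor
        # (log-SD 0.15) cancels in thickness ratios, and the lateral spread
        # is calibrated so the per-subject max-septal/max-lateral ratio
        # averages 1.3 with a realistic SD
        edwt_mm=SegmentFamilySpec(
            means=_seg(
                (5.5, 6.4, 7.3, 6.0, 5.1, 5.1),
                (4.8, 5.3, 5.6, 5.0, 4.4, 4.3),
                (3.8, 4.3, 3.9, 3.6),
            ),
            sds=_seg(
                (0.9, 1.0, 1.5, 0.9, 1.12, 1.12),
                (0.9, 0.9, 0.9, 0.9, 1.12, 1.12),
                (1.0, 1.0, 1.0, 1.12),
            ),
            global_load=0.15,
            septal_load=0.0,
            distribution="lognormal",
        ),
        peak_scs_pct=SegmentFamilySpec(
            means=_seg(
                (-17.5, -16.8, -17.0, -17.5, -17.8, -18.0),
                (-18.5, -17.5, -17.6, -18.3, -18.6, -18.8),
                (-19.0, -18.2, -18.8, -19.2),
            ),
            sds=_seg(
                (3.3, 3.3, 3.3, 3.3, 3.3, 3.3),
                (3.4, 3.4, 3.4, 3.4, 3.4, 3.4),
                (3.4, 3.4, 3.4, 3.4),
            ),
            global_load=0.45,
        ),
        peak_dcsr_pct_s=SegmentFamilySpec(
            means=_seg(
                (97.0, 92.0, 90.0, 98.0, 116.0, 95.0),
                (102.0, 98.0, 96.0, 104.0, 112.0, 105.0),
                (100.0, 95.0, 102.0, 105.0),
            ),
            sds=_seg(
                (20.0, 20.0, 20.0, 20.0, 36.0, 23.0),
                (20.0, 20.0, 20.0, 20.0, 22.0, 22.0),
                (20.0, 20.0, 20.0, 20.0),
            ),
            global_load=0.45,
        ),
        wall_thickening=SegmentFamilySpec(
            means=_seg(
                (0.70, 0.61, 0.39, 0.55, 0.80, 0.78),
                (0.70, 0.62, 0.50, 0.60, 0.78, 0.76),
                (0.65, 0.55, 0.60, 0.70),
            ),
            sds=_seg(
                (0.25, 0.31, 0.21, 0.25, 0.25, 0.25),
                (0.25, 0.25, 0.25, 0.25, 0.25, 0.25),
                (0.25, 0.25, 0.25, 0.25),
            ),
            global_load=0.4,
        ),
    )


def control_group() -> GroupSpec:
    """Paper-calibrated healthy-control group."""
    spec = carrier_group()
    return replace(
        spec,
        group_label="control",
        age_years=ScalarSpec(39.0, 12.3, 18.0, 75.0),
        heart_rate_bpm=ScalarSpec(67.0, 9.0, 42.0, 95.0),
        systolic_bp_mmhg=ScalarSpec(124.0, 12.0, 85.0, 170.0),
        diastolic_bp_mmhg=ScalarSpec(72.0, 7.0, 45.0, 100.0),
        bmi_kg_m2=ScalarSpec(22.7, 2.6, 16.0, 32.0),
        ivrt_ms=ScalarSpec(100.0, 22.0, 45.0, 160.0),
        la_min_ml_m2=ScalarSpec(20.0, 3.9, 8.0, 40.0),
        la_max_ml_m2=ScalarSpec(51.0, 6.4, 25.0, 85.0),
        la_passive_ml_m2=ScalarSpec(18.0, 5.0, 4.0, 36.0),
        la_active_ml_m2=ScalarSpec(13.0, 3.1, 2.0, 28.0),
        lvedv_ml_m2=ScalarSpec(94.0, 14.2, 55.0, 140.0),
        lvesv_ml_m2=ScalarSpec(37.0, 8.3, 16.0, 62.0),
        lv_mass_g_m2=ScalarSpec(93.0, 22.9, 40.0, 175.0),
        # symmetric wall with a coherent septum (septal-only factor, log-SD
        # 0.14); lateral spread calibrated for a mean SL ratio of 1.1
        edwt_mm=SegmentFamilySpec(
            means=_seg(
                (5.0, 5.7, 6.1, 4.2, 4.8, 4.8),
                (4.6, 5.0, 5.2, 4.4, 4.5, 4.5),
                (3.5, 4.0, 3.5, 3.8),
            ),
            sds=_seg(
                (0.9, 1.3, 1.4, 0.9, 1.20, 1.20),
                (0.9, 0.9, 0.9, 0.9, 1.20, 1.20),
                (0.8, 0.8, 0.8, 1.20),
            ),
            global_load=0.15,
            septal_load=0.14,
            distribution="lognormal",
        ),
        peak_scs_pct=SegmentFamilySpec(
            means=_seg(
                (-18.5, -17.0, -17.5, -18.5, -19.9, -19.5),
                (-19.0, -18.0, -18.2, -19.0, -20.3, -20.0),
                (-19.5, -18.8, -19.3, -20.5),
            ),
            sds=_seg(
                (3.4, 3.4, 3.4, 3.4, 3.5, 3.4),
                (3.4, 3.4, 3.4, 3.4, 3.4, 3.4),
                (3.4, 3.4, 3.4, 3.4),
            ),
            global_load=0.45,
        ),
        peak_dcsr_pct_s=SegmentFamilySpec(
            means=_seg(
                (107.0, 102.0, 100.0, 112.0, 139.0, 130.0),
                (112.0, 108.0, 106.0, 116.0, 128.0, 122.0),
                (110.0, 105.0, 112.0, 118.0),
            ),
            sds=_seg(
                (20.0, 20.0, 20.0, 20.0, 26.0, 30.0),
                (20.0, 20.0, 20.0, 20.0, 22.0, 22.0),
                (20.0, 20.0, 20.0, 20.0),
            ),
            global_load=0.45,
        ),
        wall_thickening=SegmentFamilySpec(
            means=_seg(
                (0.75, 0.84, 0.65, 0.70, 0.82, 0.80),
                (0.74, 0.80, 0.68, 0.70, 0.80, 0.78),
                (0.70, 0.66, 0.68, 0.72),
            ),
            sds=_seg(
                (0.25, 0.28, 0.23, 0.25, 0.25, 0.25),
                (0.25, 0.25, 0.25, 0.25, 0.25, 0.25),
                (0.25, 0.25, 0.25, 0.25),
            ),
            global_load=0.4,
        ),
    )


# ---------------------------------------------------------------------------
# sampling


def _truncnorm(spec: ScalarSpec, n: int, rng) -> np.ndarray:
    """Resampling-based truncated normal (bounds are guard rails several SDs
    out, so the mean bias is negligible)."""
    x = spec.mean + spec.sd * rng.standard_normal(n)
    if np.isfinite(spec.lower) or np.isfinite(spec.upper):
        for _ in range(100):
            bad = (x < spec.lower) | (x > spec.upper)
            if not bad.any():
                break
            x[bad] = spec.mean + spec.sd * rng.standard_normal(int(bad.sum()))
        else:
            x = np.clip(x, spec.lower, spec.upper)
    return x


def _bsa_du_bois(height_cm: np.ndarray, weight_kg: np.ndarray) -> np.ndarray:
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def _endo_radii(edv_ml: np.ndarray) -> np.ndarray:
    """(n, 3) end-diastolic endocardial radii at the basal/mid/apical planes,
    from a three-disk cavity model with a 95 mm base-apex distance and a
    fixed taper profile."""
    long_axis = 95.0
    taper = np.array([1.0, 0.92, 0.62])
    r0 = np.sqrt(edv_ml * 1000.0 / (np.pi / 3.0 * long_axis * np.sum(taper**2)))
    return r0[:, None] * taper[None, :]


def sample_cohort(spec: GroupSpec, n: int, seed: int) -> list[PhantomSubject]:
    """Draw ``n`` subjects from a group specification.

    Deterministic for a fixed seed.  Per-segment peak DCSR draws below the
    feasibility floor of the strain-curve family (relengthening too slow to
    finish within that subject's diastole) are redrawn above it; the floor
    sits several SDs below the calibrated means, so segment means move by
    well under the 1 % calibration tolerance.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1 subjects")
    spec.validate()
    rng = np.random.default_rng(seed)

    male = rng.random(n) < spec.male_fraction
    age = _truncnorm(spec.age_years, n, rng)
    hr = _truncnorm(spec.heart_rate_bpm, n, rng)
    sbp = _truncnorm(spec.systolic_bp_mmhg, n, rng)
    dbp = _truncnorm(spec.diastolic_bp_mmhg, n, rng)
    bmi = _truncnorm(spec.bmi_kg_m2, n, rng)
    height = np.where(male, 181.0, 167.0) + 7.0 * rng.standard_normal(n)
    weight = bmi * (height / 100.0) ** 2
    bsa = _bsa_du_bois(height, weight)
    ivrt = _truncnorm(spec.ivrt_ms, n, rng)
    kick = _truncnorm(spec.atrial_kick_fraction, n, rng)

    # LV volumes: correlated EDV/ESV
    rho = spec.edv_esv_corr
    z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
    edv = spec.lvedv_ml_m2.mean + spec.lvedv_ml_m2.sd * z1
    esv = spec.lvesv_ml_m2.mean + spec.lvesv_ml_m2.sd * (
        rho * z1 + np.sqrt(1 - rho * rho) * z2
    )
    for _ in range(50):
        bad = (
            (esv >= edv - 5.0)
            | (edv < spec.lvedv_ml_m2.lower) | (edv > spec.lvedv_ml_m2.upper)
            | (esv < spec.lvesv_ml_m2.lower) | (esv > spec.lvesv_ml_m2.upper)
        )
        if not bad.any():
            break
        nb = int(bad.sum())
        z1b, z2b = rng.standard_normal(nb), rng.standard_normal(nb)
        edv[bad] = spec.lvedv_ml_m2.mean + spec.lvedv_ml_m2.sd * z1b
        esv[bad] = spec.lvesv_ml_m2.mean + spec.lvesv_ml_m2.sd * (
            rho * z1b + np.sqrt(1 - rho * rho) * z2b
        )
    mass = _truncnorm(spec.lv_mass_g_m2, n, rng)

    # LA volumes: correlated min/max, emptying volumes within the reservoir
    rho = spec.la_min_max_corr
    z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
    la_min = spec.la_min_ml_m2.mean + spec.la_min_ml_m2.sd * z1
    la_max = spec.la_max_ml_m2.mean + spec.la_max_ml_m2.sd * (
        rho * z1 + np.sqrt(1 - rho * rho) * z2
    )
    for _ in range(50):
        bad = (la_min < spec.la_min_ml_m2.lower) | (la_max <= la_min + 4.0)
        if not bad.any():
            break
        nb = int(bad.sum())
        z1b, z2b = rng.standard_normal(nb), rng.standard_normal(nb)
        la_min[bad] = spec.la_min_ml_m2.mean + spec.la_min_ml_m2.sd * z1b
        la_max[bad] = spec.la_max_ml_m2.mean + spec.la_max_ml_m2.sd * (
            rho * z1b + np.sqrt(1 - rho * rho) * z2b
        )
    # emptying volumes share the reservoir's variability (larger atria
    # empty more)
    reservoir = la_max - la_min
    mean_res = spec.la_max_ml_m2.mean - spec.la_min_ml_m2.mean
    sd_res = max(
        np.sqrt(
            spec.la_max_ml_m2.sd**2
            + spec.la_min_ml_m2.sd**2
            - 2.0 * rho * spec.la_max_ml_m2.sd * spec.la_min_ml_m2.sd
        ),
        1e-9,
    )
    z_res = (reservoir - mean_res) / sd_res
    load = 0.6
    la_pe = spec.la_passive_ml_m2.mean + spec.la_passive_ml_m2.sd * (
        load * z_res + np.sqrt(1 - load * load) * rng.standard_normal(n)
    )
    la_ae = spec.la_active_ml_m2.mean + spec.la_active_ml_m2.sd * (
        load * z_res + np.sqrt(1 - load * load) * rng.standard_normal(n)
    )
    la_pe = np.clip(la_pe, spec.la_passive_ml_m2.lower, spec.la_passive_ml_m2.upper)
    la_ae = np.clip(la_ae, spec.la_active_ml_m2.lower, spec.la_active_ml_m2.upper)
    # landmark validity: diastasis >= LA min and pre-A <= LA max (pre-A may
    # exceed diastasis: the atrium refills from pulmonary venous inflow
    # during diastasis, so passive+active may exceed the reservoir)
    la_pe = np.minimum(la_pe, 0.98 * reservoir)
    la_ae = np.minimum(la_ae, 0.98 * reservoir)

    # segmental families with shared factors; DCSR cross-loaded on the
    # wall-thickness factor (negative: thicker walls relengthen more slowly)
    z_wall = rng.standard_normal(n)
    z_sept = rng.standard_normal(n)
    c = spec.edwt_dcsr_corr
    z_dcsr = c * z_wall + np.sqrt(1 - c * c) * rng.standard_normal(n)
    z_scs = rng.standard_normal(n)
    z_wt = rng.standard_normal(n)
    edwt = spec.edwt_mm.draw(z_wall, z_sept, rng)
    scs = spec.peak_scs_pct.draw(z_scs, rng.standard_normal(n), rng)
    scs = np.minimum(scs, -0.5)  # contracting myocardium throughout
    dcsr = spec.peak_dcsr_pct_s.draw(z_dcsr, rng.standard_normal(n), rng)
    wt = spec.wall_thickening.draw(z_wt, rng.standard_normal(n), rng)
    wt = np.maximum(wt, -0.8)  # keep end-systolic thickness positive

    # cardiac timing and DCSR feasibility floor
    cycle = 60000.0 / hr
    t_avc = 0.35 * cycle
    t_mvo = np.minimum(t_avc + ivrt, 0.62 * cycle)
    floor = (
        1.02 * 1000.0 * np.abs(scs) * 1.005
        / (cycle[:, None] - t_avc[:, None] - 1.0 - 60.0)
    )
    for _ in range(100):
        bad = dcsr < floor
        if not bad.any():
            break
        redraw = spec.peak_dcsr_pct_s.draw(z_dcsr, rng.standard_normal(n), rng)
        dcsr = np.where(bad, redraw, dcsr)
    else:
        dcsr = np.maximum(dcsr, floor)

    radii = _endo_radii(edv * bsa)
    dropout = (
        rng.random((n, 16)) < spec.segment_dropout_prob
        if spec.segment_dropout_prob > 0
        else np.zeros((n, 16), dtype=bool)
    )

    subjects = []
    width = max(4, len(str(n)))
    for i in range(n):
        timing = CardiacTiming(float(cycle[i]), float(t_avc[i]), float(t_mvo[i]))
        subjects.append(
            PhantomSubject(
                subject_id=f"{spec.group_label}-{i:0{width}d}",
                group_label=spec.group_label,
                age_years=float(age[i]),
                male=bool(male[i]),
                height_cm=float(height[i]),
                weight_kg=float(weight[i]),
                bsa_m2=float(bsa[i]),
                heart_rate_bpm=float(hr[i]),
                systolic_bp_mmhg=float(sbp[i]),
                diastolic_bp_mmhg=float(dbp[i]),
                timing=timing,
                time_to_peak_ms=float(spec.time_to_peak_fraction * t_avc[i]),
                atrial_kick_fraction=float(kick[i]),
                edwt_mm=edwt[i],
                peak_scs_pct=scs[i],
                peak_dcsr_pct_s=dcsr[i],
                wall_thickening=wt[i],
                endo_radius_mm=radii[i],
                lvedv_ml_m2=float(edv[i]),
                lvesv_ml_m2=float(esv[i]),
                lv_mass_g_m2=float(mass[i]),
                la_min_ml_m2=float(la_min[i]),
                la_max_ml_m2=float(la_max[i]),
                la_passive_ml_m2=float(la_pe[i]),
                la_active_ml_m2=float(la_ae[i]),
                analyzable=~dropout[i],
            )
        )
    return subjects


def truth_table(subjects: list[PhantomSubject]) -> pd.DataFrame:
    """Subject-level ground-truth metric table (one row per subject).

    Columns include the screening metrics (``sl_ratio``,
    ``basal_dcsr_mean_pct_s``, ``basal_il_dcsr_pct_s``, ...) consumed by the
    statistics stage.
    """
    rows = []
    for s in subjects:
        gt = ground_truth(s)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group_label,
                "age_years": s.age_years,
                "male": s.male,
                "bsa_m2": s.bsa_m2,
                "heart_rate_bpm": s.heart_rate_bpm,
                "sl_ratio": gt.sl_ratio,
                "basal_edwt_mean_mm": float(gt.edwt_mm[_BASAL].mean()),
                "basal_is_edwt_mm": float(gt.edwt_mm[2]),
                "basal_is_thickening": float(gt.wall_thickening[2]),
                "basal_il_scs_pct": float(gt.peak_scs_pct[4]),
                "basal_il_dcsr_pct_s": float(gt.peak_dcsr_pct_s[4]),
                "basal_dcsr_mean_pct_s": float(gt.peak_dcsr_pct_s[_BASAL].mean()),
                "lvedv_ml_m2": gt.lvedv_ml_m2,
                "lvesv_ml_m2": gt.lvesv_ml_m2,
                "lvef_pct": gt.lvef_pct,
                "lv_mass_g_m2": gt.lv_mass_g_m2,
                "la_min_ml_m2": gt.la_min_ml_m2,
                "la_max_ml_m2": gt.la_max_ml_m2,
                "laef_pct": gt.laef_pct,
                "ivrt_ms": gt.ivrt_ms,
            }
        )
    return pd.DataFrame(rows)
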