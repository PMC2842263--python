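"""Analytic segmental time-courses: circumferential strain, LV and LA volume.

The segmental circumferential strain curve E_cc(t) is the motion primitive of
the deforming phantom.  It is parameterised directly by the two summary
quantities the downstream analysis measures:

* ``peak_scs`` -- the most negative strain over the cycle (%; systolic
  shortening, sign convention: shortening negative),
* ``dcsr_target`` -- the maximum of dE_cc/dt during diastole (%/s; the peak
  diastolic circumferential strain rate).

The curve is piecewise C1: a raised-cosine systolic limb from 0 down to
``peak_scs`` at ``time_to_peak``, a plateau through aortic valve closure and
the isovolumetric relaxation period, a smoothed trapezoidal early-diastolic
relengthening limb whose maximum slope equals ``dcsr_target`` exactly, an
optional diastasis plateau, and a smoothed atrial-kick limb returning the
strain to 0 at the end of the cycle (periodicity).  Trapezoidal limbs (linear
ramp-in/out of the strain rate over ``rise_ms``) are used instead of cosine
limbs so that the diastolic rate has an exact, extended maximum and so that
slow-relengthening draws remain schedulable inside diastole.

When a parameter combination is tight the builder compresses the curve in a
fixed order -- shrink the diastasis to zero by speeding up the atrial kick
(capped just below the early-limb rate so the early limb stays the diastolic
maximum), then advance the relengthening onset from mitral-valve opening
toward aortic closure -- and raises :class:`InfeasibleStrainError` only when
no schedule exists.  Nothing is ever silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CardiacTiming",
    "InfeasibleStrainError",
    "StrainTimecourse",
    "build_strain_timecourse",
    "min_feasible_dcsr",
    "lv_volume_curve",
    "la_volume_curve",
    "VolumeCurve",
]

#: cap on the atrial-kick rate relative to the early-diastolic rate, so the
#: early limb carries the diastolic maximum
_KICK_RATE_CAP = 0.995
#: preferred (unconstrained) atrial-kick rate relative to the early limb
_KICK_RATE_PREF = 0.7


class InfeasibleStrainError(ValueError):
    """The requested strain curve cannot be scheduled within the cycle."""


@dataclass(frozen=True)
class CardiacTiming:
    """Valve event times of one cardiac cycle (all ms from end-diastole)."""

    cycle_ms: float
    aortic_closure_ms: float
    mitral_opening_ms: float

    def __post_init__(self) -> None:
        if not (0.0 < self.aortic_closure_ms <= self.mitral_opening_ms < self.cycle_ms):
            raise ValueError(
                "require 0 < aortic closure <= mitral opening < cycle length, got "
                f"{self.aortic_closure_ms}, {self.mitral_opening_ms}, {self.cycle_ms}"
            )

    @property
    def ivrt_ms(self) -> float:
        """Isovolumetric relaxation time: mitral opening - aortic closure."""
        return self.mitral_opening_ms - self.aortic_closure_ms


# ---------------------------------------------------------------------------
# smoothed trapezoidal ramps (the diastolic limb primitive)


def _ramp_duration(amp: float, peak_rate: float, rise: float) -> float:
    """Duration of a smoothed ramp of amplitude ``amp`` with maximum slope
    ``peak_rate`` and slope rise time ``rise`` (triangle profile when the
    amplitude is too small to sustain a plateau)."""
    if amp <= peak_rate * rise:
        return 2.0 * amp / peak_rate
    return amp / peak_rate + rise


def _ramp_value(t: np.ndarray, duration: float, amp: float, rise: float) -> np.ndarray:
    """Displacement of the smoothed ramp at local time t in [0, duration]."""
    tau = min(rise, duration / 2.0)
    v = amp / (duration - tau)  # peak rate
    t = np.clip(t, 0.0, duration)
    out = np.where(
        t < tau,
        v * t * t / (2.0 * tau),
        np.where(
            t <= duration - tau,
            v * tau / 2.0 + v * (t - tau),
            amp - v * (duration - t) ** 2 / (2.0 * tau),
        ),
    )
    return out


def _ramp_rate(t: np.ndarray, duration: float, amp: float, rise: float) -> np.ndarray:
    tau = min(rise, duration / 2.0)
    v = amp / (duration - tau)
    inside = (t >= 0.0) & (t <= duration)
    r = np.where(
        t < tau,
        v * t / tau,
        np.where(t <= duration - tau, v, v * (duration - t) / tau),
    )
    return np.where(inside, r, 0.0)


# ---------------------------------------------------------------------------


def min_feasible_dcsr(
    peak_scs: float,
    timing: CardiacTiming,
    rise_ms: float = 30.0,
    margin: float = 1.0,
) -> float:
    """Smallest peak DCSR (%/s) that can return ``peak_scs`` to zero within
    diastole (relengthening onset advanced to just after aortic closure, no
    diastasis, atrial kick at the capped rate)."""
    if peak_scs >= 0.0:
        return 0.0
    avail = timing.cycle_ms - timing.aortic_closure_ms - 1.0 - 2.0 * rise_ms
    if avail <= 0.0:
        raise InfeasibleStrainError("no diastolic time available")
    # both limbs near rate R: total ramp time ~ |S|/R * (1 + eps) * 1000
    return margin * 1000.0 * abs(peak_scs) * (1.0 + (1.0 - _KICK_RATE_CAP)) / avail


@dataclass(frozen=True)
class StrainTimecourse:
    """Piecewise-analytic segmental circumferential strain curve E_cc(t).

    Evaluate with :meth:`value` / :meth:`rate`; times in ms, strain in %,
    rate in %/s.
    """

    peak_scs: float
    dcsr_target: float
    time_to_peak_ms: float
    timing: CardiacTiming
    atrial_kick_fraction: float
    rise_ms: float
    onset_ms: float = field(repr=False, default=0.0)  # relengthening onset
    early_duration_ms: float = field(repr=False, default=0.0)
    kick_duration_ms: float = field(repr=False, default=0.0)
    kick_rate: float = field(repr=False, default=0.0)  # %/ms

    @property
    def cycle_ms(self) -> float:
        return self.timing.cycle_ms

    @property
    def diastasis_interval(self) -> tuple[float, float]:
        """(start, end) ms of the diastasis plateau (may be empty)."""
        start = self.onset_ms + self.early_duration_ms
        return start, self.cycle_ms - self.kick_duration_ms

    def value(self, t):
        """Strain (%) at time(s) t ms (vectorized)."""
        t = np.mod(np.asarray(t, dtype=float), self.cycle_ms)
        S = self.peak_scs
        if S == 0.0:
            return np.zeros_like(t)
        tp = self.time_to_peak_ms
        amp1 = (1.0 - self.atrial_kick_fraction) * abs(S)
        amp2 = self.atrial_kick_fraction * abs(S)
        t_kick = self.cycle_ms - self.kick_duration_ms
        out = np.empty_like(t)

        sys_m = t < tp
        out[sys_m] = S * 0.5 * (1.0 - np.cos(np.pi * t[sys_m] / tp))
        hold_m = (t >= tp) & (t < self.onset_ms)
        out[hold_m] = S
        e_m = (t >= self.onset_ms) & (t < self.onset_ms + self.early_duration_ms)
        if self.early_duration_ms > 0.0:
            out[e_m] = S + _ramp_value(
                t[e_m] - self.onset_ms, self.early_duration_ms, amp1, self.rise_ms
            )
        d_m = (t >= self.onset_ms + self.early_duration_ms) & (t < t_kick)
        out[d_m] = S + amp1
        k_m = t >= t_kick
        if self.kick_duration_ms > 0.0:
            out[k_m] = (S + amp1) + _ramp_value(
                t[k_m] - t_kick, self.kick_duration_ms, amp2, self.rise_ms
            )
        return out

    def rate(self, t):
        """Strain rate (%/s) at time(s) t ms (vectorized, analytic)."""
        t = np.mod(np.asarray(t, dtype=float), self.cycle_ms)
        S = self.peak_scs
        if S == 0.0:
            return np.zeros_like(t)
        tp = self.time_to_peak_ms
        amp1 = (1.0 - self.atrial_kick_fraction) * abs(S)
        amp2 = self.atrial_kick_fraction * abs(S)
        t_kick = self.cycle_ms - self.kick_duration_ms
        out = np.zeros_like(t)
        sys_m = t < tp
        out[sys_m] = S * 0.5 * (np.pi / tp) * np.sin(np.pi * t[sys_m] / tp)
        e_m = (t >= self.onset_ms) & (t <= self.onset_ms + self.early_duration_ms)
        if self.early_duration_ms > 0.0:
            out[e_m] = _ramp_rate(
                t[e_m] - self.onset_ms, self.early_duration_ms, amp1, self.rise_ms
            )
        k_m = t >= t_kick
        if self.kick_duration_ms > 0.0:
            out[k_m] = _ramp_rate(
                t[k_m] - t_kick, self.kick_duration_ms, amp2, self.rise_ms
            )
        return out * 1000.0  # %/ms -> %/s

    # ground-truth summaries -------------------------------------------------
    @property
    def true_peak_scs(self) -> float:
        return self.peak_scs

    @property
    def true_peak_dcsr(self) -> float:
        """Maximum diastolic strain rate (%/s), exact by construction."""
        return self.dcsr_target if self.peak_scs < 0.0 else 0.0


def build_strain_timecourse(
    peak_scs: float,
    time_to_peak_ms: float,
    dcsr_target: float,
    timing: CardiacTiming,
    atrial_kick_fraction: float = 0.25,
    rise_ms: float = 30.0,
) -> StrainTimecourse:
    """Construct the segmental strain curve (see module docstring).

    Raises
    ------
    InfeasibleStrainError
        If ``dcsr_target`` is too small to return the strain to zero within
        the available diastole.
    ValueError
        On invalid parameters (positive peak strain, non-positive rate, ...).
    """
    if peak_scs > 0.0:
        raise ValueError("peak_scs is a shortening and must be <= 0 (%)")
    if not 0.0 <= atrial_kick_fraction < 1.0:
        raise ValueError("atrial_kick_fraction must be in [0, 1)")
    if not 0.0 < time_to_peak_ms < timing.aortic_closure_ms:
        raise ValueError("time_to_peak must lie inside systole (before aortic closure)")
    if peak_scs == 0.0:
        return StrainTimecourse(
            0.0, 0.0, time_to_peak_ms, timing, atrial_kick_fraction, rise_ms,
            onset_ms=timing.mitral_opening_ms, early_duration_ms=1.0,
            kick_duration_ms=1.0, kick_rate=0.0,
        )
    if dcsr_target <= 0.0:
        raise ValueError("dcsr_target must be > 0 for a contracting segment")

    v1 = dcsr_target / 1000.0  # %/ms
    amp1 = (1.0 - atrial_kick_fraction) * abs(peak_scs)
    amp2 = atrial_kick_fraction * abs(peak_scs)
    d1 = _ramp_duration(amp1, v1, rise_ms) if amp1 > 0 else 0.0

    t_on = timing.mitral_opening_ms
    avail = timing.cycle_ms - t_on

    def kick_dur(v2: float) -> float:
        return _ramp_duration(amp2, v2, rise_ms) if amp2 > 0 else 0.0

    v2 = v1 * _KICK_RATE_PREF if amp2 > 0 else 0.0
    d2 = kick_dur(v2) if amp2 > 0 else 0.0
    if amp1 == 0.0 and amp2 > 0.0:
        # degenerate: the kick is the only limb and must carry the target rate
        v2, d2 = v1, kick_dur(v1)
    if d1 + d2 > avail and amp2 > 0.0:
        # no diastasis: speed the kick up (capped below the early-limb rate)
        v2 = v1 * _KICK_RATE_CAP
        d2 = kick_dur(v2)
    if d1 + d2 > avail:
        # advance the relengthening onset toward aortic closure
        t_on = timing.cycle_ms - (d1 + d2)
        if t_on < timing.aortic_closure_ms + 1.0:
            raise InfeasibleStrainError(
                f"peak DCSR {dcsr_target:.1f} %/s cannot return "
                f"{peak_scs:.1f} % strain to zero within diastole "
                f"(need {d1 + d2:.0f} ms, have "
                f"{timing.cycle_ms - timing.aortic_closure_ms - 1.0:.0f} ms)"
            )
    return StrainTimecourse(
        peak_scs=float(peak_scs),
        dcsr_target=float(dcsr_target),
        time_to_peak_ms=float(time_to_peak_ms),
        timing=timing,
        atrial_kick_fraction=float(atrial_kick_fraction),
        rise_ms=float(rise_ms),
        onset_ms=float(t_on),
        early_duration_ms=float(d1),
        kick_duration_ms=float(d2),
        kick_rate=float(v2),
    )


# ---------------------------------------------------------------------------
# chamber volume curves


@dataclass(frozen=True)
class VolumeCurve:
    """Piecewise C1 chamber volume curve over one cycle (ms -> mL)."""

    times_ms: np.ndarray
    volumes_ml: np.ndarray

    def value(self, t):
        t = np.mod(np.asarray(t, dtype=float), self.times_ms[-1])
        return np.interp(t, self.times_ms, self.volumes_ml)


def _dense_times(cycle_ms: float, n: int = 2048) -> np.ndarray:
    return np.linspace(0.0, cycle_ms, n)


def lv_volume_curve(
    edv_ml: float,
    esv_ml: float,
    timing: CardiacTiming,
    atrial_kick_fraction: float = 0.2,
    rise_ms: float = 40.0,
    n_samples: int = 2048,
) -> VolumeCurve:
    """LV cavity volume: EDV at t=0, cosine ejection to ESV at aortic closure,
    isovolumetric hold to mitral opening, early filling, diastasis, atrial
    kick back to EDV at end-cycle."""
    if not esv_ml < edv_ml:
        raise ValueError("require ESV < EDV")
    t = _dense_times(timing.cycle_ms, n_samples)
    sv = edv_ml - esv_ml
    amp1, amp2 = (1.0 - atrial_kick_fraction) * sv, atrial_kick_fraction * sv
    t_dia = timing.cycle_ms - timing.mitral_opening_ms
    d1 = min(0.55 * t_dia, max(150.0, 0.35 * t_dia))
    d2 = min(0.30 * t_dia, 200.0)
    t_kick = timing.cycle_ms - d2

    v = np.empty_like(t)
    m = t < timing.aortic_closure_ms
    v[m] = edv_ml - sv * 0.5 * (1.0 - np.cos(np.pi * t[m] / timing.aortic_closure_ms))
    m = (t >= timing.aortic_closure_ms) & (t < timing.mitral_opening_ms)
    v[m] = esv_ml
    m = (t >= timing.mitral_opening_ms) & (t < timing.mitral_opening_ms + d1)
    v[m] = esv_ml + _ramp_value(t[m] - timing.mitral_opening_ms, d1, amp1, rise_ms)
    m = (t >= timing.mitral_opening_ms + d1) & (t < t_kick)
    v[m] = esv_ml + amp1
    m = t >= t_kick
    v[m] = esv_ml + amp1 + _ramp_value(t[m] - t_kick, d2, amp2, rise_ms)
    return VolumeCurve(t, v)


def la_volume_curve(
    la_min_ml: float,
    la_max_ml: float,
    passive_ml: float,
    active_ml: float,
    timing: CardiacTiming,
    rise_ms: float = 40.0,
    n_samples: int = 2048,
) -> VolumeCurve:
    """LA volume: reservoir filling to LA max at mitral opening, passive
    (conduit) emptying to the diastasis volume, a slow-drift plateau down to
    the pre-A volume, and active emptying back to LA min at end-cycle.

    Landmark identities hold exactly on the returned curve:
    diastasis = max - passive, preA = min + active.  The diastasis plateau
    drifts linearly from the diastasis volume to the pre-A volume; an
    upward drift (preA > diastasis) models pulmonary venous refilling of
    the atrium while the mitral inflow is quiescent.
    """
    if not la_min_ml < la_max_ml:
        raise ValueError("require LA min < LA max")
    reservoir = la_max_ml - la_min_ml
    if passive_ml < 0 or active_ml < 0:
        raise ValueError("emptying volumes must be non-negative")
    if passive_ml > reservoir or active_ml > reservoir:
        raise ValueError("emptying volumes cannot exceed the reservoir volume")
    v_dia = la_max_ml - passive_ml
    v_pre = la_min_ml + active_ml
    t = _dense_times(timing.cycle_ms, n_samples)
    t_dia = timing.cycle_ms - timing.mitral_opening_ms
    d1 = min(0.45 * t_dia, max(150.0, 0.30 * t_dia))
    d2 = min(0.30 * t_dia, 200.0)
    t_kick = timing.cycle_ms - d2

    v = np.empty_like(t)
    m = t < timing.mitral_opening_ms
    v[m] = la_min_ml + reservoir * 0.5 * (
        1.0 - np.cos(np.pi * t[m] / timing.mitral_opening_ms)
    )
    m = (t >= timing.mitral_opening_ms) & (t < timing.mitral_opening_ms + d1)
    v[m] = la_max_ml - _ramp_value(t[m] - timing.mitral_opening_ms, d1, passive_ml, rise_ms)
    m = (t >= timing.mitral_opening_ms + d1) & (t < t_kick)  # drifting diastasis
    span = t_kick - (timing.mitral_opening_ms + d1)
    frac = (t[m] - (timing.mitral_opening_ms + d1)) / span if span > 0 else 0.0
    v[m] = v_dia + (v_pre - v_dia) * frac
    m = t >= t_kick
    v[m] = v_pre - _ramp_value(t[m] - t_kick, d2, active_ml, rise_ms)
    return VolumeCurve(t, v)
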