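# Methods

`hcmstrain` simulates and analyzes the CMR screening workflow for
hypertrophic-cardiomyopathy (HCM) mutation carriers whose LV wall thickness
is still within normal limits (< 10 mm). Carriers in this pre-hypertrophic
stage show three subtle abnormalities: septal-dominant wall-thickness
asymmetry (maximal septal-to-lateral ED wall-thickness ratio, SL ratio),
reduced peak diastolic circumferential strain rate (peak DCSR) on tagged
CMR, and enlarged left atrial volumes. The package provides (1) a deforming
LV/LA phantom generator with exact analytic ground truth, (2) tagged-image
strain quantification, (3) cine morphometry, and (4) the diagnostic
statistics, including the two-threshold screen SL > 1.2 AND
DCSR < 105 %/s.

## Segmental strain time-course

Each segment's circumferential Lagrangian strain E_cc(t) (%, shortening
negative, zero at end-diastole) is parameterised directly by the two
summary statistics the analysis measures: peak systolic circumferential
strain (peak SCS = min E_cc) and peak DCSR (max dE_cc/dt after aortic valve
closure). The curve is piecewise C1: a raised-cosine systolic limb to peak
SCS at the time-to-peak (0.85 x aortic-closure time), a plateau through the
isovolumetric relaxation period, a smoothed trapezoidal early relengthening
limb whose maximum slope is exactly the prescribed peak DCSR, an optional
diastasis, and a trapezoidal atrial-kick limb (default 25 % of the
shortening amplitude, capped at 99.5 % of the early rate so the early limb
carries the diastolic maximum) returning the strain to zero at end-cycle.
Trapezoidal limbs were chosen over cosines because (a) the rate maximum is
then exact by construction, giving exact ground truth, and (b) slow
relengthening at large shortening stays schedulable: a tight draw first
loses its diastasis, then accelerates the kick, then advances the
relengthening onset toward aortic closure, and only then raises an
infeasibility error. The generator redraws peak-DCSR values below the
feasibility floor; the floor sits several SDs below the calibrated means,
moving segment means by under 0.3 %.

## Phantom geometry and deformation

**Tagged series.** One short-axis slice is an annulus (endocardial radius
from a three-disk cavity model of the subject's EDV; per-segment ED wall
thickness). Material points move purely radially under
r = sqrt(R^2 + c(theta, t)) with c = R_mid^2 (lambda^2 - 1) and
lambda = 1 + E_cc/100 the mid-wall stretch: the map has unit Jacobian
everywhere, so the ring's cross-sectional area is conserved exactly and the
mid-wall circumference scales exactly by lambda — the per-segment ground
truth is analytic, and strain/thickening are invariant to uniform scaling
of all lengths. Segmental parameters vary over angle as plateaus with
smoothstep transitions (18 deg for strain, 12 deg for thickness) so sector
cores carry the prescribed values exactly. A SPAMM-like grid of two
orthogonal sinusoidal tag-line families (7 mm spacing) is imprinted in
material coordinates across the whole excited slab and advected by the
map's natural extension (it decays like 1/r outside the wall); compartment
intensities (bright blood, myocardium, background) are feathered over
~1.5 mm. Tags fade monoexponentially (500 ms) and optional Gaussian noise
is added (default SNR 20). Frames follow the tagging protocol geometry
(default 1.2 mm pixels, 14.1 ms frames over one cycle).

**Cine stack.** LV cavity slices use a half-ellipsoid taper whose areas are
scaled so slice summation over the slice-plus-gap extent (5 + 5 mm, 20
phases) reproduces the subject's LV volume curve exactly; the LA is a
sphere matched to the LA volume curve the same way. Epicardial contours
follow the sampled per-segment wall-thickening time-course.

**Two facets of wall thickening.** In-plane incompressibility bounds
thickening at -E/(100+E) (about 0.22 at 18 % shortening), but real systolic
thickening (0.4-0.85) is dominated by through-plane motion that a 2D slice
model cannot represent. The phantom therefore keeps the exact
area-preserving deformation for the tagged facet (what strain
quantification sees) and samples peak wall thickening as an independent
calibrated parameter for the cine facet (what morphometry sees). Reported
ground-truth ESWT/thickening comes from the cine facet, ground-truth strain
from the tagged facet.

## Cohort generator and calibration

Subject-level parameters (age, sex, heart rate, blood pressures, BMI, IVRT,
LA volumes, LV volumes/mass) are truncated normals at the two groups'
published means/SDs; EDV/ESV and LA min/max are drawn correlated (0.8 /
0.7); height is sex-specific, weight follows the sampled BMI, and BSA uses
the Du Bois formula. LA passive/active emptying volumes load 0.6 on the
reservoir volume and are capped at 98 % of it (pre-A volume may exceed the
diastasis volume: pulmonary venous inflow refills the atrium during
diastasis). Valve timing: aortic closure at 0.35 cycle, mitral opening
after the sampled IVRT.

Segmental families (EDWT, peak SCS, peak DCSR, wall thickening) share
subject-level factors. EDWT is lognormal with a *common* multiplicative
subject factor (log-SD 0.15; controls add a septal-only factor, log-SD
0.14): a truly common factor cancels exactly in thickness ratios, which
keeps the SL-ratio spread realistic while segment means and SDs are matched
exactly. Peak DCSR loads negatively (r = -0.3) on the wall-thickness
factor (thicker walls relengthen more slowly). Printed segment means (e.g.
carrier basal inferoseptal EDWT 7.3 +/- 1.5 mm, thickening 0.39, basal
inferolateral peak SCS -17.8 %) enter directly; the unprinted lateral /
mid / apical means and SDs were calibrated once so the emergent nonlinear
statistics — the SL ratio is a per-subject ratio of maxima — average 1.30
(carriers) and 1.11 (controls), and so per-slice averages match the printed
slice means. Basal DCSR means average 98 (carriers) and 115 (controls)
%/s with the anterolateral/inferolateral values at their printed levels.

Known limitation: the published segmental EDWT SDs (inferoseptal 1.4-1.5
mm) force an SL-ratio SD of ~0.22-0.24, wider than the printed 0.21/0.13;
group separation at n = 28/28 is therefore significant at p < 0.05 in
nearly all cohorts but reaches p < 0.001 in only ~half, weaker than the
published comparison. Two further inconsistencies in the published tables
are left visible rather than resolved: LV mass/volume as mass over EDV is
~1.0, not the printed 0.53, and LAEF is implemented as active emptying /
pre-A volume (~37 % at the printed means, near the printed 35 %), since
(max-min)/max would give ~57 %.

## Tag tracking and strain

Tracking is harmonic-phase based: Gaussian band-pass filters (sigma 0.4 x
the tag frequency) isolate the two tag harmonics, a DC notch (0.5 x)
suppresses anatomy, and the filtered complex images are demodulated by the
carrier so only a slowly varying envelope is interpolated (interpolating
the raw ~6 px/period oscillation biases the phase). Each material point —
seeded on the mid 50 % of the wall, central 60 % of each sector — is
followed by Newton iteration on phase constancy from its previous-frame
position, with the phase Jacobian computed analytically from the envelope.
Track quality is the local harmonic magnitude relative to the reference
frame (fading-corrected); points falling below 0.2 are flagged lost, and
segments with fewer than two valid points are excluded, never interpolated.
Block matching (the more common default) was evaluated first and abandoned:
on a periodic tag pattern it locks onto the wrong lobe and accumulates
drift (~3 mm RMS), far outside this package's 0.5 mm fidelity contract,
which harmonic tracking meets with ~0.07 mm RMS on noise-free phantoms.

Segmental strain is Lagrangian: E = 100 (L - L0)/L0 over adjacent-point
chords per depth band, averaged within the segment; the reference phase is
exactly zero. Strain rate uses central differences after an optional
3-point moving average (default on); peak SCS is the curve minimum and peak
DCSR the rate maximum after aortic closure (atrial-kick rates included).
Noise-free end-to-end recovery: peak SCS within +/-1 % strain, peak DCSR
within +/-5 %/s across groups, slices and seeds; at SNR 20 the DCSR error
grows to tens of %/s — rate estimates from noisy 14 ms data should be
interpreted accordingly.

## Morphometry

Wall thickness: 100 radial chords from the cavity centroid, per-segment
mean and maximal chord, excluding chords within 15 % of a sector boundary
(partial-volume of the neighbouring segment) and flagging segments with
> 20 % failed chords. SL ratio: max septal (AHA 2, 3, 8, 9, 14) over max
lateral (5, 6, 11, 12, 16) maximal-chord EDWT across all analyzed slices.
ED wall radius: mean centroid-to-endocardium distance on an arc-length
resampled contour. LV volumes by slice summation over thickness + gap;
mass = shell volume x 1.05 g/mL at ED. The LA volume curve is decomposed
via its rate extrema: the passive-emptying rate peak after the volume
maximum, the active peak in the final 30 % of the cycle, diastasis at the
onset of quiescence (|dV/dt| below 20 % of the peaks), pre-A at the last
quiescent sample; curves without a quiescent window (high heart rate) flag
the diastasis undefined and merge the landmarks. IVRT is mitral opening
minus aortic closure.

## Statistics

Group comparison: classical Student t-test gated by Shapiro-Wilk normality
(alpha 0.05) on both samples, Mann-Whitney U otherwise. ROC: AUC by the
rank statistic (equal to the trapezoid rule and to the exhaustive pairwise
win fraction, ties half credit), Hanley-McNeil closed-form SE, optimal
cutoff by Youden's J. Correlated-AUC comparison uses the Hanley-McNeil z
with r defaulting to the mean within-class Pearson correlation of the
paired scores (the quantity their lookup table is entered with; the table
value is approximated by the correlation itself and r is overridable).
The two-threshold rule tallies four quadrants; PPV/NPV use the concordant
quadrants only, matching how such screens are reported. Bland-Altman
agreement reports mean/SD of differences and limits of agreement; the
coefficient of variability averages per-pair SD (|d|/sqrt 2) over the pair
mean. Multilevel models are linear mixed models (ML) with random subject
intercepts and a slice-within-subject variance component, via statsmodels
MixedLM; pairwise interaction screens are fitted one at a time on top of
the main-effects model, and singular or non-converged fits are reported,
not masked. 95 % CI coverage of a known carrier effect is 95 +/- 3 % over
500 simulated cohorts of 56 subjects x 16 segments.

## Problem sizes and reproducibility

Calibration checks use 20,000 draws per group (sampling is vectorized;
~1 s). Imaging-chain checks render one slice per case at 160 x 160 /
14.1 ms (~70 frames) and track 48 mid-wall points (~2 s per slice); the
pipeline renders a configurable subset of subjects (default 2 per group)
because the generator's parameter-level truth makes rendering every subject
redundant for cohort statistics. Every output carries the master seed and a
configuration hash; reruns of the same configuration are byte-identical
(the run manifest records a content hash over all outputs).

## What the phantoms do and do not show

Passing tests demonstrate that the estimators are correct on data whose
generating process is known exactly: an annular, purely radially deforming
myocardium with plateau-wise segmental parameters, ideal sinusoidal tags,
stationary Gaussian noise, and exact contours. Real tagged CMR adds
through-plane motion, twist, off-resonance and flow artefacts,
breath-hold misregistration (the generator exposes a segment-dropout
probability, default 0, but models no mechanism for it) and observer
variability in contouring — none of which are represented. Accuracy
contracts here are therefore statements about the algorithmic chain, not
about clinical measurement error.
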