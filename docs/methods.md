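# Methods

`dvjrel` implements a complete multi-laboratory drop-vertical-jump (DVJ)
motion-analysis pipeline: raw marker/force trials (real or simulated) are
gap-filled, low-pass filtered, windowed to the stance phase, converted to
clinical joint angles and inverse-dynamics joint moments, and summarized
with the reliability statistics used in multicenter screening studies —
intraclass correlation coefficients (ICC), standard error of measurement
(SEM), and Kadaba's coefficient of multiple correlation (CMC).  This note
documents the models, the defaults, and the choices made where the design
was genuinely open.

## Processing pipeline

The per-trial order is fixed: **gap fill → low-pass filter → stance
windowing → kinematics & kinetics → 101-point time normalization**.
Filtering a series with masked samples is undefined, so gap filling always
precedes it.

**Gap filling.** Gaps shorter than 10% of the marker sampling rate
(24 frames at 240 Hz, 20 at 200 Hz; computed as `floor(0.10 * rate)`) are
filled with a cubic spline through all valid samples of that marker —
exact for trajectories that are locally polynomial up to cubic order.
Gaps in the ASIS (anterior superior iliac spine) markers between 10% and
25% of the rate are reconstructed as a *virtual marker*: the missing ASIS
is a fixed point of the rigid pelvis, so its local coordinates in a frame
built from the contralateral ASIS, the sacrum and the left PSIS are
estimated over a calibration window and re-applied across the gap.  Gaps
exactly at the 10% boundary are routed to the spline (the printed rule
"less than 10%" versus "greater than 10%" leaves the boundary ambiguous;
the inclusive-spline choice is the more accurate fill).  ASIS gaps beyond
25%, and any gap touching the trial boundary, are left masked and the
trial is flagged for exclusion.  Bilateral ASIS dropouts are retried in
sweeps, so one repaired ASIS can serve as the reference for the other.

**Filtering.** "Fourth-order low-pass Butterworth at 12 Hz" is read as a
12 Hz *cutoff* (sampling at 12 Hz would contradict the 200–240 Hz capture
rates).  The filter is applied forward–backward (zero phase), so the
effective magnitude response is the squared single-pass response — tests
and validation use that squared-response oracle.  Markers and force
channels are filtered at the same cutoff, each at its native rate; forces
are then decimated onto the marker clock by taking every rate-ratio-th
sample.

**Stance detection.** Stance runs from the first force sample where the
vertical ground-reaction force (GRF) exceeds 10 N to the first subsequent
sample below 10 N, half-open on the force clock, converted to the marker
clock by integer division.  Detection operates on the **unfiltered**
vertical GRF: a 12 Hz zero-phase filter smears the landing onset over tens
of milliseconds (and rings ahead of it), while the threshold rule on the
raw signal localizes contact to one sample.  Chatter tie-break: the
earliest qualifying crossing wins; an optional debounce window (default
off, 5 ms when enabled) is exposed for noisy plates.

**Time normalization.** Stance-phase series are linearly resampled onto
101 points (0–100% of stance), endpoints preserved exactly.  Linear
interpolation keeps the error below `h²·max|f''|/8`, i.e. under 1e-3 of
amplitude for up to ~1 cycle per stance at ≥96 stance frames.

## Kinematics

Anatomical axes come from the neutral-standing **static trial**: pelvis
from the ASIS pair and sacrum; thigh and shank from the estimated hip
center and the knee-/ankle-joint-line midpoints with the respective
medial/lateral marker pairs; foot from its heel→toe long axis and the
static vertical.  Hip joint centers use the standard pelvic regression —
0.19/0.36/0.30 of inter-ASIS breadth posterior/lateral/distal of
mid-ASIS — with the fractions configurable.

During movement each segment is tracked by a least-squares rigid-body
(Kabsch/SVD) fit of **all** its available cluster markers to the static
cluster, which resists single-marker noise; the anatomical frame rides on
the fit.  Joint angles are the intrinsic Cardan decomposition of the
distal anatomical frame relative to the proximal one in the clinical
sequence flexion → ab/adduction → axial rotation, unwrapped over time,
with per-side sign maps so flexion, adduction, internal rotation,
dorsiflexion and inversion are positive on both sides.  Angles are
**zeroed at the static pose** (the neutral standing alignment defines 0°
on every axis); this affects absolute peak values and is the documented
convention.

A consequence worth stating: marker-placement differences between
laboratories enter the angles through the anatomical-axis tilt they
induce.  With the static zeroing, a proximal-segment axis tilt cancels and
a distal-segment tilt acts as a conjugation of the joint rotation —
crosstalk that redistributes a large flexion excursion into the
small-range frontal/transverse angles.  This is exactly why, both in the
simulation and in real multi-site data, sagittal peaks stay reliable
across sites while coronal/transverse peaks degrade first.

## Kinetics

Joint moments come from a bottom-up Newton–Euler recursion
(foot → shank → thigh) per side.  Segment inertial parameters use
standard cadaver-table fractions (mass, CoM position, radius of gyration;
arms and head folded into the trunk), stored as an editable table.
Segment linear/angular velocity and acceleration are central differences
(one-sided at the ends), with angular velocity taken from the skew part of
`dR/dt·Rᵀ`.  The center of pressure is computed from the *raw* plate
channels, masked where `Fz` is below the 10 N threshold (avoiding
divide-by-small-force artifacts), edge-held, then filtered and decimated
like everything else.  Each foot is matched to the plate whose stance COP
lies nearest its ankle markers; two feet resolving to one plate is an
error.

Reported moments are **internal** (the moment musculature exerts on the
distal segment), expressed in the **proximal anatomical frame**, and
normalized by body mass (N·m/kg).  Both conventions are configurable in
principle but fixed here and stated because the knee-abduction-moment
literature mixes internal/external conventions.  The moment resolution
frame and the internal convention cannot be disambiguated from printed
summary tables; these defaults match common modeling-software behavior.

## Reliability statistics

Sixteen outcome variables: peak hip/knee/ankle flexion(dorsiflexion),
ad/abduction(eversion) and internal rotation angles (°) and the
corresponding mass-normalized moments, peaks taken within stance in a
per-variable configured direction (e.g. knee abduction is the extremum in
the abduction direction of the internally adduction-positive curve;
sagittal moments are taken in the extensor/plantarflexor direction that
dominates a landing).

* **Within-site** (trial-to-trial): each subject's 3 trials are raters —
  ICC(3,k), SEM, and the CMC over the subject's 3 stance curves
  (mean ± SD across subjects).
* **Between site pairs**: trial-averaged subject values ("the average of
  three trials"), the two sites are raters — ICC(3,1), SEM, CMC over the
  two per-site mean curves.
* **Among all three sites**: three sites as raters — ICC(3,k), CMC over
  the three per-site mean curves.

ICC uses the Shrout–Fleiss two-way mean squares: with BMS/JMS/EMS the
between-subject, between-rater and residual mean squares,
`ICC(3,1) = (BMS−EMS)/(BMS+(k−1)·EMS)` and `ICC(3,k) = (BMS−EMS)/BMS`,
classified excellent (>0.75), good (0.4–0.75), poor (<0.4).  Negative
estimates are reported as computed (the reference tables themselves print
−0.112, −0.288, −0.250), except inside SEM where the ICC is floored at 0
and flagged.  `SEM = SD·√(1−ICC)` with SD the standard deviation of all
cell values of the design (ddof = 1).  The CMC is the within-day Kadaba
form on 101-point curves; when the within-time dispersion exceeds the
total dispersion the value is undefined (recorded as NaN, excluded from
mean ± SD with an exclusion count — never clipped into [0, 1]).  Which
Kadaba variant the original analysis used is not stated; the within-day
form is the default and the site-mean-curve construction is documented
above.  Missing cells are handled by casewise deletion per analysis; no
imputation.

Sides are analyzed separately (`side="l"`/`"r"`); reports default to the
right side and the CLI `report` command renders either side against the
packaged reference tables.  A known discrepancy in the reference material
is preserved rather than silently fixed: the published text calls
ankle-dorsiflexion *A–B* the only poor between-site kinematic variable,
while the printed table gives A–B 0.789 (excellent) and B–C 0.373 (poor);
the package follows the table and the classification rule, under which the
single poor kinematic instance is B–C ankle dorsiflexion.

## Quality control

Mirroring a batch pipeline's verification steps: (1) a **simplified
skeleton check** — per-segment rigid-cluster fit residuals plus
inter-marker distance drift against the static capture; a trial fails when
any segment residual exceeds 15 mm (config) in more than 1% of frames.
Label swaps and mistracking break the rigid fit and are caught with large
margin, while realistic noise (a few mm) passes.  (2) **Outlier-curve
screening**: per variable and site, a pointwise mean ± z·SD band (95%
default) computed leave-one-out; a curve is flagged when more than 20% of
its points fall outside.  Flags are advisory by default
(`qc_gate=False`); the gate drops flagged trials before reliability when
enabled.  The full rigid-IK skeleton of the original processing chain is
deliberately reduced to the cluster-residual form: it captures the same
failure mode (the rigid model cannot fit mistracked markers) with a
testable contract.

## The synthetic cohort generator

The generator emulates the study conditions: 25 subjects (height
169.3 ± 4.5 cm, mass 62.3 ± 6.8 kg) × 3 laboratories × 3 trials, drop
from 0.31 m with feet initially 0.35 m apart, stance ≈ 0.400 s, sites
A/B at 240/1200 Hz and C at 200/1000 Hz, 43 markers (32 body + 8 shoe +
3 backpack).

**Motion model.** A hip-height spline through (contact, deepest point,
take-off) knots — boundary velocities from the ballistic drop
(√(2g·0.31) ≈ 2.47 m/s) and a 0.25 m jump — drives a closed-form two-link
sagittal inverse kinematics with the feet planted; knee-flexion depth at
the knots is the subject's primary random effect.  Smooth half-sine bumps
add pelvis tilt/obliquity/rotation/lateral sway, trunk lean, hip axial
rotation, knee valgus (a medial knee shift with the foot planted) and
rotation, and ankle inversion/foot rotation; foot placement (stance
width) also varies per subject and trial.  A short exponential
"compliance" (τ = 12 ms) decelerates the foot at contact and lifts it
into take-off so segment velocities are continuous at the stance
boundaries.  In flight the posture is frozen and the body translates
ballistically.

**Variance structure** (the two-level design the reliability analysis
assumes): amplitude parameters are drawn once per subject and shared
across sites; each trial adds jitter (e.g. 2.5° on peak knee flexion,
~1–1.5° on frontal/transverse amplitudes, 12 ms on stance duration);
marker-placement offsets (default SD 7 mm per coordinate, in the segment
frame) are drawn per site × subject and held fixed for that site's static
and movement trials.  Offsets therefore displace the constructed
anatomical axes — the crosstalk mechanism above — rather than adding
rigid-cluster-cancelling noise.  Measurement noise: 0.5 mm white marker
noise plus an 8 Hz, 2 mm soft-tissue oscillation on thigh/shank markers,
amplitude-modulated by the stance bump so the 12 Hz filter is exercised
but does not remove it entirely.  Defaults were chosen once to give SEMs
of the magnitude the reference tables print (≈2–5° between-site for
sagittal angles, sub-degree to ~1.5° within-site frontal); no
distributional parameters are published, so these are synthetic settings,
not estimates.

**Forces.** The total GRF equals body mass × (CoM acceleration + g),
with the whole-body CoM computed from the realized segment poses and
differentiated numerically on the force clock — so GRF is identically
zero in flight and the impulse–momentum balance holds to <1% by
construction, giving inverse dynamics a self-consistent oracle.  Load is
split between the two plates with a per-subject asymmetry; each plate's
COP progresses heel→toe under its foot, and plate moments are taken about
the lab origin.  Linear (CoM) consistency is exact; global *angular*
momentum consistency is not enforced — the COP trajectory is prescribed,
not derived — which is irrelevant to the closed-loop checks because truth
moments are defined from the same force system.

**Ground truth** per trial: joint-angle curves (the same static-zeroed
decomposition the pipeline computes, evaluated on the true rotation
matrices), joint-moment curves (Newton–Euler on the true poses and
generated forces), the stance interval, the gap ledger, and the applied
site offsets.  Injected gaps default to 2 per trial on the ASIS markers,
5–30 frames, uniformly placed (overlaps merged) — emulating the pelvis
dropouts that motivated the virtual fill; occasionally a merged gap
exceeds the 25% limit and the trial is excluded, as in a real study.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genuine soft-tissue kinematics (our artifact is
a parametric oscillation, not muscle/skin deformation), arm swing (arms
ride rigidly on the trunk), heel-rise and foot roll-over beyond the
compliance term, impact transients above the modeled smoothness,
non-Gaussian placement errors (a mis-palpated landmark is systematic, not
random), and any physiological coupling between kinematics and kinetics
beyond rigid-body dynamics.  Reliability magnitudes on synthetic cohorts
are therefore structurally, not numerically, comparable to the published
tables.

## Validation and problem sizes

The test suite and acceptance script verify, at these sizes (chosen to
keep full runs in the minutes range while leaving Monte-Carlo error well
inside the asserted tolerances):

* ICC equals a from-scratch loop-coded ANOVA oracle to 1e-12 on 1000
  random matrices (n ∈ [4,30], k ∈ [2,5]) and matches pingouin's
  published ICC(C,1)/(C,k) routine to 1e-9.
* CMC equals a direct triple-summation oracle to 1e-12; undefined cases
  are flagged, never clipped.
* Zero-noise closed loop (2 subjects × 3 sites): stance-phase joint-angle
  RMS error ≤0.1° (measured ~1e-12°; the unfiltered pipeline is used for
  this check because noise-free data needs no smoothing — the 12 Hz filter
  itself contributes a real, separate ~0.2–0.5° attenuation to fast knee
  curves, which is signal loss, not reconstruction error).
* Inverse dynamics: static lever arms exact to machine precision; dynamic
  sagittal knee moment within 2% of peak of an independently coded
  d'Alembert (direct angular-momentum-balance) oracle.
* Stance: the 10 N rule reproduces the generator's contact/take-off to
  within one force sample; mean stance duration 0.400 ± 0.015 s.
* Reliability recovery: with placement offsets at 0/4/8/12/16 mm
  (20 replicates × 8 subjects each), the median measured between-site ICC
  of the frontal/transverse peak angles decreases strictly monotonically;
  with zero site effect and no trial jitter the true-peak between-site
  ICCs equal 1, and under full measurement noise at the study size no
  between-site kinematic variable classifies poor.

## Known limitations

* C3D support requires the optional `ezc3d` dependency; the TSV dialect is
  the first-class, exactly-round-tripping format.
* The Euler sequence, hip-center regression, moment frame and
  internal-moment convention are defaults standing in for an unpublished
  processing configuration; all are exposed as configuration.
* SEM uses the all-cells SD; other definitions (√EMS) exist and differ
  slightly for unbalanced noise.
* The generator's GRF split across plates is a smooth weighting, not a
  contact model; per-foot horizontal forces do not individually satisfy a
  friction cone.
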