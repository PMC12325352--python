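# Methods

`romocap` implements a complete analysis chain for marker-based
assessment of spinal and shoulder active range of motion (ROM):
raw 3D marker trajectories → preprocessed coordinates → per-sample
angles in a pelvis-anchored local frame → repetition-segmented ROM and
task-duration metrics → a two-group longitudinal statistical workflow.
A forward-kinematic synthetic-trial generator with known ground truth
makes every stage testable end to end.

## Coordinate conventions and the pelvis frame

The laboratory frame (X, Y, Z) is right-handed with Y vertical (up),
Z anterior and X from the subject's left to right.  All coordinates
are millimetres; all angles are degrees.

The local frame (x, y, z) is rebuilt on every sample from the pelvic
markers: the pelvic plane is fitted through RASIS, LASIS and the PSIS
point (the mid-PSIS when both sides are instrumented, the single PSIS
otherwise); y is the upward unit normal of that plane; x is the
inter-ASIS direction re-orthogonalised against y (Gram–Schmidt, so the
basis is orthonormal to machine precision); z = x × y.  Angles
expressed in this frame discount pelvic motion, which separates, for
example, true axial trunk rotation from whole-body turning.

Two construction details were genuinely open and are our choices:

* A single ASIS–PSIS vector cannot define a plane; using all three
  pelvic landmarks (both ASIS plus the PSIS point) is the minimal
  construction that reduces to the one-PSIS wording when only RPSIS is
  instrumented.
* The local spinal-rotation angle (SRL) is described in some sources
  against the "coronal plane", which cannot contain a rotation about
  the vertical axis.  We measure SRL between the projection of the
  acromion line onto the local *transverse* (x–z) plane and z — the
  geometrically consistent reading.  This interpretation is a
  documented decision, not silently assumed.

## Measured angles

Shoulder angles are planar projection angles of the upper-arm vector
(acromion → elbow) from the neutral downward direction (−y), not 3D
elevation angles: flexion (SF) in the sagittal y–z plane (positive
anterior), extension (SE) the same construction with positive
posterior, abduction (SA) in the frontal x–y plane (positive away from
the midline).  They are signed in (−180°, 180°] and computed in the
local frame by default (configurable to laboratory axes).

Shoulder-line angles use the LACR→RACR vector: inclination against
the vertical axis (SIA laboratory, SIL local) and rotation against the
anterior axis (SRA laboratory, SRL local-transverse as above), unsigned
in [0°, 180°].

Spinal segment inclinations (S1-L1, S1-L3, L1-T1, L1-T6, T6-T1) are
unsigned angles of the caudal→cranial landmark vector against
laboratory Y.  Pelvis, trunk and thorax angles are signed
sagittal-plane projections: the pelvis angle projects S1→L1 into the
local sagittal plane, the trunk angle projects S1→T1 into the
laboratory sagittal plane, and the thorax angle is the relative angle
between the local-sagittal projections of L1→T1 and S1→L1.

Samples where the in-plane projection falls below 1 % of the vector
norm are flagged invalid and interpolated over (for extrema detection
only) rather than producing unstable values.

## Preprocessing

Reconstruction gaps are carried as an explicit boolean mask — never
sentinel coordinates — so filtering can refuse to run over unfilled
gaps.  Runs of up to `max_gap` samples (default 20, i.e. 0.2 s at
100 Hz) are filled by coordinate-wise linear interpolation between the
flanking valid samples; longer gaps and gaps touching a trial boundary
are errors.  The default is conservative: the source protocol does not
document a gap-filling limit.

Coordinates are then low-pass filtered with a Butterworth filter at
5 Hz.  The filter order and phase handling are not specified by the
protocol; we default to the de-facto standard in movement analysis — a
zero-phase, net 4th-order response obtained by applying a 2nd-order
design forward and backward (`sosfiltfilt`) with odd-reflection padding
of 3 × order samples.  Both the order and single-pass mode are
configurable.  Filtering operates on marker coordinates before angle
computation (angles are non-linear in the coordinates, so the order
matters in principle; at these noise levels the difference is far below
the repetition-level variability).

## Repetition segmentation, ROM and duration

Repetitions are detected on the task's primary angle curve:

| task             | primary angle |
|------------------|---------------|
| frontal rise     | SF            |
| lateral rise     | SA            |
| backward push    | SE            |
| lateral bending  | SIL           |
| twist            | SRL           |
| anterior flexion | trunk         |

The movement direction is inferred from the curve's asymmetry about
its median (inclination-type angles *dip* from their 90° rest value, so
repetitions appear as valleys).  Extrema with prominence below 20 % of
the global max−min amplitude are ignored (default, configurable); each
surviving peak with its flanking returns to the rest plateau forms one
repetition.  The boundary on each side is the tied-minimum sample
nearest the peak, which on an idealised rest plateau is exactly the
instant motion starts or stops — this is what makes duration recovery
exact to the sample on noiseless data.  A repetition count different
from the expected six is recorded as a warning, not an error, because
real recordings contain extra or missing cycles.

Per repetition, ROM = max − min of the primary angle (degrees); task
duration = (end of last repetition − start of first)/sample rate.
Pooling follows the study protocol: within each set the first
repetition is dropped (settling-in bias) and the rest averaged; the two
sets are averaged per participant; sides of bilateral tasks are
averaged only when a preliminary paired t-test finds no systematic
left–right difference.  The exclusion granularity is configurable
(`per_set`, the conservative default, drops repetition 1 of every set;
`per_side_first_set_only` drops it only in the first set).

## Synthetic data generator

The generator is a rigid-segment forward-kinematic model of the
14-marker upper-body set (acromia, elbows, four pelvic landmarks, and
the S1–L3–L1–T6–T1 spinous chain).  Each task drives a single rotation
(arm about the acromion for the shoulder tasks; the whole trunk about
S1 for bending/twist/flexion) with a raised-cosine profile per
repetition,

    θ_r(τ) = (ROM_r / 2) · (1 − cos 2πτ/T),   τ ∈ [0, T],

with ROM_r = true ROM + trend·(r − 1) + N(0, σ_rep²), separated by
1 s rest plateaus and 1 s lead-in/out.  Because marker placement is
exact forward kinematics, the pipeline's primary angle reproduces θ
identically — the generator is a ground-truth oracle, and noiseless
recovery is exact to numerical precision (≈10⁻¹⁴ deg in practice).

Cohorts emulate a two-group longitudinal design: a treated group (WG)
measured at PRE/ACUTE/POST and a control group (CG) at PRE/POST, 21
participants per group.  Each participant's latent per-session true
ROM and task duration are drawn from session-specific normal
distributions whose default means/SDs are the published group summary
statistics of each task's primary parameter, with an equicorrelated
between-session correlation of 0.8 (the value used throughout the
power experiments).  The per-repetition amplitude SD defaults to 2°, a
realistic within-set repeatability for active ROM; marker noise is
i.i.d. Gaussian with 2 mm SD per coordinate, standing in for soft-tissue
artifact and reconstruction error (no published artifact model exists
for this protocol).  The twist task carries a default facilitation
trend of +2.41°/repetition in the ACUTE session, consistent with the
published first-vs-last considered-repetition means (≈29.7° → ≈39.3°
across repetitions 2–6); the trend is centred so the latent session
value remains the expected pooled ROM.  Per-trial random streams are
drawn from the master seed in a fixed enumeration order, so a cohort is
bit-reproducible from (spec, seed).

What the generator does *not* model — and hence what passing tests do
not establish about real data: correlated/low-frequency soft-tissue
artifact, multi-segment spinal articulation during anterior flexion
(rigid whole-trunk rotation by default; secondary degrees of freedom
are off by default), marker occlusion structure beyond i.i.d. gaps,
and any physiological treatment mechanism.  Inter-repetition
deviations are assumed i.i.d.; the real correlation structure is
unknown.

## Statistical workflow

The workflow reproduces standard longitudinal practice: Shapiro–Wilk
normality per group×session×parameter cell and Levene homogeneity
across groups; a preliminary right-vs-left paired t-test justifying
side pooling; a 2 (group) × 2 (PRE/POST) mixed repeated-measures ANOVA
whose session×group interaction is the headline treatment-specific
test; within the treated group a one-way RM-ANOVA across
PRE/ACUTE/POST (Greenhouse–Geisser-corrected p reported alongside the
uncorrected one, since sphericity handling was unspecified) with
Holm-corrected paired t post hocs and Cohen's d; and paired PRE–POST
t-tests for the control group.  α = 0.05 throughout; missing sessions
are handled by listwise deletion within each analysis (logged, no
imputation).

Cohen's d for paired contrasts is mean(diff)/SD(diff) — the published
effect sizes are consistent with this definition — with the
average-variance form (m₂ − m₁)/√((s₁² + s₂²)/2) also provided for
independent/summary-statistic contrasts.  Bands are left-closed:
small < 0.20 ≤ moderate < 0.50 ≤ large < 0.80 ≤ very large.

The repetition-progression ("fatigue") analysis runs an RM-ANOVA
across the analysed repetitions plus a first-vs-last paired contrast.
Percent change is computed per participant as 100·(last − first)/first
and then averaged; the ratio-of-group-means variant is reported
alongside, because published percent changes are not reproducible from
printed first/last means alone and the exact per-subject form is
unstated — we label both and assert neither as canonical.

ANOVA fits are delegated to `pingouin` (cross-checked in the test
suite against `statsmodels`' `AnovaRM` and a hand-computed split-plot
decomposition); t-tests, Shapiro–Wilk and Levene to `scipy`; Holm
adjustment to `statsmodels`.  Designs with zero within-subject
residual variance (possible in degenerate simulations) are resolved
from the sums of squares directly instead of an undefined F ratio.

## Numerical and design choices

* Angle range conventions: signed planar angles in (−180°, 180°];
  line-vs-axis angles in [0°, 180°].
* Frame degeneracy (collinear pelvic landmarks) and zero-length
  vectors raise errors rather than returning NaNs.
* Repetition boundaries use a 10⁻⁹-deg tie tolerance on segment
  minima.
* The pipeline is deterministic: identical config + master seed yield
  byte-identical cohort tables; every run writes a provenance file.

## Validation experiment sizes

The validation suite (also reproducible via `scripts/acceptance.py`)
uses: 1000 random configurations for the brute-force angle oracle;
3 noiseless and 100 noisy (2 mm) trials per task for recovery;
1000 null simulations per ANOVA layer for type-I error; 21 + 21
participant marker-level cohorts of the shoulder-extension task (one
side, one set per session — the latent between-subject variability
dominates the power calculation, so additional sets/sides change it
only marginally) across several hundred replicates for interaction
power; and 21-subject twist experiments for the repetition-progression
recovery.

## Known limitations

* The C3D implementation covers the common Intel-processor, 3D-point
  subset (integer or float storage, POINT group parameters); analog
  channels, force plates and event sections are out of scope.
* Only the single primary rotation per task is simulated; cross-talk
  between angles under combined movements is testable (secondary
  degrees of freedom can be enabled) but not part of the default
  conditions.
* Side pooling decisions are all-or-nothing across tasks/parameters,
  mirroring the published protocol rather than a per-task decision.
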