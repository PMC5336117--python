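# Methods

This note documents the models, numerical choices and limitations of
`smithsquat`, in the package's own terms.

## Coordinate and sign conventions

World frame: X anterior, Y to the subject's left, Z up; the sagittal plane
is XZ. SI units internally (m, kg, N, rad); I/O uses mm for stature and
degrees for angles. Flexion is positive everywhere: hip and pelvis–thorax
flexion carry the distal segment anteriorly, knee flexion carries the shank
posteriorly. With the thigh pointing down, hip flexion is a rotation about
−Y, so the flexion-positive hip moment is the negative +Y moment component;
knee and pelvis–thorax flexion moments are the +Y component directly.

## Body and machine model

The body is a 25-segment, 16-joint rigid linkage: pelvis, thorax, head,
plus per side clavicle, scapula, humerus, ulna, radius, hand, thigh,
patella, shank, talus, foot. The 16 counted joints (pelvis–thorax, neck,
2 sternoclavicular, 2 glenohumeral — spherical; 2 elbows, 2 wrists,
2 ankles — universal; 2 hips — spherical; 2 knees — revolute) carry 38
DOFs; the remaining segments attach by uncounted welds (clavicle–scapula,
ulna–radius, thigh–patella, talus–foot). The trans-spherical joint (4 DOF)
exists in the joint vocabulary but is unused in the default roster, which
is the package's own consistent enumeration — published model descriptions
give only the segment/joint/muscle totals, kept as registry metadata
(25 / 16 / 804 with 140 muscles per arm, 159 per leg, 206 trunk+head).

Segment lengths scale linearly with stature and masses with body mass via
a Winter-style proportional table (`data/anthropometry.yaml`); the mass
fractions are tuned to sum exactly to 1 (the thorax takes the remainder,
0.329). A generic proportional scaling is used; no length–mass–fat
interaction. Segment inertia uses slender-rod radii of gyration
(thigh 0.323 L, shank 0.302 L about the transverse axis).

The Smith machine is a bar of mass `bar_load / g` (default 267 N) on a
prismatic guide tilted θ ∈ [0°, 20°] from vertical. The tilt sense makes
the descending bar drift **posteriorly**, tracking the hips; this is the
orientation under which growing θ unloads the trunk and hips, the design
direction the sweep exists to quantify. The guide line passes through the
initial-pose shoulder point: the initial pose is the straightened body
leaning `asin(D / L_total)` toward the bar with all driven angles zero, so
D = 0 puts the ankles directly under the bar. Feet are placed under the
hips (stance width = hip width, 2 × 0.0955 h); a wider stance would demand
frontal-plane leg angles that the purely sagittal driven set cannot close.

DOF accounting: 38 joint + 6 pelvis + 1 bar = 45. Constraint records
remove 11 (frozen neck/sternoclavicular/glenohumeral-flexion posture),
14 (hand-bar welds: elbows, wrists, glenohumeral abduction/rotation,
pelvis–thorax lateral bending and axial rotation) and 15 (foot welds +
shoulder revolute: hip abduction/rotation, ankles, pelvis 6-DOF, bar
travel), leaving the five driven flexion/extension coordinates.

## Closed-loop kinematics

Given the five driven angles at a frame, the unknowns are the pelvis 6-DOF
pose and the bar travel (7 coordinates). Residuals: both ankle positions
against their welded anchors (6), the shoulder point against the guide
line (2), and trunk roll/yaw locked to the bar (2). The system is solved
by Levenberg–Marquardt least squares, warm-started from the previous
frame; shoulder rows carry weight 10, foot and orientation rows weight 1.
Symmetric driven angles admit an exact solution (residual ~1e-16 m);
asymmetric angles cannot close rigid welds exactly, so the solver returns
the weighted least-squares pose with the residual surfaced (mm-level for
1.5° smooth trial noise, hard cap 0.05 m). Velocities and accelerations
come from central differences (one-sided at the endpoints) over the 6 s
cycle.

For the dynamics the body is lumped into feet (+tali), shanks, thighs
(+patellae), pelvis, an upper body rigid with the thorax (thorax + head +
arms, hands gripping the bar beside the shoulders) and the bar. Rotational
inertia enters through the sagittal (+Y) axis only — the motion is planar
up to the solver's least-squares compromise, and the frontal/transverse
rates are negligible by construction.

## GRF prediction and inverse dynamics

The human + bar system is supported by two load paths: eight ground
contact points (heel/toe × medial/lateral per foot, from scaled foot
dimensions) and the rail reaction, which acts at the bar centre and is
perpendicular to the guide (frictionless rails). Each frame solves

    min ‖f‖²  s.t.  Σ forces and moments = net wrench,  f_z(contact) ≥ 0

by a deterministic active-set elimination on the KKT system. The
minimum-norm objective reproduces the even split in the symmetric static
limit and leaves the rails unloaded when the feet alone suffice; a zero
bar load removes the rail path entirely (no shoulder contact). Frames
whose wrench would require tensile contact are flagged, not silently
clipped. This contact model is the package's declared stand-in for
motion-based GRF prediction; the solver it emulates is not published in
component form.

Joint moments: legs are cut distally (foot wrench + distal segment
inertia/gravity, recursive from the ankle up), the pelvis–thorax joint is
cut cranially with the bar's shoulder force `N_rail − m_bar (a_bar − g)`
applied at the shoulder. Magnitude mode is the pointwise absolute value,
and it is the default for sweep reports. Bilateral symmetry is emergent,
never enforced: a 15% deeper left knee produces visibly unequal left/right
moment series.

## Muscle recruitment

Reduced parametric lower-limb set, eight muscles per leg (gluteus maximus,
biceps femoris, semitendinosus, rectus femoris, three vasti, adductor
longus) with literature PCSAs and constant signed moment arms
(`data/muscles.csv`), plus a ±270 N·m ideal actuator pair for the
pelvis–thorax joint. Maximum force = PCSA × 90 N/cm². Per frame:

1. LP (HiGHS): minimize the maximum activity γ subject to
   `Σ rᵢ fᵢ = M` per DOF and `0 ≤ fᵢ ≤ γ fmaxᵢ`;
2. tie-break (SLSQP): minimize Σ activity² at fixed γ for uniqueness.

Frames whose moments exceed total capacity are flagged with γ > 1 rather
than failed. Moment reconstruction holds to ~1e-16 relative. Constant
moment arms are the default; no activation/tendon dynamics, no
EMG signal processing. Quantitative muscle-activity magnitudes are
therefore indicative only; no match to published per-case activity tables
is claimed.

## Motion synthesis (GPR)

One GP per driven angle over `x = (D/h, θ/20, t/T)`; anisotropic squared
exponential kernel; targets centred (zero prior mean, centring constant
stored). Defaults: signal SD 40°, length scales (0.15, 0.6, 0.18) in the
scaled features, noise variance 0.25 deg² — chosen once for the smooth
curve family and kept fixed for determinism; marginal-likelihood
optimisation (L-BFGS-B on log-parameters, seeded restarts) is available
via `fit --optimize`. The Gram matrix is Cholesky-factorised with
geometric jitter escalation 1e-10 → 1e-6, recorded on the model. The
predictive covariance ends in K* (the standard form). Training uses
per-case mean curves subsampled to every 4th cycle point (9 cases × 26
points = 234 rows), which loses nothing measurable on these band-limited
curves and keeps the factorisation instant. One GP per joint rather than a
multi-output model: cross-joint coherence is already induced by the shared
inputs.

## Synthetic database

Structure mirrors the study conditions: 14 subjects × 9 cases
(D/h ∈ {0, 0.14, 0.28} × θ ∈ {0°, 10°, 20°}) × 5 reps = 630 trials, 6 s
cycles on a 101-point grid, anthropometry Normal(1770, 82.6²) mm and
Normal(78, 11.6²) kg truncated at ±3 SD, deterministic per
(seed, subject, case, rep) RNG streams.

Each trial's truth curve is a raised cosine `0.5 (1 − cos 2πt)` between
the initial posture (all driven angles zero) and an exactly consistent
bottom posture: the bottom shank tilt is
`22° − 25° (D/h) + 3° (D/h)(θ/20)` (feet forward → shins more vertical),
the bottom pelvis–thorax flexion `8° + 36° (D/h)(1 − 0.6 θ/20)`
(guide tilt attenuates trunk-flexion demand), the thigh is horizontal
(parallel squat), and the trunk angle follows from the
shoulder-on-guide-line constraint. Hip and knee bottom angles are read off
that geometry, so the mid-cycle thigh is horizontal under forward
kinematics by construction. Trial noise is a smooth squared-exponential
process (SD 1.5°, length scale 0.15 cycle) windowed by sin²(πt) so cycles
close exactly; subjects carry habitual offsets (SD 1.5° shank, 0.9° trunk).

The effect magnitudes are declared stand-ins: only their directions follow
the documented design discussion, and the generator is not claimed to
match any measured curve family. Consequently, passing the held-out
recovery test shows the *synthesis pipeline* can recover smooth case
effects of realistic size from a noisy multi-subject database — it says
nothing about how well a GP would fit real squat kinematics, and the
moment/activity magnitudes downstream inherit the same caveat. Real data
features the generator does not emulate: inter-subject timing variability,
descend/ascend asymmetry, bilateral asymmetry beyond smooth noise,
measurement artefacts (soft-tissue, marker gaps) and EMG stochasticity
(the EMG-like surrogate exists only to exercise the metrics).

## Validation metrics

NRMSE = 100 × RMSE / (max − min) of the **reference** series (the
normalising range is configurable but defaults to the reference, the
natural reading); zero reference range raises rather than returning
infinity. Pearson r with the two-sided t-transform p-value; constant
series raise. Peak timing is the cycle fraction of the global maximum,
earliest frame on ties. Total muscle activity is the full-cycle mean of
samples ≥ 0.20 (sub-threshold samples contribute zero), × 100 — the
published definition does not state the normaliser, so this choice is
declared, not inferred.

Table aggregation uses exact decimal arithmetic on the printed cell
strings, displayed with round-half-even at the table's precision — the
convention that reproduces the published summary rows, including the tie
cells (e.g. a column mean of 15.65 printed as 15.6). The hip summary of
the joint-angle correlation table is reproduced as the mean of the two
already-rounded side averages; direct cell arithmetic gives 0.993 instead
of the printed 0.994, one of two small internal inconsistencies in the
published summaries (the other: a grand-average correlation printed as
0.988 where the cells average to 0.990 — not asserted anywhere).

## Problem sizes and determinism

Defaults: 101-frame cycles, 630-trial database, 234-row GP training sets,
25-case sweep. These are the sizes the package's own validation runs use;
the acceptance script completes in well under a minute on one CPU. All
randomness flows from a single integer seed through named RNG streams;
re-running any pipeline stage with the same seed and config reproduces
outputs byte-for-byte (the CLI logs a config hash with every artefact).

## Known limitations

* The muscle set, moment arms and the contact/rail distribution rule are
  declared surrogates; absolute moment and activity magnitudes should be
  read as model outputs, not subject measurements.
* Constant moment arms ignore the angle dependence of knee-extensor
  leverage at deep flexion.
* The frozen-arm lump applies the full bar load at the shoulder; hand
  force paths are not resolved individually.
* Asymmetric driven angles close only in the least-squares sense; the
  residual (reported per frame) is the proxy for soft-tissue compliance.
* No friction cone at the feet and no rail friction; tangential contact
  forces are unbounded.
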