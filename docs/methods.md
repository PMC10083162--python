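# Methods

## Scope and model

`pafosim` estimates how the mass, mass distribution and ideal actuation of
a powered ankle–foot orthosis (PAFO) change lower-limb net joint moments
and individual muscle forces during walking. The analysis is restricted to
the sagittal plane — the primary plane of progression — with a four-segment
chain (pelvis, thigh, shank, foot) and hinge joints at hip, knee and
ankle. Generalized coordinates are the pelvis translation (locating the
hip joint), pelvis tilt, hip flexion (+), knee flexion (+) and ankle
dorsiflexion (+). Internal moments are reported in the same conventions;
an all-positive series therefore has its "extension peak" at the signed
minimum, which may itself be positive.

Key simplifications, accepted deliberately:

* no 3D hip degrees of freedom, subtalar/toe joints, or muscle wrapping;
* rigid tendons, no passive muscle elements, no activation dynamics;
* pelvis motion is prescribed from the (recovered) kinematics rather than
  balanced by residual actuators, so no upper body is modelled;
* the stance-side ground reaction force (GRF) is applied to the right
  foot only, and — by assumption — is **never augmented with the device
  weight**. All device configurations therefore see identical external
  loads, and differences between configurations isolate the inertial and
  gravitational effect of the device itself.

## Anthropometric scaling

Segment properties are fractions of height `H` and body mass `M`
(Winter-style table, swappable via YAML): segment masses 67.8% (lumped
pelvis + head-arms-trunk), 10.0% thigh, 4.65% shank, 1.45% foot of `M`;
lengths 24.5% (thigh), 24.6% (shank) and 11.4% (ankle-to-toe foot axis) of
`H`; CoM at 43.3% of segment length from the proximal joint (50% for
pelvis and foot); radii of gyration 32.3/30.2/47.5% of segment length.
Only one leg is modelled, so segment masses intentionally sum to ~83.9%
of `M`; the GRF generator carries the full body weight.

## The device as distributed mass

The actuator is the heavy component: 80% of the device mass is a point
mass at its position; 10% spreads over the shank brace and 10% over the
foot plate. The seven actuator positions are ankle-aligned (`A_S`) and
75/50/25% of shank length distal of the knee (`L`, `M`, `U`), each side-
or back-mounted. Side mounts (and `A_S`) are offset laterally — out of
the sagittal plane, hence no in-plane lever — while back mounts sit
0.05 m posterior (configurable; the true offset depends on the wearer's
geometry and is not published). Brace and plate masses merge at the
segment geometric midpoints: a uniformly spread component is centred on
its segment, and a fixed merge point makes repeated applications compose
exactly like one heavier device (merging at the inertial CoM would not,
because that point moves with each addition). Composite mass, CoM and
inertia follow from mass-weighted averaging and the parallel-axis
theorem; total model mass grows by exactly the device mass.

## Synthetic gait generator

The generator emulates the *statistical structure* of treadmill gait
recordings: many consecutive strides per subject at a fixed belt speed
(1.25 m/s), averaged into one representative stride, with
forward-kinematics-derived marker trajectories plus sensor noise. It does
not replay any recorded dataset.

* **Joint angles.** Truncated Fourier series (4–6 harmonics) fitted by
  least squares to normative waypoint templates: one hip
  flexion–extension wave (≈ +30° to −16°), a knee pattern with a small
  stance bump and a dominant ~63° flexion peak at ~72% of the cycle, and
  an ankle trajectory with stance dorsiflexion progression, a
  plantarflexion burst (≈ −15°) at push-off and a small dorsiflexion hold
  in late swing. Fourier bases make every series exactly periodic.
  Per-subject variation scales each joint's amplitude (σ = 3%) and shifts
  phase (σ = 0.5% of the cycle); cycle-to-cycle jitter (σ = 2% amplitude,
  3% GRF) is averaged out over 31 strides, the minimum stride count the
  averaging emulates.
* **GRF.** Vertical force `sin(πu) + 0.25·sin(3πu)` on normalized stance
  time `u`, zero in swing (stance fraction 0.60), rescaled so the
  both-limb stride average equals supported weight exactly;
  anterior–posterior force −0.16·W·sin(2πu) (braking then propulsion,
  zero net impulse). The centre of pressure moves linearly on the ground
  from the heel-contact point to the toe-off point, which reproduces the
  early-stance dorsiflexor and late-stance plantarflexor demand.
* **Markers.** Nine markers (two on the pelvis, two per thigh/shank,
  three on the foot) with i.i.d. Gaussian noise, default σ = 2 mm.
* **Pacing.** Stride length 0.79·H, so cycle duration is 0.79·H/1.25 s;
  the pelvis advances at belt speed with a ±1.2 cm double-bump vertical
  oscillation.

What the generator does *not* emulate: out-of-plane kinematics, soft
tissue artefact (noise is white, not correlated), treadmill-belt
dynamics, inter-subject waveform shape differences beyond amplitude/phase
scaling, and pathological gait. Passing trend tests therefore show that
the *mechanical chain* (added distal mass → inertial moments → muscle
redundancy resolution) produces the expected qualitative structure, not
that the
synthetic panel reproduces any recorded cohort's numbers.

## Inverse kinematics

Per frame, damped Gauss–Newton (Levenberg) minimization of the weighted
squared marker residual over all six coordinates, forward-difference
Jacobian (step 1e-7), damping adapted ×10/÷3 on rejection/acceptance,
convergence at objective decrease < 1e-10 m² (or objective < 1e-24), max
100 iterations, warm-started from the previous frame. Marker weights are
equal by default (no better-motivated weighting is available).
Including pelvis translation as free coordinates makes the solution
equivariant to rigid marker translations. Recovered joint angles are
clipped into joint limits; on noiseless data the round-trip error is
~1e-10 rad.

## Differentiation and inverse dynamics

Series on the 101-frame percent grid are treated as periodic (the last
frame repeats the first): a linear trend (pelvis travel) is removed, the
remainder is low-pass filtered with a zero-phase 4th-order Butterworth
(default cutoff 6 Hz on the implied time grid — conventional for gait —
`None` disables), and differentiated by central differences with wrap-
around; the trend rate is added back.

Net moments come from a recursive Newton–Euler pass (foot → shank →
thigh) with analytic segment CoM accelerations from the joint derivative
series. The recursion is verified in the tests against an independent
non-recursive free-body summation and closed-form static/pendulum
oracles; because the equations are linear in the inertial parameters, the
device's moment contribution superposes exactly.

## Static optimization

Per frame: minimize Σa² (+ the reserve term) subject to moment balance at
the three joints, 0 ≤ a ≤ 1. Force–length is Gaussian with width 0.45
normalized lengths; force–velocity is a linear clamp — zero at maximum
shortening velocity (10 optimal lengths/s), eccentric plateau 1.4. Both
factors are frozen at the frame's kinematic state (the standard
linearization), making the program strictly convex with a unique
solution; ties are impossible. Fiber length uses constant signed moment
arms about a reference pose (hip 0.15, knee 0.35, ankle −0.05 rad, the
approximate mid-range of gait) at which every muscle sits at optimal
length.

The twelve lumped muscles (Fmax N, optimal fiber length m, constant
moment arms m, flexion/dorsiflexion-positive): iliopsoas (3000, 0.11,
hip +0.040), gluteus maximus (1950, 0.15, hip −0.060), adductor magnus
(1650, 0.14, hip −0.030), rectus femoris (1170, 0.11, hip +0.035, knee
−0.045), vasti (5000, 0.10, knee −0.045), semimembranosus (1540, 0.11,
hip −0.055, knee +0.035), semitendinosus (410, 0.19, hip −0.055, knee
+0.040), biceps femoris short head (800, 0.17, knee +0.035), medial/
lateral gastrocnemius (1560/680, 0.09, knee +0.020, ankle −0.045),
soleus (3550, 0.10, ankle −0.048), dorsiflexor group (1400, 0.11, ankle
+0.040). Values are representative literature-scale parameters for
lumped actuators; the iliopsoas value reflects the combined
psoas+iliacus strength needed to swing the limb (weaker values make
heavy distal device configurations genuinely infeasible in early swing).

**Reserve actuator.** Foot drop plus ideal assistance is modelled as in
a single mechanism: the dorsiflexors stay in the model, and a
dorsiflexion-only ankle reserve with optimal torque 1 MN·m enters the
cost as (τ/τ_opt)². At that weighting its cost is ~1e-10 of any
activation cost, so whenever the reserve is present (the two actuation
situations) it absorbs all dorsiflexion demand and the dorsiflexors go
silent — no explicit strength zeroing is needed (a `weak_dorsiflexors`
flag exists for sensitivity checks). We interpret the 1 MN·m value as a
cost normalization, the quadratic form above.

**Solver.** The reserve variable is eliminated analytically: in the
1 MN·m limit the ankle equality relaxes to "muscle ankle torque ≤
demand" with the reserve as slack, which for a strictly convex program
with one inequality reduces to at most two equality-constrained solves —
and keeps every linear system at muscle scale instead of carrying a 1e6
column. The box-constrained minimum-norm subproblem is solved by
semismooth Newton on its concave dual (primal recovery
x = clip(Aᵀλ/2, bounds)), globalized by an Armijo line search on the
dual value with step candidates at the piecewise-linear kinks; tolerance
1e-10 on the moment residual. Frames whose moments are unreachable with
bounded activations are flagged with their moment deficit rather than
silently absorbed by extra reserves. The solver is cross-checked in the
tests against SLSQP at tight tolerance and an exhaustive grid oracle.

## Metrics and aggregation

Outcome metrics: percentage change (V₂−V₁)/|V₁|·100 against the
no-device baseline; the muscle force integral, a trapezoidal integral of
|F| over the 0–100% grid (units force × percent) computed on the
body-mass-normalized force; signed peak moments per joint; and the
overall effect — the unweighted mean percentage change across muscles,
excluding the dorsiflexor group (foot-drop-affected) and any muscle
tagged `lower_back_excluded` (none in the default 12-muscle set, which
has no back muscles). Aggregation order: normalize per subject →
per-subject integrals and peaks → average across subjects → percentage
change of the averages (the alternative per-subject-change-then-average
order is available behind `per_subject_changes`).

Sweep economics (package defaults): 101 frames per cycle, 31 strides
averaged per subject, 10 subjects, 7 positions × 5 masses × 4
situations. The no-device and actuation-only situations are physically
independent of position and mass, so they are computed once per subject
and shared across cells; each mass-bearing cell rebuilds the model from
the pristine baseline. A full default sweep is a few minutes of
single-core compute.

## Known limitations

* **Muscle-set granularity affects the per-muscle-averaged actuation
  comparison.** Activating the ideal reserve produces, per muscle, the
  expected directional responses: the dorsiflexors collapse to zero, the
  gastrocnemius heads rise strongly (antagonists of the dorsiflexion
  reserve and knee-flexion synergists once their plantarflexion is free),
  the hamstrings fall (relieved at the knee), and gluteus maximus /
  adductor magnus rise (hip-extension flow-on). In the unweighted mean
  over the 11 included muscles the two gastrocnemius terms carry ~18% of
  the weight, and the mean lands a few points *above* the mass-only
  value; in a full-fidelity (~30-muscle) model the same directional
  pattern averages to a net reduction because the gastrocnemius terms
  are diluted by many small, slightly relieved muscles. The reduced set
  is a deliberate design choice; conclusions about the *overall*
  actuation benefit should therefore be drawn from the per-muscle
  responses, not from this package's 11-muscle average.
* The ten-subject anthropometric fixture's printed weights give a sample
  SD of 12.87 kg, while the published summary row shows 12.90 kg
  (evidently computed from unrounded source data); recomputation from
  the printed table necessarily returns 12.87.
* Percentage changes of peak moments and force integrals depend on the
  synthetic templates' baseline magnitudes; only signs, orderings and
  monotonicities are meaningful for comparison with recorded-data
  analyses.
* Infeasible frames are possible in principle for extreme device
  configurations; they are flagged with their moment deficits rather than
  silently corrected. None occur under the default conditions.
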