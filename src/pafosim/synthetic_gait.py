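"""Seeded synthetic treadmill gait: joint angles, GRFs, markers, averaging.

Generates normatively shaped sagittal gait for one stride on a normalized
0–100% cycle grid (101 frames): a single hip flexion–extension wave, a
double-peaked knee flexion pattern with its main peak in swing, an ankle
trajectory with a plantarflexion burst at push-off and a small dorsiflexion
hold in late swing, a double-bump vertical ground reaction force confined
to stance (0–60% by default), and forward-kinematics-derived marker
trajectories with optional additive Gaussian noise.  Joint angles are
truncated Fourier series fitted to waypoint templates, so every generated
series is exactly periodic.  All randomness is seeded.

The generator emulates the statistical structure of treadmill gait
recordings (many consecutive cycles per subject at a fixed belt speed,
averaged into one representative stride); it does not replay any recorded
dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._fk import COORD_NAMES, marker_array
from .msk_model import GRAVITY, LowerLimbModel

# --- waypoint templates (percent of gait cycle, degrees) --------------------
# Normative sagittal trajectories: values chosen to match textbook gait at
# free walking speed.  Fourier fitting below smooths and periodizes them.

HIP_WAYPOINTS = [
    (0, 30), (10, 25), (20, 14), (30, 3), (40, -8), (50, -16), (55, -15),
    (60, -10), (70, 6), (80, 22), (90, 30), (95, 31),
]
KNEE_WAYPOINTS = [
    (0, 6), (10, 16), (15, 18), (25, 13), (35, 6), (45, 5), (55, 15),
    (60, 34), (68, 58), (73, 63), (80, 50), (88, 25), (95, 10), (100, 6),
]
ANKLE_WAYPOINTS = [
    (0, 0), (5, -6), (10, -3), (15, 1), (25, 6), (35, 9), (45, 11),
    (50, 9), (55, 0), (60, -15), (64, -13), (68, -7), (72, -2), (78, 2),
    (85, 3), (92, 2), (100, 0),
]

_TEMPLATES = {"hip": (HIP_WAYPOINTS, 4), "knee": (KNEE_WAYPOINTS, 5),
              "ankle": (ANKLE_WAYPOINTS, 6)}

#: stride length as a fraction of height at 1.25 m/s free walking
STRIDE_LENGTH_FRACTION = 0.79
#: ankle-joint height above the ground as a fraction of body height
ANKLE_HEIGHT_FRACTION = 0.039


def _fourier_fit(waypoints, n_harmonics: int) -> np.ndarray:
    """Least-squares Fourier coefficients [c0, a1, b1, ...] from waypoints."""
    pts = np.asarray(waypoints, dtype=float)
    s = pts[:, 0] / 100.0
    cols = [np.ones_like(s)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.cos(2 * np.pi * k * s))
        cols.append(np.sin(2 * np.pi * k * s))
    A = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(A, pts[:, 1], rcond=None)
    return coef


def _fourier_eval(coef: np.ndarray, s: np.ndarray) -> np.ndarray:
    out = np.full_like(s, coef[0], dtype=float)
    n_harm = (len(coef) - 1) // 2
    for k in range(1, n_harm + 1):
        out += coef[2 * k - 1] * np.cos(2 * np.pi * k * s)
        out += coef[2 * k] * np.sin(2 * np.pi * k * s)
    return out


@dataclass
class GaitParams:
    """Parameters of the synthetic gait generator.

    ``amp_scale`` multiplies each joint template's deviation from its cycle
    mean; ``phase_shift`` is a whole-cycle phase offset (cycle fraction).
    ``grf_bump`` sets the depth of the mid-stance valley via the
    third-harmonic coefficient of the vertical GRF shape.
    """

    amp_scale: dict = field(default_factory=lambda: {"hip": 1.0, "knee": 1.0,
                                                     "ankle": 1.0})
    phase_shift: float = 0.0
    stance_fraction: float = 0.60
    grf_bump: float = 0.25
    grf_ap_scale: float = 0.16
    pelvis_osc: float = 0.012
    marker_noise_sd: float = 0.002
    walking_speed: float = 1.25
    n_frames: int = 101
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        for j, a in self.amp_scale.items():
            if a < 0 or a > 2.0:
                raise ValueError(f"amp_scale[{j}] outside plausible range")

    @classmethod
    def subject_variant(cls, seed: int, **overrides) -> "GaitParams":
        """Seeded per-subject variation of the default template (±3% amps)."""
        rng = np.random.default_rng(seed)
        amp = {j: float(rng.normal(1.0, 0.03)) for j in ("hip", "knee", "ankle")}
        phase = float(rng.normal(0.0, 0.005))
        bump = float(np.clip(rng.normal(0.25, 0.02), 0.1, 0.4))
        return cls(amp_scale=amp, phase_shift=phase, grf_bump=bump,
                   seed=seed, **overrides)


@dataclass
class GaitCycle:
    """One (possibly averaged) time-normalized stride.

    ``angles`` maps each generalized coordinate to a length-``n_frames``
    series (frame 0 = frame 100% by construction for generated cycles).
    ``grf`` maps side → {"f": (n, 2) force N, "cop": (n, 2) m}; forces are
    zero outside stance.  ``markers`` maps marker name → (n, 2) m.
    """

    n_frames: int
    cycle_duration: float
    walking_speed: float
    stance_fraction: float
    angles: dict
    grf: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")

    @property
    def percent(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.n_frames)

    @property
    def s(self) -> np.ndarray:
        """Normalized cycle coordinate in [0, 1]."""
        return np.linspace(0.0, 1.0, self.n_frames)

    @property
    def stance_mask(self) -> np.ndarray:
        return self.s <= self.stance_fraction + 1e-12

    def copy(self) -> "GaitCycle":
        return GaitCycle(
            self.n_frames, self.cycle_duration, self.walking_speed,
            self.stance_fraction,
            {k: v.copy() for k, v in self.angles.items()},
            {side: {k: v.copy() for k, v in d.items()}
             for side, d in self.grf.items()},
            {k: v.copy() for k, v in self.markers.items()})


def generate_joint_angles(params: GaitParams, model: LowerLimbModel) -> GaitCycle:
    """Generate the periodic joint-angle trajectories for one stride.

    Hip/knee/ankle series come from the Fourier waypoint templates with the
    per-joint amplitude scaling and phase shift in ``params``; pelvis
    translation advances at the walking speed with a small double-bump
    vertical oscillation.  Deterministic given ``params``.
    """
    n = params.n_frames
    s = np.linspace(0.0, 1.0, n)
    se = np.mod(s - params.phase_shift, 1.0)

    angles: dict[str, np.ndarray] = {}
    for joint, (wps, nh) in _TEMPLATES.items():
        coef = _fourier_fit(wps, nh)
        base = _fourier_eval(coef, se)
        scaled = coef[0] + params.amp_scale[joint] * (base - coef[0])
        series = np.deg2rad(scaled)
        lo, hi = model.joints[joint].limits
        if series.min() < lo or series.max() > hi:
            raise ValueError(
                f"{joint} trajectory exceeds joint limits "
                f"[{lo:.2f}, {hi:.2f}] rad")
        angles[joint] = series

    T = STRIDE_LENGTH_FRACTION * model.height / params.walking_speed
    hip_y = (model.segments["thigh"].length + model.segments["shank"].length
             + ANKLE_HEIGHT_FRACTION * model.height)
    angles["pelvis_x"] = params.walking_speed * T * s
    angles["pelvis_y"] = hip_y + params.pelvis_osc * np.cos(
        4 * np.pi * (s - 0.07))
    angles["pelvis_tilt"] = 0.02 * np.sin(2 * np.pi * s + 0.3)

    return GaitCycle(n_frames=n, cycle_duration=T,
                     walking_speed=params.walking_speed,
                     stance_fraction=params.stance_fraction, angles=angles)


def generate_grf(cycle: GaitCycle, body_mass: float, added_mass: float = 0.0,
                 grf_bump: float = 0.25, ap_scale: float = 0.16,
                 model: LowerLimbModel | None = None) -> GaitCycle:
    """Attach double-bump ground reaction forces to a gait cycle.

    The vertical force acts during stance only and is scaled so the
    stride-averaged vertical force over both limbs equals the supported
    weight exactly.  ``added_mass`` defaults to 0: by assumption the device
    mass is *not* reflected in the GRFs, so comparisons across device
    configurations share identical external loads.  The centre of pressure
    progresses heel → toe along the foot; if ``model`` is given the CoP is
    placed on the moving foot, otherwise on a fixed forward line.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be > 0")
    out = cycle.copy()
    n = cycle.n_frames
    s = cycle.s
    sf = cycle.stance_fraction
    stance = cycle.stance_mask
    u = np.where(stance, s / sf, 0.0)  # normalized stance time in [0, 1]

    shape = np.where(stance, np.sin(np.pi * u) + grf_bump * np.sin(3 * np.pi * u),
                     0.0)
    shape = np.clip(shape, 0.0, None)
    weight = (body_mass + added_mass) * GRAVITY
    # both-limb stride average = weight: the left leg mirrors the right at a
    # half-cycle shift, so one leg must average weight/2 over the stride
    mean_one_leg = np.trapezoid(shape, s) / (s[-1] - s[0])
    fy = shape * (0.5 * weight / mean_one_leg)
    fx = np.where(stance, -ap_scale * weight * np.sin(2 * np.pi * u), 0.0)

    if model is not None:
        # CoP on the ground plane, progressing monotonically from the heel
        # contact point to the toe-off point of the planted foot
        from ._fk import ChainKinematics
        foot_len = model.segments["foot"].length
        ck = ChainKinematics(model, cycle.angles)
        heel = ck.point("foot", -0.25 * foot_len, -0.02)[0]
        toe = ck.point("foot", foot_len, -0.02)[0]
        i_off = int(np.searchsorted(s, sf, side="right")) - 1
        x_heel, x_toe = heel[0, 0], toe[i_off, 0]
        ground_y = 0.5 * (heel[0, 1] + toe[i_off, 1])
        cop = np.stack([x_heel + (x_toe - x_heel) * u,
                        np.full(n, ground_y)], axis=-1)
    else:
        x0 = cycle.angles["pelvis_x"]
        cop = np.stack([x0 + 0.2 * (u - 0.3), np.zeros(n)], axis=-1)
    cop = np.where(stance[:, None], cop, 0.0)

    f_right = np.stack([fx, fy], axis=-1)
    out.grf["right"] = {"f": f_right, "cop": cop}

    # left leg: same pattern advanced half a cycle (periodic roll on the
    # 100-interval grid; frame n-1 duplicates frame 0)
    half = (n - 1) // 2
    f_left = np.roll(f_right[:-1], half, axis=0)
    cop_left = np.roll(cop[:-1], half, axis=0)
    stride_len = cycle.walking_speed * cycle.cycle_duration
    cop_left = np.where(np.any(f_left != 0, axis=1)[:, None],
                        cop_left - np.array([stride_len / 2, 0.0]), 0.0)
    out.grf["left"] = {"f": np.vstack([f_left, f_left[:1]]),
                       "cop": np.vstack([cop_left, cop_left[:1]])}
    return out


def forward_markers(model: LowerLimbModel, cycle: GaitCycle,
                    noise_sd: float = 0.0, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> dict:
    """Marker trajectories from planar forward kinematics plus i.i.d. noise.

    Returns marker name → (n_frames, 2) array and stores it on the cycle.
    ``noise_sd`` is the per-coordinate Gaussian SD in metres.
    """
    names = list(model.markers)
    arr = marker_array(model, cycle.angles, names)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        arr = arr + rng.normal(0.0, noise_sd, size=arr.shape)
    markers = {nm: arr[:, i, :] for i, nm in enumerate(names)}
    cycle.markers = markers
    return markers


def average_cycles(cycles: list[GaitCycle]) -> GaitCycle:
    """Frame-wise arithmetic mean of angles, GRFs and markers.

    All cycles must share the frame count.  This is the averaging that
    turns a set of consecutive treadmill strides into one representative
    stride per subject.
    """
    if not cycles:
        raise ValueError("need at least one cycle to average")
    n = cycles[0].n_frames
    if any(c.n_frames != n for c in cycles):
        raise ValueError("all cycles must have the same n_frames")

    def _mean(extract):
        return np.mean([np.asarray(extract(c), dtype=float) for c in cycles],
                       axis=0)

    angles = {k: _mean(lambda c, k=k: c.angles[k]) for k in cycles[0].angles}
    grf = {}
    for side in cycles[0].grf:
        grf[side] = {k: _mean(lambda c, k=k, side=side: c.grf[side][k])
                     for k in cycles[0].grf[side]}
    markers = {}
    if cycles[0].markers and all(c.markers.keys() == cycles[0].markers.keys()
                                 for c in cycles):
        markers = {k: _mean(lambda c, k=k: c.markers[k])
                   for k in cycles[0].markers}
    return GaitCycle(
        n_frames=n,
        cycle_duration=float(np.mean([c.cycle_duration for c in cycles])),
        walking_speed=float(np.mean([c.walking_speed for c in cycles])),
        stance_fraction=float(np.mean([c.stance_fraction for c in cycles])),
        angles=angles, grf=grf, markers=markers)


def generate_averaged_gait(model: LowerLimbModel, params: GaitParams,
                           n_cycles: int = 31) -> GaitCycle:
    """Representative stride: average of ``n_cycles`` jittered strides.

    Each stride perturbs the subject's template with small seeded
    cycle-to-cycle amplitude jitter (±2% of each joint's amplitude, ±3% on
    the GRF magnitude), emulating natural stride-to-stride variability
    before averaging.
    """
    rng = np.random.default_rng(params.seed)
    cycles = []
    for _ in range(n_cycles):
        amp = {j: a * float(rng.normal(1.0, 0.02))
               for j, a in params.amp_scale.items()}
        p = replace(params, amp_scale=amp)
        c = generate_joint_angles(p, model)
        grf_scale = float(rng.normal(1.0, 0.03))
        c = generate_grf(c, model.body_mass * grf_scale,
                         grf_bump=params.grf_bump,
                         ap_scale=params.grf_ap_scale, model=model)
        cycles.append(c)
    return average_cycles(cycles)
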