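"""Sagittal-plane inverse dynamics: net joint moments from motion and GRFs.

Given joint-angle series, their time derivatives and the ground reaction
force under the stance foot, a recursive Newton–Euler pass over
foot → shank → thigh yields the net internal moments at the ankle, knee
and hip.  Segment inertial properties may include orthosis composite
terms; by design the GRFs are *not* augmented with the device weight, so
all device configurations are compared under identical external loads.

Internal moments are reported in each joint's positive convention:
flexion-positive at hip and knee, dorsiflexion-positive at the ankle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from ._fk import COORD_NAMES, JOINT_NAMES, ChainKinematics
from .msk_model import GRAVITY, LowerLimbModel

_G = np.array([0.0, -GRAVITY])


@dataclass
class KinematicDerivatives:
    """First and second time derivatives of the coordinate series."""

    velocity: dict                    # coordinate -> (n,) rad/s or m/s
    acceleration: dict                # coordinate -> (n,) rad/s^2 or m/s^2
    cycle_duration: float
    smoothing_cutoff: float | None = None


@dataclass
class JointMomentSeries:
    """Net internal joint moments over the 0–100% cycle grid."""

    moments: dict                     # joint -> (n,) N·m (or N·m/kg)
    percent: np.ndarray
    normalized: bool = False
    body_mass: float | None = None

    @property
    def n_frames(self) -> int:
        return len(self.percent)

    def normalize_to_body_mass(self, body_mass: float) -> "JointMomentSeries":
        if self.normalized:
            raise ValueError("moment series is already body-mass normalized")
        if body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        return JointMomentSeries(
            {j: m / body_mass for j, m in self.moments.items()},
            self.percent.copy(), normalized=True, body_mass=body_mass)


def differentiate(angles: dict, cycle_duration: float,
                  smoothing_cutoff: float | None = 6.0) -> KinematicDerivatives:
    """Zero-phase low-pass filter then central differences, periodic wrap.

    The series live on a 0–100% grid whose last frame repeats the first;
    differentiation treats them as periodic with period ``cycle_duration``.
    A linear trend (e.g. forward pelvis travel) is removed before the
    periodic treatment and its constant rate added back to the velocity.
    ``smoothing_cutoff`` is in Hz on the implied time grid (None disables
    filtering) and must be below the Nyquist frequency.
    """
    n = len(next(iter(angles.values())))
    if n < 5:
        raise ValueError("need at least 5 frames to differentiate")
    if cycle_duration <= 0:
        raise ValueError("cycle_duration must be > 0")
    m = n - 1                       # independent samples per period
    h = cycle_duration / m
    fs = 1.0 / h
    if smoothing_cutoff is not None and smoothing_cutoff >= fs / 2:
        raise ValueError("smoothing cutoff must be below Nyquist")
    sos = (signal.butter(4, smoothing_cutoff / (fs / 2), output="sos")
           if smoothing_cutoff is not None else None)

    vel, acc = {}, {}
    for key, series in angles.items():
        x = np.asarray(series, dtype=float)
        slope = (x[-1] - x[0]) / cycle_duration
        t = np.arange(n) * h
        xp = (x - slope * t)[:m]    # periodic remainder
        if sos is not None:
            ext = np.tile(xp, 3)
            xp = signal.sosfiltfilt(sos, ext)[m:2 * m]
        xplus = np.roll(xp, -1)
        xminus = np.roll(xp, 1)
        v = (xplus - xminus) / (2 * h) + slope
        a = (xplus - 2 * xp + xminus) / h ** 2
        vel[key] = np.append(v, v[0])
        acc[key] = np.append(a, a[0])
    return KinematicDerivatives(vel, acc, cycle_duration, smoothing_cutoff)


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the planar cross product, vectorized over frames."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def inverse_dynamics(model: LowerLimbModel, angles: dict,
                     derivatives: KinematicDerivatives,
                     grf: dict | None = None) -> JointMomentSeries:
    """Recursive Newton–Euler over foot → shank → thigh.

    ``angles`` holds all six coordinate series; ``grf`` is
    ``{"f": (n, 2) N, "cop": (n, 2) m}`` for the modelled (right) foot, or
    None for a fully unloaded limb.  Returns net internal moments at
    ankle, knee and hip in their sign conventions.
    """
    n = len(angles["hip"])
    for k in COORD_NAMES:
        if len(angles[k]) != n or len(derivatives.velocity[k]) != n:
            raise ValueError("angle and derivative grids must match")
    if grf is not None:
        f_ext = np.asarray(grf["f"], dtype=float)
        cop = np.asarray(grf["cop"], dtype=float)
        if f_ext.shape != (n, 2):
            raise ValueError("GRF grid does not match the kinematic grid")
    else:
        f_ext = np.zeros((n, 2))
        cop = np.zeros((n, 2))

    ck = ChainKinematics(model, angles, derivatives.velocity,
                         derivatives.acceleration)

    # proximal joint of each segment in the backward recursion
    prox_joint = {"foot": "ankle", "shank": "knee", "thigh": "hip"}
    F_dist = np.zeros((n, 2))        # force on current segment from distal
    M_dist = np.zeros(n)
    moments_z: dict[str, np.ndarray] = {}
    for segname in ("foot", "shank", "thigh"):
        seg = model.segments[segname]
        com_p, _, com_a = ck.com(segname)
        alpha = ck.phidd[segname]
        jpos = ck.joint_position(prox_joint[segname])
        ext_f = f_ext if segname == "foot" else np.zeros((n, 2))
        ext_p = cop if segname == "foot" else com_p
        # force balance: F_prox + F_dist + m g + F_ext = m a
        F_prox = seg.mass * (com_a - _G) - F_dist - ext_f
        # moment balance about the CoM
        M_prox = (seg.inertia_com * alpha - M_dist
                  - _cross2(jpos - com_p, F_prox)
                  - _cross2(ext_p - com_p, ext_f))
        if segname != "foot":
            M_prox -= _cross2(ck.joint_position(
                {"shank": "ankle", "thigh": "knee"}[segname]) - com_p, F_dist)
        moments_z[prox_joint[segname]] = M_prox
        F_dist, M_dist = -F_prox, -M_prox

    moments = {j: model.joints[j].sign * moments_z[j] for j in JOINT_NAMES}
    percent = np.linspace(0.0, 100.0, n)
    return JointMomentSeries(moments=moments, percent=percent)


def peak_moments(series: JointMomentSeries) -> dict:
    """Signed extrema per joint: (peak positive-direction, peak negative).

    In the flexion/dorsiflexion-positive convention the "flexion peak" is
    the signed maximum and the "extension peak" the signed minimum; for an
    all-positive series the extension peak is therefore the smallest
    positive value rather than a negative number.
    """
    if not series.moments or series.n_frames == 0:
        raise ValueError("empty moment series")
    return {j: (float(np.max(m)), float(np.min(m)))
            for j, m in series.moments.items()}
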