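"""Planar forward kinematics of the pelvis–thigh–shank–foot chain.

Generalized coordinates per frame:

==========  =====================================================
pelvis_x    hip-joint x position (m); the pelvis frame's origin
pelvis_y    hip-joint y position (m)
pelvis_tilt pelvis orientation (rad, CCW in the x-forward/y-up view)
hip         hip flexion (rad, flexion positive)
knee        knee flexion (rad, flexion positive)
ankle       ankle dorsiflexion (rad, dorsiflexion positive)
==========  =====================================================

Segment CCW orientation angles follow from the joint sign conventions:
thigh = pelvis_tilt + hip, shank = thigh − knee, foot = shank + ankle.
The thigh/shank long axis points distally (straight down at zero angle);
the foot axis points from the ankle toward the toes (forward at zero).
Points fixed in a segment are located by an (along-axis, normal) pair, and
their velocities/accelerations are evaluated analytically from the joint
derivative series.
"""

from __future__ import annotations

import numpy as np

from .msk_model import LowerLimbModel

COORD_NAMES = ("pelvis_x", "pelvis_y", "pelvis_tilt", "hip", "knee", "ankle")
JOINT_NAMES = ("hip", "knee", "ankle")


def segment_angles(q: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """CCW orientation series of each segment from generalized coordinates.

    Works for angles, angular velocities or accelerations alike because the
    relations are linear.
    """
    tilt = np.asarray(q["pelvis_tilt"], dtype=float)
    thigh = tilt + np.asarray(q["hip"], dtype=float)
    shank = thigh - np.asarray(q["knee"], dtype=float)
    foot = shank + np.asarray(q["ankle"], dtype=float)
    return {"pelvis": tilt, "thigh": thigh, "shank": shank, "foot": foot}


def _axis_pair(segment: str, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit long-axis U and its derivative N = dU/dphi, stacked (n, 2).

    For thigh and shank the axis points down at phi = 0; for pelvis and
    foot it points forward.  In both cases dN/dphi = -U, so downstream
    algebra is uniform.
    """
    c, s = np.cos(phi), np.sin(phi)
    if segment in ("thigh", "shank"):
        U = np.stack([s, -c], axis=-1)
        N = np.stack([c, s], axis=-1)
    else:  # pelvis, foot
        U = np.stack([c, s], axis=-1)
        N = np.stack([-s, c], axis=-1)
    return U, N


class ChainKinematics:
    """Pose (and optionally velocity/acceleration) of every segment.

    ``q`` maps coordinate name → series; ``qd``/``qdd`` are optional first
    and second time derivatives on the same grid.  All outputs are arrays
    shaped (n_frames, 2) for points and (n_frames,) for angles.
    """

    def __init__(self, model: LowerLimbModel, q: dict[str, np.ndarray],
                 qd: dict[str, np.ndarray] | None = None,
                 qdd: dict[str, np.ndarray] | None = None):
        self.model = model
        self.q = {k: np.atleast_1d(np.asarray(q[k], dtype=float))
                  for k in COORD_NAMES}
        self.n = len(self.q["hip"])
        self.phi = segment_angles(self.q)
        self.phid = segment_angles(qd) if qd is not None else None
        self.phidd = segment_angles(qdd) if qdd is not None else None
        self._qd, self._qdd = qd, qdd
        self._origins = self._chain_origins()

    def _chain_origins(self):
        zero = np.zeros((self.n, 2))
        pos = {"pelvis": np.stack([self.q["pelvis_x"], self.q["pelvis_y"]],
                                  axis=-1)}
        vel = {"pelvis": zero if self._qd is None else np.stack(
            [np.atleast_1d(self._qd["pelvis_x"]),
             np.atleast_1d(self._qd["pelvis_y"])], axis=-1)}
        acc = {"pelvis": zero if self._qdd is None else np.stack(
            [np.atleast_1d(self._qdd["pelvis_x"]),
             np.atleast_1d(self._qdd["pelvis_y"])], axis=-1)}
        # thigh origin (hip joint) coincides with the pelvis origin
        pos["thigh"], vel["thigh"], acc["thigh"] = (
            pos["pelvis"], vel["pelvis"], acc["pelvis"])
        for parent, child in (("thigh", "shank"), ("shank", "foot")):
            L = self.model.segments[parent].length
            p, v, a = self._point_from(parent, pos[parent], vel[parent],
                                       acc[parent], L, 0.0)
            pos[child], vel[child], acc[child] = p, v, a
        return pos, vel, acc

    def _point_from(self, segment, base_p, base_v, base_a, along, perp):
        phi = self.phi[segment]
        U, N = _axis_pair(segment, phi)
        r = along * U + perp * N           # point minus segment origin
        dr = along * N - perp * U          # d r / d phi
        p = base_p + r
        if self.phid is None:
            return p, None, None
        w = self.phid[segment][:, None]
        v = base_v + w * dr
        if self.phidd is None:
            return p, v, None
        al = self.phidd[segment][:, None]
        a = base_a + al * dr - w ** 2 * r
        return p, v, a

    def point(self, segment: str, along: float, perp: float = 0.0):
        """Position/velocity/acceleration of a segment-fixed point."""
        pos, vel, acc = self._origins
        return self._point_from(segment, pos[segment], vel[segment],
                                acc[segment], along, perp)

    def origin(self, segment: str):
        pos, vel, acc = self._origins
        return pos[segment], vel[segment], acc[segment]

    def joint_position(self, joint: str) -> np.ndarray:
        child = {"hip": "thigh", "knee": "shank", "ankle": "foot"}[joint]
        return self._origins[0][child]

    def com(self, segment: str):
        seg = self.model.segments[segment]
        return self.point(segment, seg.com_offset, seg.com_perp)

    def marker_positions(self) -> dict[str, np.ndarray]:
        out = {}
        for name, (seg, along, perp) in self.model.markers.items():
            out[name] = self.point(seg, along, perp)[0]
        return out


def marker_array(model: LowerLimbModel, q: dict[str, np.ndarray],
                 names: list[str] | None = None) -> np.ndarray:
    """Marker positions stacked (n_frames, n_markers, 2) in ``names`` order."""
    ck = ChainKinematics(model, q)
    names = names if names is not None else list(model.markers)
    pos = ck.marker_positions()
    return np.stack([pos[n] for n in names], axis=1)
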