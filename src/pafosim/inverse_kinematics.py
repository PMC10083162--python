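"""Per-frame weighted least-squares inverse kinematics.

Recovers the six planar generalized coordinates (pelvis translation and
tilt plus hip/knee/ankle angles) from marker trajectories by minimizing
the weighted squared marker residual frame by frame with a damped
Gauss–Newton (Levenberg) iteration, warm-started from the previous frame.
Including the pelvis position/orientation as free coordinates lets a rigid
translation of all markers be absorbed by the pelvis, leaving joint angles
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fk import COORD_NAMES, marker_array
from .msk_model import LowerLimbModel

_N_COORDS = len(COORD_NAMES)


@dataclass
class IKResult:
    """Recovered coordinates plus per-frame diagnostics."""

    angles: dict                      # coordinate name -> (n_frames,) rad / m
    rms: np.ndarray                   # per-frame weighted marker RMS (m)
    converged: np.ndarray             # per-frame bool
    iterations: np.ndarray            # per-frame iteration counts
    marker_names: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.rms)


def _residual(model: LowerLimbModel, q: np.ndarray, obs: np.ndarray,
              names: list[str], w: np.ndarray) -> np.ndarray:
    """Weighted stacked residual for one frame; q in COORD_NAMES order."""
    qd = {k: np.array([q[i]]) for i, k in enumerate(COORD_NAMES)}
    pred = marker_array(model, qd, names)[0]
    return (w[:, None] * (pred - obs)).ravel()


def solve_ik(markers: dict, model: LowerLimbModel,
             weights: dict | None = None,
             init: np.ndarray | None = None,
             max_iter: int = 100, tol: float = 1e-10,
             fd_step: float = 1e-7) -> IKResult:
    """Solve marker-based IK for every frame.

    ``markers`` maps marker name → (n_frames, 2) observed positions; names
    must exist in the model's marker set.  ``weights`` are per-marker
    non-negative weights (default equal).  Each frame minimizes
    Σᵢ wᵢ ‖mᵢ_obs − mᵢ_model(q)‖² by damped Gauss–Newton with a numerical
    Jacobian, warm-started from the previous frame's solution; convergence
    is declared when the objective decrease falls below ``tol``
    (absolute, m²) or the objective is at numerical zero.

    Raises ``ValueError`` if fewer independent marker coordinates than
    free coordinates are supplied (rank-deficient problem).
    """
    names = [n for n in markers if n in model.markers]
    if len(names) < len(markers):
        unknown = set(markers) - set(names)
        raise ValueError(f"markers not in model: {sorted(unknown)}")
    w = np.array([1.0 if weights is None else float(weights.get(n, 0.0))
                  for n in names])
    if np.any(w < 0):
        raise ValueError("marker weights must be >= 0")
    n_active = int(np.sum(w > 0))
    if 2 * n_active < _N_COORDS:
        raise ValueError(
            f"need >= {_N_COORDS} weighted marker coordinates, "
            f"have {2 * n_active}")
    sw = np.sqrt(w)

    obs = np.stack([np.asarray(markers[n], dtype=float) for n in names],
                   axis=1)  # (n_frames, n_markers, 2)
    n_frames = obs.shape[0]

    if init is None:
        q = np.zeros(_N_COORDS)
        # crude pelvis initialization from the first weighted marker
        q[0], q[1] = obs[0, np.argmax(w)] if n_active else (0.0, 0.0)
    else:
        q = np.asarray(init, dtype=float).copy()

    out = {k: np.empty(n_frames) for k in COORD_NAMES}
    rms = np.empty(n_frames)
    conv = np.zeros(n_frames, dtype=bool)
    iters = np.zeros(n_frames, dtype=int)
    wsum = np.sum(w) * 2  # number of weighted scalar residuals

    for f in range(n_frames):
        target = obs[f]
        r = _residual(model, q, target, names, sw)
        obj = float(r @ r)
        lam = 1e-6
        it = 0
        for it in range(1, max_iter + 1):
            # forward-difference Jacobian of the weighted residual
            J = np.empty((r.size, _N_COORDS))
            for j in range(_N_COORDS):
                qp = q.copy()
                qp[j] += fd_step
                J[:, j] = (_residual(model, qp, target, names, sw) - r) / fd_step
            accepted = False
            for _ in range(25):
                H = J.T @ J + lam * np.eye(_N_COORDS)
                step = np.linalg.solve(H, -J.T @ r)
                r_new = _residual(model, q + step, target, names, sw)
                obj_new = float(r_new @ r_new)
                if obj_new <= obj:  # damped: accept only non-increase
                    q = q + step
                    accepted = True
                    lam = max(lam / 3.0, 1e-12)
                    break
                lam *= 10.0
            if not accepted:
                break
            decrease = obj - obj_new
            r, obj = r_new, obj_new
            if obj < 1e-24 or decrease < tol:
                conv[f] = True
                break
        iters[f] = it
        rms[f] = np.sqrt(obj / wsum) if wsum > 0 else 0.0
        for i, k in enumerate(COORD_NAMES):
            out[k][f] = q[i]
        # warm start next frame from this solution

    # clamp joint angles into their limits (keeps results physical when
    # noise pushes a frame marginally outside)
    for jname, joint in model.joints.items():
        out[jname] = np.clip(out[jname], *joint.limits)
    return IKResult(angles=out, rms=rms, converged=conv, iterations=iters,
                    marker_names=names)
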