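"""Muscle-redundancy resolution by per-frame activation-squared minimization.

Each frame solves the strictly convex program

    min  Σ_m a_m²  +  (τ_res / τ_opt)²
    s.t. Σ_m a_m · Fmax_m · fl_m · fv_m · r_mj  +  δ_{j,ankle} · τ_res = τ_j
         0 ≤ a_m ≤ 1,   τ_res ≥ 0

where τ_j are the net joint moments from inverse dynamics and the
force–length (Gaussian) and force–velocity (linear clamp) factors are
frozen at the frame's kinematic state — the standard static-optimization
linearization with a rigid tendon and no passive element.

The reserve actuator is an ideal dorsiflexion-only torque source at the
ankle.  With its optimal torque set to 1 MN·m its cost contribution is
negligible, so whenever it is enabled it absorbs dorsiflexion demand at
essentially zero cost — simultaneously modelling paralyzed dorsiflexors
(foot drop) and ideal orthosis assistance.  Plantarflexion demand is never
met by the reserve (non-negativity).

The per-frame QP is solved by a small active-set method specialized to
this bounded minimum-norm structure; infeasible frames (moments
unreachable with bounded activations) are flagged with their moment
deficit rather than silently absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fk import JOINT_NAMES
from .msk_model import LowerLimbModel, Muscle, PAFOConfig, Situation
from .inverse_dynamics import JointMomentSeries, KinematicDerivatives

FL_WIDTH = 0.45          # Gaussian active force-length width (norm. lengths)
FV_ECC_CAP = 1.4         # eccentric force-velocity plateau
DEFAULT_OPTIMAL_TORQUE = 1.0e6   # N·m; makes the reserve cost negligible


@dataclass
class ReserveActuator:
    """Ideal dorsiflexion-only ankle torque with a huge optimal torque."""

    joint: str = "ankle"
    optimal_torque: float = DEFAULT_OPTIMAL_TORQUE

    def __post_init__(self) -> None:
        if self.optimal_torque <= 0:
            raise ValueError("optimal_torque must be > 0")


def force_length(l_norm: np.ndarray) -> np.ndarray:
    """Gaussian active force-length factor, fl(1) = 1."""
    return np.exp(-(((np.asarray(l_norm) - 1.0) / FL_WIDTH) ** 2))


def force_velocity(v_norm: np.ndarray) -> np.ndarray:
    """Linear force-velocity factor of normalized fiber velocity.

    ``v_norm`` is dl/dt in optimal lengths per second divided by the
    muscle's maximum contraction velocity, negative when shortening;
    fv(0) = 1, fv = 0 at maximum shortening velocity, eccentric plateau
    at ``FV_ECC_CAP``.
    """
    return np.clip(1.0 + np.asarray(v_norm), 0.0, FV_ECC_CAP)


def hill_force(muscle: Muscle, activation: float, fiber_length: float,
               fiber_velocity: float) -> float:
    """Musculotendon force F = a · Fmax · fl(l̃) · fv(ṽ), rigid tendon.

    ``fiber_length`` in m, ``fiber_velocity`` in m/s (negative when
    shortening).
    """
    if not 0.0 <= activation <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    l_norm = fiber_length / muscle.optimal_fiber_length
    v_norm = fiber_velocity / (muscle.max_contraction_velocity
                               * muscle.optimal_fiber_length)
    return float(activation * muscle.max_isometric_force
                 * force_length(l_norm) * force_velocity(v_norm))


@dataclass
class MuscleState:
    """Fiber lengths/velocities per muscle per frame (rigid tendon).

    With constant moment arms, fiber length is the optimal length minus the
    moment-arm-weighted joint excursion from the model's reference pose:
    l = l₀ − Σ_j r_j (q_j − q_ref_j), so a muscle shortens when a joint
    moves in the direction it acts.
    """

    muscle_names: list
    fiber_length: np.ndarray      # (n_frames, n_muscles) m
    fiber_velocity: np.ndarray    # (n_frames, n_muscles) m/s

    def __post_init__(self) -> None:
        if np.any(self.fiber_length <= 0):
            raise ValueError("fiber lengths must be > 0")


def compute_muscle_states(model: LowerLimbModel, angles: dict,
                          derivatives: KinematicDerivatives) -> MuscleState:
    n = len(angles["hip"])
    names = [m.name for m in model.muscles]
    L = np.empty((n, len(names)))
    V = np.empty((n, len(names)))
    for i, mus in enumerate(model.muscles):
        dl = np.zeros(n)
        dv = np.zeros(n)
        for jname in mus.moment_arms:
            q = np.asarray(angles[jname], dtype=float)
            r = np.array([mus.moment_arm(jname, qk) for qk in q]) \
                if callable(mus.moment_arms[jname]) \
                else mus.moment_arm(jname) * np.ones(n)
            dl += r * (q - model.reference_pose.get(jname, 0.0))
            dv += r * np.asarray(derivatives.velocity[jname], dtype=float)
        L[:, i] = np.maximum(mus.optimal_fiber_length - dl,
                             0.05 * mus.optimal_fiber_length)
        V[:, i] = -dv
    return MuscleState(names, L, V)


@dataclass
class MuscleForceSeries:
    """Per-muscle activations and forces plus the reserve torque."""

    muscle_names: list
    activations: np.ndarray       # (n_frames, n_muscles) in [0, 1]
    forces: np.ndarray            # (n_frames, n_muscles) N (or N/kg)
    reserve: np.ndarray           # (n_frames,) N·m (or N·m/kg), >= 0
    percent: np.ndarray
    feasible: np.ndarray          # (n_frames,) bool
    deficit: np.ndarray           # (n_frames, 3) unmet moment per joint
    normalized: bool = False
    body_mass: float | None = None

    def force(self, muscle: str) -> np.ndarray:
        return self.forces[:, self.muscle_names.index(muscle)]

    def activation(self, muscle: str) -> np.ndarray:
        return self.activations[:, self.muscle_names.index(muscle)]

    def normalize_to_body_mass(self, body_mass: float) -> "MuscleForceSeries":
        if self.normalized:
            raise ValueError("force series is already body-mass normalized")
        if body_mass <= 0:
            raise ValueError("body_mass must be > 0")
        return MuscleForceSeries(
            list(self.muscle_names), self.activations.copy(),
            self.forces / body_mass, self.reserve / body_mass,
            self.percent.copy(), self.feasible.copy(), self.deficit.copy(),
            normalized=True, body_mass=body_mass)


def _refined_solve(J: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """lstsq plus iterative refinement (the 1 MN·m reserve column makes
    these little systems conditioned ~1e8-1e12; refinement recovers the
    lost digits cheaply)."""
    sol, *_ = np.linalg.lstsq(J, rhs, rcond=None)
    for _ in range(2):
        dsol, *_ = np.linalg.lstsq(J, rhs - J @ sol, rcond=None)
        sol = sol + dsol
    return sol


def _dykstra_projection(A, b, lo, up, max_iter=200_000, tol=1e-12):
    """Project the origin onto {x: A x = b} ∩ box by Dykstra's alternating
    projections.  Guaranteed convergent; used as a rare fallback."""
    pinv = np.linalg.pinv(A)

    def proj_affine(z):
        return z - pinv @ (A @ z - b)

    x = proj_affine(np.zeros(A.shape[1]))
    p = np.zeros_like(x)
    q = np.zeros_like(x)
    for _ in range(max_iter):
        y = np.clip(x + p, lo, up)
        p = x + p - y
        x_new = proj_affine(y + q)
        q = y + q - x_new
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return np.clip(x, lo, up)


def solve_box_min_norm(A: np.ndarray, b: np.ndarray, lo: np.ndarray,
                       up: np.ndarray, weights: np.ndarray | None = None,
                       tol: float = 1e-10, max_iter: int = 100):
    """min Σ w_i x_i² subject to A x = b and lo ≤ x ≤ up.

    Strictly convex (w > 0), so the solution is unique.  Solved by
    semismooth Newton on the dual: the inner minimizer is the closed form
    x(λ) = clip(Aᵀλ / 2, lo, up), and the dual stationarity condition
    A x(λ) = b is a piecewise-linear system in the few (≤ 3 here) joint
    multipliers.  Infeasible systems (moments unreachable within bounds)
    are detected with a bounded least-squares probe.

    Returns ``(x, feasible, residual)`` where ``residual = b − A x``;
    when ``feasible`` is False, x is the closest achievable bounded point
    and the residual is the deficit.
    """
    m, n = A.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    # scale variables so the cost is an unweighted norm: x = y / sqrt(w)
    S = 1.0 / np.sqrt(w)
    As = A * S
    los, ups = lo / S, up / S
    scale_b = max(1.0, float(np.max(np.abs(b))) if b.size else 1.0)

    def y_of(lam):
        return np.clip(As.T @ lam / 2.0, los, ups)

    def dual_value(lam, y):
        # g(λ) = min over the box of (yᵀy − λᵀ(As y − b)); concave in λ
        # with gradient b − As y(λ)
        return float(y @ y - lam @ (As @ y - b))

    lam = np.zeros(m)
    y = y_of(lam)
    F = As @ y - b                 # −∇g
    g = dual_value(lam, y)
    normF = float(np.max(np.abs(F)))
    converged = normF <= tol * scale_b
    for _ in range(max_iter):
        if converged:
            break
        stat = As.T @ lam / 2.0
        # B-subdifferential choice: count boundary points as interior so
        # the Newton model can push them inward
        interior = (stat >= los) & (stat <= ups)
        Ai = As[:, interior]
        J = Ai @ Ai.T / 2.0
        # tiny Tikhonov term keeps J positive definite, so the Newton
        # direction is a strict ascent direction for the concave dual
        J = J + 1e-14 * max(1.0, np.trace(J)) * np.eye(m)
        dlam = _refined_solve(J, -F)
        ascent = float(F @ dlam) * -1.0      # dᵀ∇g = Fᵀ J⁻¹ F > 0
        if ascent <= 0:                       # numerically flat
            break
        # the dual is piecewise quadratic along the step with kinks where
        # a stationary value crosses a bound; evaluate the Newton step,
        # the kinks and midpoints, Armijo-accepting the longest good step
        slope = As.T @ dlam / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_kinks = np.concatenate([(los - stat) / slope,
                                      (ups - stat) / slope])
        t_kinks = t_kinks[np.isfinite(t_kinks)
                          & (t_kinks > 1e-14) & (t_kinks < 1.0)]
        halvings = 1.0 / 2 ** np.arange(1, 20)
        cands = np.unique(np.concatenate(
            [[1.0], t_kinks, (1.0 + t_kinks) / 2, halvings]))[::-1]
        accepted = False
        for t in cands:
            lam_try = lam + t * dlam
            y_try = y_of(lam_try)
            g_try = dual_value(lam_try, y_try)
            if g_try >= g + 1e-4 * t * ascent:
                lam, y, g = lam_try, y_try, g_try
                F = As @ y - b
                normF = float(np.max(np.abs(F)))
                accepted = True
                break
        if not accepted:
            break  # at numerical precision limit of the dual
        converged = normF <= tol * scale_b

    y = y_of(lam)
    if not converged:
        # stalled Newton: either the system is infeasible within the box,
        # or (rarely) the iteration got stuck.  A bounded least-squares
        # probe distinguishes the two.
        from scipy.optimize import lsq_linear
        # column equilibration keeps the probe fast despite the 1e6 column
        D = np.maximum(np.max(np.abs(As), axis=0), 1.0)
        probe = lsq_linear(As / D, b, bounds=(los * D, ups * D), tol=1e-10)
        probe.x = probe.x / D
        probe_norm = float(np.max(np.abs(As @ probe.x - b)))
        if probe_norm <= 1e-6 * scale_b:
            y = _dykstra_projection(As, b, los, ups)   # feasible: project
        else:
            y = probe.x                                 # true deficit
    x = y * S
    resid = b - A @ x
    feasible = bool(np.max(np.abs(resid)) <= 1e-6 * scale_b)
    return x, feasible, resid


def _torque_matrix(model: LowerLimbModel, flfv: np.ndarray,
                   angles: dict | None = None,
                   weak_dorsiflexors: bool = False) -> np.ndarray:
    """Per-frame capacity matrix C[f, j, m] = Fmax·fl·fv·r (N·m at a = 1)."""
    n, nm = flfv.shape
    C = np.zeros((n, len(JOINT_NAMES), nm))
    for i, mus in enumerate(model.muscles):
        fmax = 0.0 if (weak_dorsiflexors and "dorsiflexor" in mus.groups) \
            else mus.max_isometric_force
        for j, jname in enumerate(JOINT_NAMES):
            if not mus.spans(jname):
                continue
            if callable(mus.moment_arms[jname]) and angles is not None:
                r = np.array([mus.moment_arm(jname, qk)
                              for qk in angles[jname]])
            else:
                r = mus.moment_arm(jname)
            C[:, j, i] = fmax * flfv[:, i] * r
    return C


def static_optimization_step(C_frame: np.ndarray, tau: np.ndarray,
                             reserve: ReserveActuator | None = None):
    """Solve one frame given its capacity matrix and net moments.

    ``C_frame`` is (n_joints, n_muscles) of joint torque at full
    activation; ``tau`` the required net moments in joint order.
    Returns ``(activations, reserve_torque, feasible, residual)``.

    With the reserve present its cost (τ/τ_opt)² is vanishingly small at
    τ_opt = 1 MN·m, so the reserve variable is eliminated analytically:
    the ankle equality relaxes to the one-sided constraint
    "muscle ankle torque ≤ demand" and the reserve absorbs the slack.
    For a strictly convex program with a single inequality this two-phase
    solve (relaxed first, equality-pinned if the slack comes out negative)
    is exact in the large-τ_opt limit and keeps every linear system at
    muscle scale.
    """
    nj, nm = C_frame.shape
    lo, up = np.zeros(nm), np.ones(nm)
    if reserve is None:
        a, feasible, resid = solve_box_min_norm(C_frame, tau, lo, up)
        return a, 0.0, feasible, resid

    k = JOINT_NAMES.index(reserve.joint)
    others = [j for j in range(nj) if j != k]
    scale = max(1.0, float(np.max(np.abs(tau))))
    a, ok, resid_o = solve_box_min_norm(C_frame[others], tau[others], lo, up)
    slack = float(tau[k] - C_frame[k] @ a)
    if slack >= -1e-9 * scale:
        resid = np.zeros(nj)
        resid[others] = resid_o
        tau_res = max(slack, 0.0)
        return a, tau_res, ok, resid
    # slack negative: the reserve cannot plantarflex, so the ankle row
    # binds as an equality and the reserve stays at zero
    a, feasible, resid = solve_box_min_norm(C_frame, tau, lo, up)
    return a, 0.0, feasible, resid


def run_static_optimization(model: LowerLimbModel, angles: dict,
                            derivatives: KinematicDerivatives,
                            moments: JointMomentSeries,
                            config: PAFOConfig | None = None,
                            weak_dorsiflexors: bool = False,
                            reserve: ReserveActuator | None = None,
                            ) -> MuscleForceSeries:
    """Distribute the net moments over the muscle set for every frame.

    The reserve actuator participates only in the two actuation
    situations; the foot-drop weakness flag (explicitly zeroing dorsiflexor
    strength) is off by default — the near-free reserve already absorbs
    dorsiflexion demand whenever it is present.
    """
    if moments.normalized:
        raise ValueError("static optimization expects unnormalized moments")
    situation = config.situation if config is not None else Situation.NO_PAFO
    use_reserve = situation.has_actuation
    if use_reserve and reserve is None:
        reserve = ReserveActuator()
    if not use_reserve:
        reserve = None

    state = compute_muscle_states(model, angles, derivatives)
    lnorm = state.fiber_length / np.array(
        [m.optimal_fiber_length for m in model.muscles])
    vnorm = state.fiber_velocity / np.array(
        [m.max_contraction_velocity * m.optimal_fiber_length
         for m in model.muscles])
    flfv = force_length(lnorm) * force_velocity(vnorm)
    C = _torque_matrix(model, flfv, angles, weak_dorsiflexors)

    n, nm = flfv.shape
    tau = np.stack([moments.moments[j] for j in JOINT_NAMES], axis=1)
    acts = np.empty((n, nm))
    res_t = np.zeros(n)
    feas = np.ones(n, dtype=bool)
    deficit = np.zeros((n, len(JOINT_NAMES)))
    for f in range(n):
        a, tr, ok, resid = static_optimization_step(C[f], tau[f], reserve)
        acts[f] = a
        res_t[f] = tr
        feas[f] = ok
        if not ok:
            deficit[f] = resid
    fmax = np.array([m.max_isometric_force for m in model.muscles])
    forces = acts * flfv * fmax
    return MuscleForceSeries(
        muscle_names=list(state.muscle_names), activations=acts,
        forces=forces, reserve=res_t, percent=moments.percent.copy(),
        feasible=feas, deficit=deficit)
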