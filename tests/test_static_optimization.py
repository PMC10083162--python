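"""Static optimization: Hill factors, QP oracles, reserve semantics."""

import itertools

import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from pafosim import (GaitParams, PAFOConfig, ReserveActuator, Situation,
                     differentiate, generate_grf, generate_joint_angles,
                     hill_force, inverse_dynamics, run_static_optimization)
from pafosim._fk import JOINT_NAMES
from pafosim.static_optimization import (force_length, force_velocity,
                                         solve_box_min_norm,
                                         static_optimization_step)
from pafosim.msk_model import Muscle


def slsqp_oracle(A, b, lo, up, x0=None, tol=1e-14):
    """Independent constrained solver at tight tolerance."""
    n = A.shape[1]
    x0 = np.clip(np.zeros(n) if x0 is None else x0, lo,
                 np.where(np.isinf(up), 1.0, up))
    bounds = [(lo[i], None if np.isinf(up[i]) else up[i]) for i in range(n)]
    res = minimize(lambda z: z @ z, x0, jac=lambda z: 2 * z, bounds=bounds,
                   constraints=[LinearConstraint(A, b, b)], method="SLSQP",
                   options={"maxiter": 500, "ftol": tol})
    return res


def grid_oracle(A, b, lo, up, n_grid=2001):
    """Exhaustive search for 1 equality constraint and 2 variables:
    walk x1 over a fine grid, solve x2 from the constraint."""
    assert A.shape == (1, 2)
    best, best_cost = None, np.inf
    for x1 in np.linspace(lo[0], up[0], n_grid):
        if A[0, 1] == 0:
            continue
        x2 = (b[0] - A[0, 0] * x1) / A[0, 1]
        if lo[1] - 1e-12 <= x2 <= up[1] + 1e-12:
            c = x1 ** 2 + x2 ** 2
            if c < best_cost:
                best, best_cost = np.array([x1, x2]), c
    return best


class TestHillModel:
    def test_normalization(self):
        m = Muscle("m", 1000.0, 0.1, {"ankle": 0.05})
        assert hill_force(m, 1.0, 0.1, 0.0) == pytest.approx(1000.0)
        assert hill_force(m, 0.0, 0.1, 0.0) == 0.0
        assert hill_force(m, 0.5, 0.1, 0.0) == pytest.approx(500.0)

    def test_force_length_is_gaussian_peak_one(self):
        assert force_length(1.0) == 1.0
        assert force_length(0.55) == pytest.approx(np.exp(-1.0))
        assert force_length(1.45) == pytest.approx(np.exp(-1.0))

    def test_force_velocity_clamp(self):
        assert force_velocity(0.0) == 1.0
        assert force_velocity(-1.0) == 0.0     # max shortening
        assert force_velocity(-2.0) == 0.0
        assert force_velocity(0.4) == pytest.approx(1.4)  # eccentric cap

    def test_activation_bounds_enforced(self):
        m = Muscle("m", 1000.0, 0.1, {"ankle": 0.05})
        with pytest.raises(ValueError):
            hill_force(m, 1.2, 0.1, 0.0)


class TestSingleFrameQP:
    def test_single_muscle_closed_form(self):
        """a = tau / (r * Fmax) when fl*fv = 1."""
        C = np.zeros((3, 1))
        C[2, 0] = 0.05 * 1000.0
        a, tr, ok, _ = static_optimization_step(C, np.array([0, 0, 25.0]))
        assert ok and a[0] == pytest.approx(0.5, abs=1e-9)
        assert tr == 0.0

    def test_two_identical_muscles_split_equally(self):
        C = np.zeros((3, 2))
        C[2] = [50.0, 50.0]
        a, _, ok, _ = static_optimization_step(C, np.array([0, 0, 25.0]))
        assert ok
        np.testing.assert_allclose(a, [0.25, 0.25], atol=1e-9)

    def test_two_muscle_grid_oracle(self):
        A = np.array([[40.0, 70.0]])
        b = np.array([55.0])
        lo, up = np.zeros(2), np.ones(2)
        x, ok, _ = solve_box_min_norm(A, b, lo, up)
        ref = grid_oracle(A, b, lo, up)
        assert ok
        np.testing.assert_allclose(x, ref, atol=2e-3)
        assert x @ x <= ref @ ref + 1e-6

    def test_reserve_absorbs_dorsiflexion_demand(self):
        """With the 1 MN·m reserve the dorsiflexors go silent: the reserve
        cost (10/1e6)^2 is negligible against any activation^2."""
        C = np.zeros((3, 1))
        C[2, 0] = 1400.0 * 0.04
        a, tr, ok, _ = static_optimization_step(
            C, np.array([0, 0, 10.0]), ReserveActuator())
        assert ok
        assert tr == pytest.approx(10.0, rel=1e-6)
        assert a[0] < 1e-6
        # objective beats the muscle-only solution
        a0, _, _, _ = static_optimization_step(C, np.array([0, 0, 10.0]))
        assert (a @ a + (tr / 1e6) ** 2) < float(a0 @ a0)

    def test_reserve_never_plantarflexes(self):
        C = np.zeros((3, 1))
        C[2, 0] = -3550.0 * 0.048
        a, tr, ok, _ = static_optimization_step(
            C, np.array([0, 0, -40.0]), ReserveActuator())
        assert ok and tr == 0.0 and a[0] > 0

    def test_infeasible_frame_flagged_with_deficit(self):
        C = np.zeros((3, 1))
        C[2, 0] = 50.0
        a, tr, ok, resid = static_optimization_step(
            C, np.array([0, 0, 80.0]))
        assert not ok
        assert a[0] == pytest.approx(1.0)
        assert resid[2] == pytest.approx(30.0)

    @pytest.mark.parametrize("n_muscles", [1, 2, 3])
    def test_matches_tight_constrained_solver(self, n_muscles, rng):
        """Active-set solution agrees with an independent solver to 1e-4
        on small random frames."""
        checked = 0
        for _ in range(200):
            m = int(rng.integers(1, 4))
            A = rng.normal(0, 50.0, (m, n_muscles))
            target = A @ rng.uniform(0, 1, n_muscles) * rng.uniform(0.2, 1.1)
            lo, up = np.zeros(n_muscles), np.ones(n_muscles)
            x, ok, _ = solve_box_min_norm(A, target, lo, up)
            if not ok:
                continue
            ref = slsqp_oracle(A, target, lo, up,
                               x0=np.clip(x + rng.normal(0, 0.05, x.size),
                                          0, 1))
            if not ref.success or np.abs(A @ ref.x - target).max() > 1e-8:
                continue
            checked += 1
            assert float(x @ x) <= ref.fun + 1e-8
            np.testing.assert_allclose(x, ref.x, atol=1e-4)
        assert checked > 20


@pytest.fixture(scope="module")
def so_pipeline(model):
    cycle = generate_joint_angles(GaitParams(), model)
    cycle = generate_grf(cycle, model.body_mass, model=model)
    derivs = differentiate(cycle.angles, cycle.cycle_duration)
    moments = inverse_dynamics(model, cycle.angles, derivs,
                               cycle.grf["right"])
    return cycle, derivs, moments


class TestRunStaticOptimization:
    def test_moment_balance_every_frame(self, model, so_pipeline):
        """Muscle moments plus reserve reproduce the net moments."""
        cycle, derivs, moments = so_pipeline
        for sit in (Situation.NO_PAFO, Situation.ACTUATION_ONLY):
            forces = run_static_optimization(
                model, cycle.angles, derivs, moments,
                PAFOConfig(situation=sit))
            assert forces.feasible.all()
            recon = np.zeros((cycle.n_frames, 3))
            for i, mus in enumerate(model.muscles):
                for j, jname in enumerate(JOINT_NAMES):
                    if mus.spans(jname):
                        recon[:, j] += forces.forces[:, i] \
                            * mus.moment_arm(jname)
            recon[:, 2] += forces.reserve
            tau = np.stack([moments.moments[j] for j in JOINT_NAMES], axis=1)
            scale = np.abs(tau).max()
            np.testing.assert_allclose(recon, tau, atol=1e-6 * scale)

    def test_zero_mass_device_reproduces_baseline_forces(self, model,
                                                         so_pipeline):
        cycle, derivs, moments = so_pipeline
        f0 = run_static_optimization(model, cycle.angles, derivs, moments,
                                     PAFOConfig(situation=Situation.NO_PAFO))
        f1 = run_static_optimization(
            model, cycle.angles, derivs, moments,
            PAFOConfig(total_mass=0.0, position="L_S",
                       situation=Situation.MASS_ONLY))
        np.testing.assert_allclose(f1.forces, f0.forces, atol=1e-9)

    def test_actuation_silences_dorsiflexors(self, model, so_pipeline):
        """The near-free reserve outcompetes the foot-drop-affected
        dorsiflexor group, whose force integral collapses to ~0."""
        cycle, derivs, moments = so_pipeline
        f_off = run_static_optimization(model, cycle.angles, derivs, moments,
                                        PAFOConfig(situation=Situation.NO_PAFO))
        f_on = run_static_optimization(
            model, cycle.angles, derivs, moments,
            PAFOConfig(situation=Situation.ACTUATION_ONLY))
        df_off = np.trapezoid(f_off.force("dorsiflexors"), cycle.percent)
        df_on = np.trapezoid(f_on.force("dorsiflexors"), cycle.percent)
        assert df_off > 1.0          # dorsiflexors work in normal gait
        assert df_on < 1e-3 * df_off
        assert f_on.reserve.max() > 1.0

    def test_gastrocnemius_antagonizes_the_actuator_late_swing(
            self, model, so_pipeline):
        """With the ideal dorsiflexion reserve active, gastrocnemius force
        in late swing exceeds its unassisted value: the free reserve
        cancels its plantarflexion, so it is recruited for knee flexion."""
        cycle, derivs, moments = so_pipeline
        f_off = run_static_optimization(model, cycle.angles, derivs, moments,
                                        PAFOConfig(situation=Situation.NO_PAFO))
        f_on = run_static_optimization(
            model, cycle.angles, derivs, moments,
            PAFOConfig(situation=Situation.ACTUATION_ONLY))
        late_swing = slice(85, 101)
        gas_on = (f_on.force("gastrocnemius_med")[late_swing]
                  + f_on.force("gastrocnemius_lat")[late_swing])
        gas_off = (f_off.force("gastrocnemius_med")[late_swing]
                   + f_off.force("gastrocnemius_lat")[late_swing])
        assert gas_on.max() > gas_off.max()
        assert gas_on.sum() > gas_off.sum()

    def test_weakness_flag_zeroes_dorsiflexor_capacity(self, model,
                                                       so_pipeline):
        cycle, derivs, moments = so_pipeline
        forces = run_static_optimization(
            model, cycle.angles, derivs, moments,
            PAFOConfig(situation=Situation.ACTUATION_ONLY),
            weak_dorsiflexors=True)
        np.testing.assert_allclose(forces.force("dorsiflexors"), 0.0,
                                   atol=1e-12)
        assert forces.feasible.all()

    def test_normalization_flag(self, model, so_pipeline):
        cycle, derivs, moments = so_pipeline
        f = run_static_optimization(model, cycle.angles, derivs, moments,
                                    PAFOConfig(situation=Situation.NO_PAFO))
        fn = f.normalize_to_body_mass(model.body_mass)
        np.testing.assert_allclose(fn.forces * model.body_mass, f.forces)
        with pytest.raises(ValueError):
            fn.normalize_to_body_mass(model.body_mass)
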