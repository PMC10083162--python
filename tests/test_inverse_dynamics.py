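"""Inverse dynamics: differentiation, Newton-Euler oracles, device effects."""

import numpy as np
import pytest

from pafosim import (GaitParams, KinematicDerivatives, PAFOConfig, Situation,
                     apply_pafo, differentiate, generate_grf,
                     generate_joint_angles, inverse_dynamics, peak_moments,
                     scale_model)
from pafosim._fk import COORD_NAMES, JOINT_NAMES, ChainKinematics
from pafosim.inverse_dynamics import JointMomentSeries
from pafosim.msk_model import GRAVITY, Segment


def _zero_angles(n=3, pelvis_y=1.0):
    q = {k: np.zeros(n) for k in COORD_NAMES}
    q["pelvis_y"] = np.full(n, pelvis_y)
    return q


def _zero_derivs(n=3):
    z = {k: np.zeros(n) for k in COORD_NAMES}
    return KinematicDerivatives(z, {k: np.zeros(n) for k in COORD_NAMES}, 1.0)


def free_body_moments(model, angles, derivs, grf=None):
    """Independent oracle: sum over distal segments of inertial and
    gravitational moments about each joint, minus the GRF moment.

    M_j = Σ_i [ I_i α_i + (r_ci − r_j) × m_i (a_i − g) ] − (r_cop − r_j) × F
    over segments i distal to joint j; no recursion involved.
    """
    ck = ChainKinematics(model, angles, derivs.velocity, derivs.acceleration)
    g = np.array([0.0, -GRAVITY])
    n = len(angles["hip"])
    if grf is None:
        f_ext, cop = np.zeros((n, 2)), np.zeros((n, 2))
    else:
        f_ext, cop = grf["f"], grf["cop"]

    def cross(a, b):
        return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]

    distal = {"ankle": ["foot"], "knee": ["shank", "foot"],
              "hip": ["thigh", "shank", "foot"]}
    out = {}
    for joint, segs in distal.items():
        r_j = ck.joint_position(joint)
        M = np.zeros(n)
        for s in segs:
            seg = model.segments[s]
            r_c, _, a_c = ck.com(s)
            M += seg.inertia_com * ck.phidd[s]
            M += cross(r_c - r_j, seg.mass * (a_c - g))
        M -= cross(cop - r_j, f_ext)
        out[joint] = model.joints[joint].sign * M
    return out


@pytest.fixture(scope="module")
def pipeline(model):
    """Template gait with derivatives, GRFs and baseline moments."""
    cycle = generate_joint_angles(GaitParams(), model)
    cycle = generate_grf(cycle, model.body_mass, model=model)
    derivs = differentiate(cycle.angles, cycle.cycle_duration)
    moments = inverse_dynamics(model, cycle.angles, derivs,
                               cycle.grf["right"])
    return cycle, derivs, moments


class TestDifferentiate:
    def test_sine_wave_derivative(self):
        n, T = 101, 1.1
        t = np.linspace(0, T, n)
        ang = {k: np.zeros(n) for k in COORD_NAMES}
        ang["hip"] = np.sin(2 * np.pi * t / T)
        d = differentiate(ang, T, smoothing_cutoff=None)
        v_true = (2 * np.pi / T) * np.cos(2 * np.pi * t / T)
        assert np.abs(d.velocity["hip"] - v_true).max() \
            < 0.01 * (2 * np.pi / T)

    def test_constant_series_has_zero_derivatives(self):
        ang = {k: np.full(101, 0.3) for k in COORD_NAMES}
        d = differentiate(ang, 1.0)
        for k in COORD_NAMES:
            np.testing.assert_allclose(d.velocity[k], 0.0, atol=1e-12)
            np.testing.assert_allclose(d.acceleration[k], 0.0, atol=1e-9)

    def test_doubling_duration_halves_velocity(self, gait):
        d1 = differentiate(gait.angles, 1.0, smoothing_cutoff=None)
        d2 = differentiate(gait.angles, 2.0, smoothing_cutoff=None)
        np.testing.assert_allclose(d2.velocity["knee"],
                                   d1.velocity["knee"] / 2, rtol=1e-12,
                                   atol=1e-12)

    def test_linear_trend_recovered(self):
        # non-periodic coordinate (forward travel) gets its rate back
        n, T = 101, 1.25
        t = np.linspace(0, T, n)
        ang = {k: np.zeros(n) for k in COORD_NAMES}
        ang["pelvis_x"] = 1.25 * t
        d = differentiate(ang, T)
        np.testing.assert_allclose(d.velocity["pelvis_x"], 1.25, atol=1e-9)

    def test_too_few_frames_rejected(self):
        ang = {k: np.zeros(4) for k in COORD_NAMES}
        with pytest.raises(ValueError):
            differentiate(ang, 1.0)

    def test_cutoff_above_nyquist_rejected(self, gait):
        with pytest.raises(ValueError):
            differentiate(gait.angles, 10.0, smoothing_cutoff=50.0)


class TestNewtonEulerOracles:
    def test_no_forces_no_motion_no_moments(self, model):
        m = model.copy()
        for s in m.segments.values():
            s.mass = 0.0
            s.inertia_com = 0.0
        res = inverse_dynamics(m, _zero_angles(), _zero_derivs(), None)
        for j in JOINT_NAMES:
            np.testing.assert_allclose(res.moments[j], 0.0, atol=1e-12)

    def test_static_stance_ankle_moment_is_force_times_lever(self):
        """Vertical force F at lever d anterior to the ankle demands an
        internal plantarflexor moment of magnitude F·d."""
        m = scale_model(1.71, 68.03)
        m.segments["foot"] = Segment("foot", m.segments["foot"].length,
                                     0.0, 0.05, 0.0)
        q = _zero_angles()
        ck = ChainKinematics(m, q)
        ankle = ck.joint_position("ankle")
        F, d = 600.0, 0.08
        grf = {"f": np.tile([0.0, F], (3, 1)),
               "cop": ankle + np.array([d, -0.04])}
        res = inverse_dynamics(m, q, _zero_derivs(), grf)
        np.testing.assert_allclose(res.moments["ankle"], -F * d, rtol=1e-8)

    def test_compound_pendulum_knee_moment(self):
        """Holding a point-mass shank at angle θ from vertical requires a
        knee flexor moment m·g·r·sinθ."""
        mm, r, theta = 4.0, 0.3, 0.5
        m = scale_model(1.71, 68.03)
        m.segments["shank"] = Segment("shank", m.segments["shank"].length,
                                      mm, r, 0.0)
        m.segments["foot"] = Segment("foot", m.segments["foot"].length,
                                     0.0, 0.05, 0.0)
        m.segments["thigh"] = Segment("thigh", m.segments["thigh"].length,
                                      0.0, 0.1, 0.0)
        q = _zero_angles()
        q["knee"] = np.full(3, theta)
        res = inverse_dynamics(m, q, _zero_derivs(), None)
        expected = mm * GRAVITY * r * np.sin(theta)
        np.testing.assert_allclose(res.moments["knee"], expected, rtol=1e-8)

    def test_matches_free_body_oracle_on_gait(self, model, pipeline):
        cycle, derivs, moments = pipeline
        oracle = free_body_moments(model, cycle.angles, derivs,
                                   cycle.grf["right"])
        for j in JOINT_NAMES:
            np.testing.assert_allclose(moments.moments[j], oracle[j],
                                       rtol=1e-9, atol=1e-9)

    def test_mismatched_grids_rejected(self, model, pipeline):
        cycle, derivs, _ = pipeline
        bad_grf = {"f": np.zeros((7, 2)), "cop": np.zeros((7, 2))}
        with pytest.raises(ValueError):
            inverse_dynamics(model, cycle.angles, derivs, bad_grf)


class TestDeviceMassEffects:
    def test_zero_mass_device_leaves_moments_unchanged(self, model, pipeline):
        cycle, derivs, base = pipeline
        cfg = PAFOConfig(total_mass=0.0, position="A_S",
                         situation=Situation.MASS_ONLY)
        res = inverse_dynamics(apply_pafo(model, cfg), cycle.angles, derivs,
                               cycle.grf["right"])
        for j in JOINT_NAMES:
            scale = np.abs(base.moments[j]).max()
            np.testing.assert_allclose(res.moments[j], base.moments[j],
                                       atol=1e-12 * scale)

    def test_swing_peaks_grow_with_distal_placement(self, model, pipeline):
        """At fixed device mass, swing-phase knee and hip peak moment
        magnitudes are non-decreasing U → M → L → ankle-aligned."""
        cycle, derivs, _ = pipeline
        swing = ~cycle.stance_mask
        peaks = {"knee": [], "hip": []}
        for pos in ("U_S", "M_S", "L_S", "A_S"):
            cfg = PAFOConfig(total_mass=3.0, position=pos,
                             situation=Situation.MASS_ONLY)
            res = inverse_dynamics(apply_pafo(model, cfg), cycle.angles,
                                   derivs, cycle.grf["right"])
            for j in peaks:
                peaks[j].append(np.abs(res.moments[j][swing]).max())
        for j in peaks:
            assert np.all(np.diff(peaks[j]) >= 0)

    def test_ankle_insensitive_relative_to_knee_hip(self, model, pipeline):
        """Only 10% of device mass reaches the foot, so ankle peak-moment
        changes are small next to knee/hip changes."""
        cycle, derivs, base = pipeline
        cfg = PAFOConfig(total_mass=5.0, position="A_S",
                         situation=Situation.MASS_ONLY)
        res = inverse_dynamics(apply_pafo(model, cfg), cycle.angles, derivs,
                               cycle.grf["right"])
        rel = {}
        for j in JOINT_NAMES:
            num = np.abs(res.moments[j] - base.moments[j]).max()
            rel[j] = num / np.abs(base.moments[j]).max()
        assert rel["ankle"] < 0.2 * min(rel["knee"], rel["hip"])

    def test_added_mass_superposition(self, model, pipeline):
        """Moment change from the device equals the inverse dynamics of the
        added masses alone (Newton-Euler is linear in inertial params)."""
        cycle, derivs, base = pipeline
        cfg = PAFOConfig(total_mass=4.0, position="L_B",
                         situation=Situation.MASS_ONLY)
        full = inverse_dynamics(apply_pafo(model, cfg), cycle.angles, derivs,
                                cycle.grf["right"])
        # model carrying only the added masses: zero out the body
        only = apply_pafo(model, cfg)
        for name in only.segments:
            seg, ref = only.segments[name], model.segments[name]
            m_add = seg.mass - ref.mass
            if m_add <= 1e-12:
                seg.mass, seg.inertia_com = 0.0, 0.0
                continue
            com_add = (seg.mass * seg.com_offset
                       - ref.mass * ref.com_offset) / m_add
            perp_add = (seg.mass * seg.com_perp
                        - ref.mass * ref.com_perp) / m_add
            i_add = (seg.inertia_about(com_add, perp_add)
                     - ref.mass * ((ref.com_offset - com_add) ** 2
                                   + (ref.com_perp - perp_add) ** 2)
                     - ref.inertia_com)
            seg.mass, seg.inertia_com = m_add, i_add
            seg.com_offset, seg.com_perp = com_add, perp_add
        extra = inverse_dynamics(only, cycle.angles, derivs, None)
        for j in JOINT_NAMES:
            np.testing.assert_allclose(
                full.moments[j] - base.moments[j], extra.moments[j],
                atol=1e-8 * max(1.0, np.abs(full.moments[j]).max()))


class TestPeakMoments:
    def test_sine_series_peaks(self):
        n = 101
        series = JointMomentSeries(
            {"hip": np.sin(np.linspace(0, 2 * np.pi, n)),
             "knee": np.zeros(n), "ankle": np.zeros(n)},
            np.linspace(0, 100, n))
        pk = peak_moments(series)
        assert pk["hip"][0] == pytest.approx(1.0, abs=1e-3)
        assert pk["hip"][1] == pytest.approx(-1.0, abs=1e-3)

    def test_all_positive_series_convention(self):
        series = JointMomentSeries(
            {"hip": np.linspace(1.0, 2.0, 11), "knee": np.ones(11),
             "ankle": np.ones(11)}, np.linspace(0, 100, 11))
        pk = peak_moments(series)
        # the negative-direction peak is the signed minimum, still positive
        assert pk["hip"] == (2.0, 1.0)

    def test_knee_flexion_peak_moves_to_swing_under_device_mass(
            self, model, pipeline):
        """With distal device mass the knee flexor demand of decelerating
        the heavier swinging shank dominates the cycle peak."""
        cycle, derivs, _ = pipeline
        cfg = PAFOConfig(total_mass=3.0, position="A_S",
                         situation=Situation.MASS_ONLY)
        res = inverse_dynamics(apply_pafo(model, cfg), cycle.angles, derivs,
                               cycle.grf["right"])
        stance_end = int(cycle.stance_fraction * (cycle.n_frames - 1))
        assert int(np.argmax(res.moments["knee"])) > stance_end

    def test_normalization_round_trip_and_double_flag(self, pipeline):
        _, _, moments = pipeline
        nm = moments.normalize_to_body_mass(68.03)
        np.testing.assert_allclose(nm.moments["hip"] * 68.03,
                                   moments.moments["hip"])
        with pytest.raises(ValueError):
            nm.normalize_to_body_mass(68.03)
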