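import numpy as np
import pytest
from scipy.interpolate import CubicSpline

import skijump as sk
from skijump.body import body_angle_of_attack, compute_com, joint_angle
from skijump.simulate import (SimulationError, apply_takeoff, sample_sensors,
                              simulate_flight, simulate_inrun)


class TestInrun:
    def test_frictionless_energy_conservation(self, hill):
        cfg = sk.SimulationConfig(mu=0.0, cda_inrun=0.0)
        res = simulate_inrun(cfg, hill, record_every=10)
        st = res.series
        h0 = hill.inrun_position(hill.gate_arc_position(cfg.gate))[1]
        v_expected = np.sqrt(2 * cfg.g * (h0 - st.y[-1]))
        assert np.hypot(st.vx[-1], st.vy[-1]) == pytest.approx(v_expected, rel=1e-7)

    def test_terminal_velocity_on_long_straight(self, straight_hill):
        cfg = sk.SimulationConfig(mu=0.05, cda_inrun=0.6, gate=1, step=2e-3)
        res = simulate_inrun(cfg, straight_hill, record_every=50)
        v_end = np.hypot(res.series.vx[-1], res.series.vy[-1])
        delta = straight_hill.inrun_straight_angle
        m = cfg.total_mass
        v_term = np.sqrt(2 * m * cfg.g * (np.sin(delta) - cfg.mu * np.cos(delta))
                         / (cfg.rho * 0.6))
        assert v_end == pytest.approx(v_term, rel=0.01)

    def test_lower_gate_is_slower(self, hill):
        v = {}
        for gate in (12, 15):
            res = simulate_inrun(sk.SimulationConfig(gate=gate, step=2e-3),
                                 hill, record_every=50)
            v[gate] = np.hypot(res.series.vx[-1], res.series.vy[-1])
        assert v[12] < v[15]


class TestTakeoff:
    def test_zero_impulse_noop(self):
        state = np.array([0.0, 0.0, 24.0, -4.0])
        cfg = sk.SimulationConfig(takeoff_impulse_vperp=0.0)
        assert np.allclose(apply_takeoff(state, cfg), state)

    def test_orthogonal_speed_addition(self):
        state = np.array([0.0, 0.0, 24.0, -4.0])
        cfg = sk.SimulationConfig(takeoff_impulse_vperp=2.5)
        out = apply_takeoff(state, cfg)
        v_before = np.hypot(24.0, -4.0)
        assert np.hypot(out[2], out[3]) == pytest.approx(
            np.sqrt(v_before ** 2 + 2.5 ** 2))

    def test_impulse_points_up(self):
        state = np.array([0.0, 0.0, 24.0, -4.0])
        out = apply_takeoff(state, sk.SimulationConfig(takeoff_impulse_vperp=2.5))
        assert out[3] > state[3]


class TestFlight:
    def test_ballistic_parabola(self, hill):
        cfg = sk.SimulationConfig(cda_flight=0.0, cla_flight=0.0, step=1e-3)
        state0 = np.array([0.0, 0.0, 24.0, -1.0])
        res, _, _ = simulate_flight(cfg, hill, state0, record_every=10)
        st = res.series
        assert np.allclose(st.x, 24.0 * st.t, atol=1e-9)
        assert np.allclose(st.y, -1.0 * st.t - 0.5 * cfg.g * st.t ** 2, atol=1e-9)

    def test_lift_does_no_work(self, hill):
        cfg = sk.SimulationConfig(cda_flight=0.0, cla_flight=0.4)
        state0 = np.array([0.0, 0.0, 25.0, -2.0])
        res, _, _ = simulate_flight(cfg, hill, state0, record_every=10)
        st = res.series
        lhs = st.vx ** 2 + st.vy ** 2
        rhs = 25.0 ** 2 + 2.0 ** 2 + 2 * cfg.g * (0.0 - st.y)
        assert np.max(np.abs(lhs - rhs) / rhs) < 1e-9

    def test_lift_extends_jump(self, hill):
        base = dict(cda_flight=0.2, takeoff_impulse_vperp=2.0,
                    m=65.0, rho=1.225)
        j_nolift = sk.simulate_jump(sk.SimulationConfig(cla_flight=0.0, **base), hill)
        j_lift = sk.simulate_jump(sk.SimulationConfig(cla_flight=0.3, **base), hill)
        assert j_lift.distance > j_nolift.distance


class TestJump:
    def test_gate_monotonicity(self, hill):
        speeds, dists = [], []
        for gate in (11, 13, 15):
            j = sk.simulate_jump(sk.SimulationConfig(gate=gate, step=2e-3), hill)
            speeds.append(j.edge_speed)
            dists.append(j.distance)
        assert speeds == sorted(speeds)
        assert dists == sorted(dists)

    def test_energy_audit_without_dissipation(self, hill):
        cfg = sk.SimulationConfig(mu=0.0, cda_inrun=0.0, cda_flight=0.0,
                                  cla_flight=0.0, takeoff_impulse_vperp=0.0)
        jump = sk.simulate_jump(cfg, hill)
        h0 = hill.inrun_position(hill.gate_arc_position(cfg.gate))[1]
        E = 0.5 * (jump.com.vx ** 2 + jump.com.vy ** 2) + cfg.g * jump.com.y
        assert np.max(np.abs(E - cfg.g * h0)) / (cfg.g * abs(h0)) < 1e-6

    def test_stall_raises(self, straight_hill):
        # friction exceeding the slope grade stalls a standing start
        cfg = sk.SimulationConfig(mu=0.9, gate=1)
        with pytest.raises(SimulationError):
            simulate_inrun(cfg, straight_hill)


class TestPoseSynthesis:
    def test_extended_chain_collinear(self, hill, model, default_jump):
        pose = sk.PoseProfile(theta_crouch=np.pi, theta_flight=np.pi,
                              gamma_crouch=np.pi, gamma_flight=np.pi)
        frames = sk.synthesize_pose(default_jump.com, pose, model,
                                    rate_hz=30.0, t0=0.5, t1=1.5)
        for i in range(0, len(frames), 7):
            fr = frames.frame(i)
            v1 = fr["knee"] - fr["ankle"]
            v2 = fr["shoulder"] - fr["ankle"]
            assert abs(v1[0] * v2[1] - v1[1] * v2[0]) < 1e-9

    def test_com_round_trip(self, model, default_jump):
        frames = sk.synthesize_pose(default_jump.com, sk.PoseProfile(), model,
                                    rate_hz=60.0, t0=-1.0, t1=1.5)
        cx = CubicSpline(default_jump.com.t, default_jump.com.x)
        cy = CubicSpline(default_jump.com.t, default_jump.com.y)
        for i in range(0, len(frames), 11):
            com = compute_com(frames.frame(i), model)
            assert np.hypot(com[0] - cx(frames.t[i]),
                            com[1] - cy(frames.t[i])) < 1e-9

    def test_angle_profiles_realized(self, model, default_jump):
        pose = sk.PoseProfile()
        frames = sk.synthesize_pose(default_jump.com, pose, model,
                                    rate_hz=60.0, t0=-1.0, t1=1.5)
        cvx = CubicSpline(default_jump.com.t, default_jump.com.vx)
        cvy = CubicSpline(default_jump.com.t, default_jump.com.vy)
        for i in range(0, len(frames), 11):
            fr = frames.frame(i)
            t = frames.t[i]
            assert joint_angle(fr["ankle"], fr["knee"], fr["hip"]) == pytest.approx(
                pose.theta(t), abs=1e-9)
            assert joint_angle(fr["knee"], fr["hip"], fr["shoulder"]) == pytest.approx(
                pose.gamma(t), abs=1e-9)
            vel = (cvx(t), cvy(t))
            assert body_angle_of_attack(fr, vel) == pytest.approx(
                pose.psi(t), abs=1e-9)


class TestSensorSampling:
    def test_noiseless_lies_on_interpolant(self):
        t = np.linspace(0, 10, 501)
        x = np.sin(t)
        tt, out = sample_sensors(t, x, 50.0, 0.0, seed=0)
        assert np.allclose(out, np.sin(tt), atol=1e-6)

    def test_noise_sd_calibrated(self):
        t = np.linspace(0, 250, 12501)
        x = np.zeros_like(t)
        tt, out = sample_sensors(t, x, 50.0, 0.05, seed=42)
        assert len(out) > 10_000
        assert np.std(out) == pytest.approx(0.05, rel=0.05)

    def test_deterministic_for_fixed_seed(self):
        t = np.linspace(0, 10, 501)
        x = np.cos(t)
        _, a = sample_sensors(t, x, 60.0, 0.02, seed=7)
        _, b = sample_sensors(t, x, 60.0, 0.02, seed=7)
        assert np.array_equal(a, b)

    def test_window_outside_support_rejected(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValueError):
            sample_sensors(t, t, 50.0, 0.0, seed=0, t0=-1.0)
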