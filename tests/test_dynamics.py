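import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ballincup import (
    ModelParams,
    Strategy,
    cup_kinematics,
    forward_simulate,
    inverse_dynamics_force,
    linear_mode_analysis,
    simulate_ball,
    simulate_strategy,
)
from ballincup.dynamics import total_energy

from conftest import PERIOD1


class TestModelParams:
    def test_defaults_are_the_task_constants(self):
        p = ModelParams()
        assert (p.m_ball, p.m_cup, p.rod_length, p.gravity) == (0.6, 2.4, 0.25, 9.81)

    @pytest.mark.parametrize("field", ["m_ball", "m_cup", "rod_length", "gravity"])
    def test_nonpositive_rejected(self, field):
        with pytest.raises(ValueError):
            ModelParams(**{field: 0.0})


class TestStrategy:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            Strategy(0.1, 0.0, 0.0)
        with pytest.raises(ValueError):
            Strategy(-0.1, 1.0, 0.0)

    def test_map_domain_validator(self):
        assert Strategy(0.10, 1.0, 1.0).in_map_domain()
        assert not Strategy(0.50, 1.0, 1.0).in_map_domain()
        assert not Strategy(0.10, 2.0, 1.0).in_map_domain()
        assert not Strategy(0.10, 1.0, 2.0).in_map_domain()


class TestCupKinematics:
    def test_zero_amplitude_is_static(self):
        t = np.arange(0, 601) / 120
        pos, vel, acc = cup_kinematics(Strategy(0.0, 1.0, 0.0), t)
        assert not pos.any() and not vel.any() and not acc.any()

    def test_closed_form_sinusoid_extremes(self):
        t = np.arange(0, 45 * 120 + 1) / 120
        pos, vel, acc = cup_kinematics(Strategy(0.2, 1.0, 0.0), t)
        assert np.abs(pos).max() == pytest.approx(0.1)
        assert np.abs(acc).max() == pytest.approx(0.1 * (2 * math.pi) ** 2)

    def test_peak_aligned_convention_at_t0(self):
        t = np.arange(0, 121) / 120
        pos, vel, _ = cup_kinematics(Strategy(0.2, 1.0, 0.0), t)
        assert pos[0] == pytest.approx(0.1)
        assert vel[0] == pytest.approx(0.0)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            cup_kinematics(PERIOD1, np.array([0.0, 0.1, 0.3]))


class TestSimulateBall:
    def test_equilibrium_stays_at_rest(self):
        traj = simulate_ball(Strategy(0.0, 1.0, 0.0, 0.0), duration=5.0)
        assert np.abs(traj.ball_ang).max() < 1e-10

    def test_small_angle_frequency_is_pendulum_frequency(self):
        # undriven, theta0 = 0.05 rad: f = sqrt(g/l)/2pi = 0.9967 Hz
        traj = simulate_ball(Strategy(0.0, 1.0, 0.05, 0.0), duration=60.0)
        spec = np.abs(np.fft.rfft(traj.ball_ang - traj.ball_ang.mean()))
        freq = np.fft.rfftfreq(len(traj.time), 1 / 120)
        f_peak = freq[spec.argmax()]
        assert f_peak == pytest.approx(math.sqrt(9.81 / 0.25) / (2 * math.pi), abs=0.02)

    def test_period1_orbit_returns_to_initial_state(self, period1_traj):
        # strobed ball state at every cup peak stays at (1.0, 0.0)
        pk = np.arange(0, 45 * 120 + 1, 120)
        assert np.abs(period1_traj.ball_ang[pk] - 1.0).max() < 0.02
        assert np.abs(period1_traj.ball_angvel[pk]).max() < 0.1

    def test_integrator_convergence(self):
        a = simulate_ball(PERIOD1, rtol=1e-8, atol=1e-8, duration=45.0)
        b = simulate_ball(PERIOD1, rtol=1e-10, atol=1e-10, duration=45.0)
        assert np.abs(a.ball_ang - b.ball_ang).max() < 1e-4


class TestInverseDynamics:
    def test_static_system_requires_no_force(self):
        traj = simulate_ball(Strategy(0.0, 1.0, 0.0, 0.0), duration=5.0)
        inverse_dynamics_force(traj)
        assert np.abs(traj.force).max() < 1e-9

    def test_small_angle_force_amplitude(self):
        # A = 0: F ~ m_ball * g * theta, amplitude 0.6*9.81*0.1 = 0.589 N
        traj = simulate_ball(Strategy(0.0, 1.0, 0.1, 0.0), duration=30.0)
        inverse_dynamics_force(traj)
        assert np.abs(traj.force).max() == pytest.approx(0.6 * 9.81 * 0.1, rel=0.02)

    def test_force_residual_zero_by_construction(self, period1_traj, params):
        assert np.abs(period1_traj.force_residual(params)).max() < 1e-9

    def test_inconsistent_ball_channels_rejected(self, period1_traj, params):
        import copy

        bad = copy.deepcopy(period1_traj)
        bad.ball_ang = bad.ball_ang + 0.3 * np.sin(7.0 * bad.time)
        with pytest.raises(ValueError, match="residual"):
            inverse_dynamics_force(bad, params)


class TestForwardSimulate:
    def test_all_zero_input_stays_zero(self):
        t = np.arange(0, 241) / 120
        traj = forward_simulate(np.zeros_like(t), t)
        assert np.abs(traj.cup_pos).max() < 1e-12
        assert np.abs(traj.ball_ang).max() < 1e-12

    def test_round_trip_reproduces_cup_trajectory(self, period1_traj):
        # inverse-dynamics force fed back through forward dynamics
        fw = forward_simulate(
            period1_traj.force, period1_traj.time,
            initial_state=(0.05, 0.0, 1.0, 0.0),
        )
        assert np.abs(fw.cup_pos - period1_traj.cup_pos).max() < 1e-4

    def test_free_oscillation_matches_linearised_model(self):
        # F = 0 with the anti-phase initial condition of the forward model:
        # the consistent linearisation predicts
        # f = (1/2pi) sqrt((g/l) (1 + m_b/(m_c+m_b)))
        p = ModelParams()
        th0 = 0.05
        x0 = p.m_ball * p.rod_length / (p.m_ball + p.m_cup) * th0
        t = np.arange(0, 40 * 120 + 1) / 120
        traj = forward_simulate(np.zeros_like(t), t, initial_state=(x0, 0, th0, 0))
        spec = np.abs(np.fft.rfft(traj.cup_pos - traj.cup_pos.mean()))
        freq = np.fft.rfftfreq(len(t), 1 / 120)
        f_pred = math.sqrt(
            p.gravity / p.rod_length * (1 + p.m_ball / (p.m_ball + p.m_cup))
        ) / (2 * math.pi)
        assert freq[spec.argmax()] == pytest.approx(f_pred, abs=0.03)

    def test_energy_conserved_without_force(self, params):
        t = np.arange(0, 30 * 120 + 1) / 120
        traj = forward_simulate(np.zeros_like(t), t, initial_state=(0.01, 0, 0.3, 0))
        e = total_energy(traj, params)
        assert np.abs(e - e[0]).max() / e[0] < 1e-5


class TestLinearModeAnalysis:
    def test_antiphase_mode_frequency(self):
        lm = linear_mode_analysis()
        assert lm["mode_frequencies"][0] == pytest.approx(0.0, abs=1e-9)
        assert lm["mode_frequencies"][1] == pytest.approx(1.11, abs=0.005)

    def test_max_free_amplitude_is_10_cm(self):
        lm = linear_mode_analysis()
        assert lm["max_free_cup_amplitude_pp"] == pytest.approx(0.10)

    def test_mode_shape_is_antiphase(self):
        shape = linear_mode_analysis()["antiphase_mode_shape"]
        # cup displacement m_b*l/(m_b+m_c) per unit ball angle; the ball's
        # absolute displacement (x - l*theta) moves opposite to the cup
        cup, ball_ang = shape
        assert cup == pytest.approx(0.6 * 0.25 / 3.0, rel=1e-6)
        assert (cup - 0.25 * ball_ang) * cup < 0

    def test_light_ball_limit(self):
        lm = linear_mode_analysis(ModelParams(m_ball=1e-6))
        assert lm["mode_frequencies"][1] == pytest.approx(
            math.sqrt(9.81 / 0.25) / (2 * math.pi), rel=1e-4
        )


@settings(deadline=None, max_examples=20)
@given(
    a=st.floats(0.0, 0.44),
    f=st.floats(0.8, 1.2),
    t0=st.floats(-1.5, 1.5),
)
def test_cup_velocity_is_derivative_of_position(a, f, t0):
    """Property: analytic velocity matches the numerical derivative."""
    t = np.arange(0, 5 * 120 + 1) / 120
    pos, vel, acc = cup_kinematics(Strategy(a, f, t0), t)
    dv = np.gradient(pos, t)
    assert np.abs(dv[2:-2] - vel[2:-2]).max() < 0.03 * max(a, 1e-9) * (2 * np.pi * f) + 1e-12


def test_trajectory_io_round_trip(tmp_path, period1_traj):
    from ballincup import Trajectory

    p = tmp_path / "traj.csv"
    period1_traj.save(p)
    back = Trajectory.load(p)
    assert np.allclose(back.force, period1_traj.force)
    assert np.allclose(back.ball_ang, period1_traj.ball_ang)
    h5 = tmp_path / "traj.h5"
    period1_traj.save(h5)
    back2 = Trajectory.load(h5)
    assert np.array_equal(back2.cup_pos, period1_traj.cup_pos)
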