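"""Cart-and-pendulum ("ball in a cup") object dynamics.

The manipulated object is a cart of mass ``m_cup`` sliding on a horizontal
line, with a point-mass ball ``m_ball`` suspended from it by a rigid massless
rod of length ``rod_length``.  The hand acts on the cart through a horizontal
force ``F``.  Ball angle ``theta`` is measured from the hanging vertical and
is **positive when the ball is displaced opposite to positive cup
displacement** (rightward cup, leftward/clockwise ball), so anti-phase
coordination has ``theta > 0`` at a positive cup peak.

Under this convention the ball obeys

    l * theta'' = x'' * cos(theta) - g * sin(theta)

and the hand force rendered by the task is

    F = (m_cup + 2*m_ball) * x''
        - m_ball * l * (theta'' * cos(theta) - theta'^2 * sin(theta))

Note the translating inertia in the force equation is ``m_cup + m_ball``
(the coefficient ``m_cup + 2*m_ball`` after adding the pendulum-bob term),
not the bare cup mass: the virtual task renders the cup and the suspension
point as a rigidly moving unit.  This force definition is anchored by the
period-1 fixed point of the rhythmic task, at which the strobed hand force
is constant at -4.1 N (1 Hz, 10 cm peak-to-peak, theta0 = 1 rad), and by the
strobed-force range of the neighbouring quasi-periodic orbits.  The
free-vibration mode analysis of the bare object (cup mass alone translating)
is a separate, conservative linearisation; see :func:`linear_mode_analysis`.

Rhythmic strategies prescribe a sinusoidal cup trajectory.  The peak-aligned
cosine convention is used throughout:

    x(t) = (A_pp / 2) * cos(2*pi*f*t)

so ``t = 0`` is a positive cup peak, where the strategy's initial ball state
``(theta0, omega0)`` is defined.  This makes simulated initial conditions
directly comparable with experimental ball states strobed at cup peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "Strategy",
    "Trajectory",
    "MAP_DOMAIN",
    "cup_kinematics",
    "simulate_ball",
    "inverse_dynamics_force",
    "simulate_strategy",
    "forward_simulate",
    "linear_mode_analysis",
]

#: Execution-variable ranges of the task (used by the map-domain validator):
#: frequency (Hz), peak-to-peak amplitude (m), initial ball angle (rad),
#: initial ball angular velocity (rad/s).
MAP_DOMAIN = {
    "frequency": (0.8, 1.2),
    "amplitude_pp": (0.08, 0.44),
    "theta0": (-math.pi / 2, math.pi / 2),
    "omega0": (-3.0, 3.0),
}

#: Columns of the delimited on-disk trajectory table, in order.
TRAJECTORY_COLUMNS = [
    "time_s",
    "force_N",
    "cup_pos_m",
    "cup_vel_mps",
    "cup_acc_mps2",
    "ball_ang_rad",
    "ball_angvel_radps",
    "phase_rad",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the cart-pendulum object (SI units)."""

    m_ball: float = 0.6
    m_cup: float = 2.4
    rod_length: float = 0.25
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name in ("m_ball", "m_cup", "rod_length", "gravity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def translating_mass(self) -> float:
        """Inertia translating rigidly with the hand (cup plus suspension)."""
        return self.m_cup + self.m_ball


@dataclass(frozen=True)
class Strategy:
    """One point of result space: the four scalar execution variables.

    Parameters
    ----------
    amplitude_pp
        Full peak-to-peak cup displacement (m).
    frequency
        Cup oscillation frequency (Hz).
    theta0
        Ball angle at the ``t = 0`` cup peak (rad), positive anti-phase.
    omega0
        Ball angular velocity at the ``t = 0`` cup peak (rad/s).
    """

    amplitude_pp: float
    frequency: float
    theta0: float
    omega0: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError("frequency must be > 0")
        if self.amplitude_pp < 0:
            raise ValueError("amplitude_pp must be >= 0")

    def in_map_domain(self) -> bool:
        """True if all four execution variables lie inside the task ranges."""
        lo_f, hi_f = MAP_DOMAIN["frequency"]
        lo_a, hi_a = MAP_DOMAIN["amplitude_pp"]
        lo_t, hi_t = MAP_DOMAIN["theta0"]
        lo_w, hi_w = MAP_DOMAIN["omega0"]
        return (
            lo_f <= self.frequency <= hi_f
            and lo_a <= self.amplitude_pp <= hi_a
            and lo_t <= self.theta0 <= hi_t
            and lo_w <= self.omega0 <= hi_w
        )

    def perturbed(self, **deltas: float) -> "Strategy":
        """Return a copy with the given execution variables incremented."""
        return replace(
            self, **{k: getattr(self, k) + dv for k, dv in deltas.items()}
        )


@dataclass
class Trajectory:
    """Uniformly sampled kinematics and force of one simulated performance.

    All channels share one length; ``phase`` is the cup phase in [0, 2*pi).
    A freshly simulated trajectory may carry NaN in ``force`` until
    :func:`inverse_dynamics_force` fills it.
    """

    time: np.ndarray
    cup_pos: np.ndarray
    cup_vel: np.ndarray
    cup_acc: np.ndarray
    ball_ang: np.ndarray
    ball_angvel: np.ndarray
    force: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("cup_pos", "cup_vel", "cup_acc", "ball_ang",
                     "ball_angvel", "force", "phase"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time length")
        dt = np.diff(self.time)
        if n >= 2 and (dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def rate(self) -> float:
        """Sampling rate (Hz)."""
        return 1.0 / float(self.time[1] - self.time[0])

    def ball_ode_residual(self, params: ModelParams) -> np.ndarray:
        """Residual of the ball equation with finite-difference theta''.

        ``l*theta'' - (x''*cos(theta) - g*sin(theta))`` evaluated with a
        second-order central-difference estimate of ``theta''`` from the
        stored angular velocity.  The discretisation error is
        O(h^2 * max|theta''''|), so at 120 Hz a smooth trajectory shows
        residuals of order 0.01-0.1 rad/s^2 rather than integrator tolerance.
        """
        thdd_fd = np.gradient(self.ball_angvel, self.time)
        rhs = (self.cup_acc * np.cos(self.ball_ang)
               - params.gravity * np.sin(self.ball_ang)) / params.rod_length
        return params.rod_length * (thdd_fd - rhs)

    def force_residual(self, params: ModelParams) -> np.ndarray:
        """Residual of the force equation at every sample (N).

        theta'' is eliminated through the ball equation, so this checks the
        stored force channel against the stored kinematic channels exactly.
        """
        return self.force - _hand_force(
            self.cup_acc, self.ball_ang, self.ball_angvel, params
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "force_N": self.force,
                "cup_pos_m": self.cup_pos,
                "cup_vel_mps": self.cup_vel,
                "cup_acc_mps2": self.cup_acc,
                "ball_ang_rad": self.ball_ang,
                "ball_angvel_radps": self.ball_angvel,
                "phase_rad": self.phase,
            }
        )

    def save(self, path) -> None:
        """Write the trajectory as a delimited text table (or HDF5 if *.h5)."""
        path = str(path)
        if path.endswith((".h5", ".hdf5")):
            import h5py

            with h5py.File(path, "w") as fh:
                for col, arr in zip(TRAJECTORY_COLUMNS, self._arrays()):
                    fh.create_dataset(col, data=arr)
        else:
            self.to_frame().to_csv(path, index=False)

    def _arrays(self):
        return (self.time, self.force, self.cup_pos, self.cup_vel,
                self.cup_acc, self.ball_ang, self.ball_angvel, self.phase)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            time=df["time_s"].to_numpy(float),
            force=df["force_N"].to_numpy(float),
            cup_pos=df["cup_pos_m"].to_numpy(float),
            cup_vel=df["cup_vel_mps"].to_numpy(float),
            cup_acc=df["cup_acc_mps2"].to_numpy(float),
            ball_ang=df["ball_ang_rad"].to_numpy(float),
            ball_angvel=df["ball_angvel_radps"].to_numpy(float),
            phase=df["phase_rad"].to_numpy(float),
        )

    @classmethod
    def load(cls, path) -> "Trajectory":
        path = str(path)
        if path.endswith((".h5", ".hdf5")):
            import h5py

            with h5py.File(path, "r") as fh:
                df = pd.DataFrame({c: fh[c][...] for c in TRAJECTORY_COLUMNS})
        else:
            df = pd.read_csv(path)
        return cls.from_frame(df)


def _check_uniform(time_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("time grid must be a 1-D array with >= 2 samples")
    dt = np.diff(t)
    if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time grid must be strictly increasing and uniform")
    return t


def cup_kinematics(strategy: Strategy, time_grid: np.ndarray):
    """Analytic cup position, velocity and acceleration on a uniform grid.

    Peak-aligned cosine: ``x(t) = (A_pp/2) * cos(2*pi*f*t)``, so the cup sits
    at its positive peak at ``t = 0`` where the ball state is defined.
    """
    t = _check_uniform(time_grid)
    w = 2.0 * math.pi * strategy.frequency
    a = strategy.amplitude_pp / 2.0
    pos = a * np.cos(w * t)
    vel = -a * w * np.sin(w * t)
    acc = -a * w * w * np.cos(w * t)
    return pos, vel, acc


def cup_phase(strategy: Strategy, time_grid: np.ndarray) -> np.ndarray:
    """Cup phase ``(2*pi*f*t) mod 2*pi``; zero at every positive cup peak."""
    t = np.asarray(time_grid, dtype=float)
    return np.mod(2.0 * math.pi * strategy.frequency * t, 2.0 * math.pi)


def _ball_rhs_factory(strategy: Strategy, params: ModelParams):
    w = 2.0 * math.pi * strategy.frequency
    a = strategy.amplitude_pp / 2.0
    g = params.gravity
    l = params.rod_length

    def rhs(t, y):
        th, om = y
        xdd = -a * w * w * math.cos(w * t)
        return (om, (xdd * math.cos(th) - g * math.sin(th)) / l)

    return rhs


def simulate_ball(
    strategy: Strategy,
    params: ModelParams = ModelParams(),
    duration: float = 45.0,
    rate: float = 120.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the driven ball under a prescribed sinusoidal cup motion.

    Returns a :class:`Trajectory` with cup and ball channels filled and the
    force channel NaN (fill it with :func:`inverse_dynamics_force`).
    Deterministic for fixed inputs; adaptive Runge-Kutta (RK45) with the
    stated tolerances, dense output resampled on the uniform grid.
    """
    if duration < 1.0 / strategy.frequency:
        raise ValueError("duration must cover at least one cup period")
    n = int(round(duration * rate))
    t = np.arange(n + 1) / rate
    sol = solve_ivp(
        _ball_rhs_factory(strategy, params),
        (0.0, float(t[-1])),
        (strategy.theta0, strategy.omega0),
        t_eval=t,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(
            f"ball integration failed for {strategy}: {sol.message}"
        )
    pos, vel, acc = cup_kinematics(strategy, t)
    return Trajectory(
        time=t,
        cup_pos=pos,
        cup_vel=vel,
        cup_acc=acc,
        ball_ang=sol.y[0],
        ball_angvel=sol.y[1],
        force=np.full_like(t, np.nan),
        phase=cup_phase(strategy, t),
    )


def _hand_force(cup_acc, ball_ang, ball_angvel, params: ModelParams):
    """Hand force with theta'' eliminated through the ball equation."""
    g, l = params.gravity, params.rod_length
    mb = params.m_ball
    s, c = np.sin(ball_ang), np.cos(ball_ang)
    thdd = (cup_acc * c - g * s) / l
    return (params.translating_mass + mb) * cup_acc - mb * l * (
        thdd * c - ball_angvel**2 * s
    )


def inverse_dynamics_force(
    trajectory: Trajectory,
    params: ModelParams = ModelParams(),
    residual_tol: float | None = None,
) -> Trajectory:
    """Fill the force channel by inverse dynamics (in place; also returned).

    The ball channels must satisfy the ball equation; consistency is checked
    with a finite-difference residual whose tolerance defaults to an
    O(h^2)-aware bound (see :meth:`Trajectory.ball_ode_residual`).
    """
    res = trajectory.ball_ode_residual(params)
    # interior samples only: np.gradient is first-order at the ends
    interior = np.abs(res[2:-2]).max() if len(res) > 4 else np.abs(res).max()
    if residual_tol is None:
        h = 1.0 / trajectory.rate
        # h^2/6 * |l*theta''''| with a generous curvature scale for the
        # driven pendulum (|theta''''| ~ (g/l)^2 * a few)
        residual_tol = max(10.0 * h**2 * (params.gravity / params.rod_length) ** 2, 1e-6)
    if interior > residual_tol:
        raise ValueError(
            "ball channels inconsistent with the ball equation: "
            f"max residual {interior:.3g} rad/s^2 exceeds {residual_tol:.3g}"
        )
    trajectory.force = _hand_force(
        trajectory.cup_acc, trajectory.ball_ang, trajectory.ball_angvel, params
    )
    return trajectory


def simulate_strategy(
    strategy: Strategy,
    params: ModelParams = ModelParams(),
    duration: float = 45.0,
    rate: float = 120.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Simulate the ball and fill the force channel in one call."""
    traj = simulate_ball(strategy, params, duration, rate, rtol, atol)
    traj.force = _hand_force(traj.cup_acc, traj.ball_ang, traj.ball_angvel, params)
    return traj


def forward_simulate(
    force: np.ndarray,
    time_grid: np.ndarray,
    params: ModelParams = ModelParams(),
    initial_state=(0.0, 0.0, 0.0, 0.0),
    rtol: float = 1e-8,
    atol: float = 1e-8,
    max_step: float | None = None,
) -> Trajectory:
    """Integrate the full four-state object under an applied force series.

    The force is interpolated piecewise-linearly inside the integrator, and
    the solver step is capped at one force-sample interval by default so the
    integrator never steps across interpolation kinks uncontrolled.  The
    cart equation is the same hand-force convention used by inverse dynamics
    (translating inertia ``m_cup + m_ball``), so feeding back an
    inverse-dynamics force reproduces the prescribed cup trajectory.

    Parameters
    ----------
    initial_state
        ``(x, x', theta, theta')`` at ``t = time_grid[0]``.
    """
    t = _check_uniform(time_grid)
    f = np.asarray(force, dtype=float)
    if len(f) != len(t):
        raise ValueError("force and time grid lengths differ")
    g, l = params.gravity, params.rod_length
    mb, mtr = params.m_ball, params.translating_mass
    t0 = t[0]
    dt = t[1] - t[0]
    n_last = len(t) - 1

    def rhs(tt, y):
        x, xd, th, om = y
        # inline linear interpolation (cheaper than np.interp per call)
        u = (tt - t0) / dt
        i = min(int(u), n_last - 1)
        fi = f[i] + (f[i + 1] - f[i]) * (u - i)
        s, c = math.sin(th), math.cos(th)
        xdd = (fi - mb * s * (g * c + l * om * om)) / (mtr + mb * s * s)
        thdd = (xdd * c - g * s) / l
        return (xd, xdd, om, thdd)

    sol = solve_ivp(rhs, (t[0], t[-1]), initial_state, t_eval=t,
                    rtol=rtol, atol=atol, method="RK45",
                    max_step=dt if max_step is None else max_step)
    if not sol.success:
        raise RuntimeError(f"forward integration failed: {sol.message}")
    x, xd, th, om = sol.y
    s, c = np.sin(th), np.cos(th)
    xdd = (f - mb * s * (g * c + l * om**2)) / (mtr + mb * s**2)
    # phase from the cup trajectory is undefined without a prescribed
    # sinusoid; store NaN and let callers derive one if needed
    return Trajectory(
        time=t, cup_pos=x, cup_vel=xd, cup_acc=xdd,
        ball_ang=th, ball_angvel=om, force=f,
        phase=np.full_like(t, np.nan),
    )


def total_energy(traj: Trajectory, params: ModelParams = ModelParams()) -> np.ndarray:
    """Mechanical energy of the object per sample (J), for F = 0 checks.

    Kinetic energy of the translating unit (mass ``m_cup + m_ball``) plus the
    pendulum bob, plus gravitational potential of the bob.
    """
    g, l, mb = params.gravity, params.rod_length, params.m_ball
    mtr = params.translating_mass
    # bob velocity: x_b = x - l sin(theta)  =>  x_b' = x' - l th' cos, y_b' = l th' sin
    vxb = traj.cup_vel - l * traj.ball_angvel * np.cos(traj.ball_ang)
    vyb = l * traj.ball_angvel * np.sin(traj.ball_ang)
    ke = 0.5 * mtr * traj.cup_vel**2 + 0.5 * mb * (vxb**2 + vyb**2)
    pe = mb * g * l * (1.0 - np.cos(traj.ball_ang))
    return ke + pe


def linear_mode_analysis(params: ModelParams = ModelParams()) -> dict:
    """Vibration modes of the free (F = 0) conservative object.

    Linearises the bare cart-pendulum (cup mass alone translating, as in the
    classic two-degree-of-freedom treatment) about the hanging equilibrium in
    generalised coordinates (x, theta) and solves the generalised
    eigenproblem ``K v = omega^2 M v``.  Returns the zero-frequency
    free-motion mode and the anti-phase oscillation mode, whose frequency is

        f = (1/2pi) * sqrt((g/l) * (1 + m_ball/m_cup))

    plus the largest possible free-oscillation peak-to-peak cup amplitude,
    ``2*l*m_ball/(m_ball + m_cup)``, from the stationary-centre-of-mass
    constraint with ball excursion bounded by the rod length.
    """
    from scipy.linalg import eigh

    mb, mc = params.m_ball, params.m_cup
    g, l = params.gravity, params.rod_length
    # KE ~ 1/2 (mc+mb) x'^2 - mb l x' th' + 1/2 mb l^2 th'^2 ; PE ~ 1/2 mb g l th^2
    M = np.array([[mc + mb, -mb * l], [-mb * l, mb * l * l]])
    K = np.array([[0.0, 0.0], [0.0, mb * g * l]])
    w2, vecs = eigh(K, M)
    w2 = np.clip(w2, 0.0, None)
    freqs = np.sqrt(w2) / (2.0 * math.pi)
    order = np.argsort(freqs)
    freqs = freqs[order]
    vecs = vecs[:, order]
    anti = vecs[:, -1]
    # normalise the anti-phase shape to unit ball angle
    if anti[1] != 0:
        anti = anti / anti[1]
    return {
        "mode_frequencies": freqs,
        "antiphase_mode_shape": anti,  # (cup displacement, ball angle)
        "max_free_cup_amplitude_pp": 2.0 * l * mb / (mb + mc),
    }
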