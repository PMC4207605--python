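"""Per-strategy measures of the rhythmic manipulation task.

Each rhythmic strategy is scored by how predictable, effortful and smooth the
required hand force and the resulting ball kinematics are:

* stroboscopic sampling of force and ball state at positive cup-position
  peaks (a Poincare section of the driven system), and bifurcation scans of
  the strobed-force distribution over the initial ball angle;
* Mutual Information between the continuous force and the cup phase
  (kernel-density estimate, natural log, units nat) and its Sensitivity to
  perturbations of the execution variables;
* a Predictability Index summarising the strobed-force scatter;
* the largest finite-time Lyapunov exponent of the driven ball subsystem;
* Mean Squared Force (signal power of the hand force, N^2);
* mean absolute jerk (raw and amplitude-normalised) and the spectral
  arc-length smoothness measure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .dynamics import ModelParams, Strategy, Trajectory, simulate_strategy

__all__ = [
    "StrobeSeries",
    "MeasureSet",
    "strobe_at_cup_peaks",
    "bifurcation_scan",
    "mutual_information",
    "predictability_index",
    "mi_sensitivity",
    "global_lyapunov",
    "mean_squared_force",
    "mean_abs_jerk",
    "spectral_arc_length",
    "measure_strategy",
]


@dataclass
class StrobeSeries:
    """Signals sampled once per cycle at positive cup-position maxima."""

    peak_times: np.ndarray
    force_at_peak: np.ndarray
    ball_ang_at_peak: np.ndarray
    ball_angvel_at_peak: np.ndarray
    cycle_period: np.ndarray      # one shorter: spacing of successive maxima
    cycle_amplitude_pp: np.ndarray  # one shorter: peak minus following trough

    def __post_init__(self) -> None:
        n = len(self.peak_times)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        for name in ("force_at_peak", "ball_ang_at_peak", "ball_angvel_at_peak"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of peaks")
        for name in ("cycle_period", "cycle_amplitude_pp"):
            if len(getattr(self, name)) != n - 1:
                raise ValueError(f"{name} must have one element per cycle")

    @property
    def force_variance(self) -> float:
        return float(np.var(self.force_at_peak))


@dataclass
class MeasureSet:
    """All strategy measures for one strategy or one trial."""

    mi: float = np.nan                    # nat
    predictability_index: float = np.nan  # dimensionless, in [0, 1]
    sensitivity: float = np.nan           # dimensionless
    gle: float = np.nan                   # 1/s
    msf: float = np.nan                   # N^2
    jerk_ball_norm: float = np.nan        # dimensionless (ball displacement)
    jerk_ball_raw: float = np.nan         # m/s^3 (ball displacement)
    jerk_force_raw: float = np.nan        # N/s^3
    jerk_force_norm: float = np.nan       # dimensionless
    jerk_cup_raw: float = np.nan          # m/s^3
    sal: float = np.nan                   # dimensionless, <= 0
    strobe_force_variance: float = np.nan      # N^2
    strobe_force_variance_rel: float = np.nan  # dimensionless

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _peak_indices(x: np.ndarray, min_distance: int) -> np.ndarray:
    """Local maxima including closed-interval endpoint maxima."""
    idx, _ = find_peaks(x, distance=max(min_distance, 1))
    ends = []
    if len(x) >= 2 and x[0] >= x[1]:
        ends.append(0)
    if len(x) >= 2 and x[-1] >= x[-2]:
        ends.append(len(x) - 1)
    if ends:
        idx = np.sort(np.concatenate([idx, ends]).astype(int))
        # enforce the minimum separation against endpoint duplicates
        keep = [idx[0]]
        for i in idx[1:]:
            if i - keep[-1] >= min_distance:
                keep.append(i)
        idx = np.asarray(keep)
    return idx


def strobe_at_cup_peaks(
    trajectory: Trajectory, nominal_frequency: float | None = None
) -> StrobeSeries:
    """Sample force and ball state at every positive cup-position maximum.

    Maxima only (not minima); for peak-aligned simulated trajectories the
    ``t = 0`` peak and, when the duration is an integer number of periods,
    the final-sample peak are both included.
    """
    x = trajectory.cup_pos
    if np.ptp(x) == 0:
        raise ValueError("cup position is constant: no peaks to strobe")
    if nominal_frequency is None:
        # dominant frequency from the phase channel if present, else 1 Hz
        dph = np.diff(trajectory.phase)
        if np.all(np.isfinite(dph)):
            nominal_frequency = float(
                np.median(dph[dph > 0]) * trajectory.rate / (2 * math.pi)
            )
        else:
            nominal_frequency = 1.0
    min_sep = int(0.5 * trajectory.rate / nominal_frequency)
    idx = _peak_indices(x, min_sep)
    # positive maxima only: discard spurious ripples below the midline
    idx = idx[x[idx] > np.median(x)]
    if len(idx) < 2:
        raise ValueError("fewer than two positive cup-position maxima found")
    t_pk = trajectory.time[idx]
    # per-cycle peak-to-trough amplitude (peak minus minimum before next peak)
    amps = np.empty(len(idx) - 1)
    for k in range(len(idx) - 1):
        amps[k] = x[idx[k]] - x[idx[k]:idx[k + 1] + 1].min()
    return StrobeSeries(
        peak_times=t_pk,
        force_at_peak=trajectory.force[idx],
        ball_ang_at_peak=trajectory.ball_ang[idx],
        ball_angvel_at_peak=trajectory.ball_angvel[idx],
        cycle_period=np.diff(t_pk),
        cycle_amplitude_pp=amps,
    )


def bifurcation_scan(
    theta0_grid,
    fixed: dict | None = None,
    params: ModelParams = ModelParams(),
    duration: float = 45.0,
    rate: float = 120.0,
):
    """Strobed-force distributions as a function of the initial ball angle.

    Returns a list of records ``{"theta0", "forces", "min", "max", "var"}``;
    per-point integrator failures are logged into the record (``"error"``)
    rather than aborting the scan.
    """
    fixed = {"amplitude_pp": 0.10, "frequency": 1.0, "omega0": 0.0, **(fixed or {})}
    out = []
    for th0 in np.atleast_1d(np.asarray(theta0_grid, dtype=float)):
        rec = {"theta0": float(th0)}
        try:
            strat = Strategy(
                amplitude_pp=fixed["amplitude_pp"],
                frequency=fixed["frequency"],
                theta0=float(th0),
                omega0=fixed["omega0"],
            )
            traj = simulate_strategy(strat, params, duration, rate)
            f = strobe_at_cup_peaks(traj, strat.frequency).force_at_peak
            rec.update(
                forces=f, min=float(f.min()), max=float(f.max()), var=float(f.var())
            )
        except Exception as exc:  # pragma: no cover - integrator failures
            warnings.warn(f"bifurcation point theta0={th0}: {exc}")
            rec["error"] = str(exc)
        out.append(rec)
    return out


def _silverman(x: np.ndarray) -> float:
    return 1.06 * float(np.std(x)) * len(x) ** (-0.2)


def mutual_information(
    force: np.ndarray,
    phase: np.ndarray,
    n_grid: int = 128,
    min_cycles: int = 10,
) -> float:
    """Mutual Information between force and cup phase, in nat.

    The joint density p(F, phi) is a product-Gaussian kernel estimate with
    per-dimension Silverman bandwidths, evaluated on an ``n_grid x n_grid``
    lattice spanning [min - 3h, max + 3h] in force and [0, 2*pi) in phase.
    Phase circularity is handled by replicating the sample at phi +/- 2*pi.
    Marginals are obtained by integrating the joint, and MI by trapezoidal
    summation of p*ln(p/(pF*pphi)).  The estimate is exactly invariant under
    affine rescaling of the force (bandwidth and grid co-transform).
    """
    f = np.asarray(force, dtype=float)
    ph = np.asarray(phase, dtype=float)
    if f.shape != ph.shape or f.ndim != 1:
        raise ValueError("force and phase must be equal-length 1-D arrays")
    n_cycles = (np.diff(ph) < -math.pi).sum() + 1
    if n_cycles < min_cycles:
        raise ValueError(f"need >= {min_cycles} cycles of data, got {n_cycles}")
    hf = _silverman(f)
    hp = _silverman(ph)
    if hf <= 0:
        warnings.warn("constant force series: MI defined as 0")
        return 0.0
    n = len(f)
    fg = np.linspace(f.min() - 3 * hf, f.max() + 3 * hf, n_grid)
    pg = np.linspace(0.0, 2.0 * math.pi, n_grid, endpoint=False)
    kf = np.exp(-0.5 * ((fg[:, None] - f[None, :]) / hf) ** 2)
    kp = np.zeros((n_grid, n))
    for shift in (0.0, 2.0 * math.pi, -2.0 * math.pi):
        kp += np.exp(-0.5 * ((pg[:, None] - (ph + shift)[None, :]) / hp) ** 2)
    joint = kf @ kp.T
    df = fg[1] - fg[0]
    dp = pg[1] - pg[0]
    joint /= joint.sum() * df * dp
    p_f = joint.sum(axis=1) * dp
    p_p = joint.sum(axis=0) * df
    mask = joint > 0
    outer = np.outer(p_f, p_p)
    mi = float((joint[mask] * np.log(joint[mask] / outer[mask])).sum() * df * dp)
    return max(mi, 0.0)


def predictability_index(variance: float, normalizer: float) -> float:
    """``1 - variance/normalizer`` clipped to [0, 1].

    ``variance`` is a strobed-force scatter summary — either the raw variance
    (N^2) or the variance relative to the continuous-force variance
    (dimensionless) — and ``normalizer`` the reference value that maps to
    zero predictability (by default the maximum over the evaluated map).
    """
    if not normalizer > 0:
        raise ValueError("normalizer must be > 0")
    return float(np.clip(1.0 - variance / normalizer, 0.0, 1.0))


#: 10 %-of-range perturbation steps for Sensitivity: frequency (Hz),
#: peak-to-peak amplitude (m), initial ball angle (rad).
SENSITIVITY_DELTAS = {"frequency": 0.04, "amplitude_pp": 0.036, "theta0": math.pi / 10}


def mi_sensitivity(
    strategy: Strategy,
    params: ModelParams = ModelParams(),
    mi_range: float = 1.0,
    duration: float = 45.0,
    rate: float = 120.0,
    base_mi: float | None = None,
) -> float:
    """Maximum MI deviation under 10 %-of-range execution-variable changes.

    Perturbs frequency, amplitude and initial angle (not omega0) by plus and
    minus one step each; Sensitivity is max |delta MI| / (0.1 * mi_range),
    with ``mi_range`` the MI span over the evaluated map.  Perturbations
    leaving the simulable domain are skipped with a warning.
    """
    if base_mi is None:
        traj = simulate_strategy(strategy, params, duration, rate)
        base_mi = mutual_information(traj.force, traj.phase)
    dev = 0.0
    for name, step in SENSITIVITY_DELTAS.items():
        for sign in (+1.0, -1.0):
            new_value = getattr(strategy, name) + sign * step
            if (name == "frequency" and new_value <= 0) or (
                name == "amplitude_pp" and new_value < 0
            ):
                warnings.warn(
                    f"sensitivity perturbation {name}{sign:+} leaves domain; skipped"
                )
                continue
            pert = strategy.perturbed(**{name: sign * step})
            traj = simulate_strategy(pert, params, duration, rate)
            mi = mutual_information(traj.force, traj.phase)
            dev = max(dev, abs(mi - base_mi))
    return dev / (0.1 * mi_range)


def _tangent_exponent(accel_coef: np.ndarray, step: float, n_steps: int) -> float:
    """Largest exponent from RK4 propagation of the variational dynamics.

    ``accel_coef`` holds d(theta'')/d(theta) along the reference trajectory,
    sampled at half-steps (length ``2*n_steps + 1``).  Two tangent vectors
    (unit theta and unit theta' directions) are propagated together and
    renormalised every step; the larger average log growth is returned.
    """
    u = np.array([[1.0, 0.0], [0.0, 1.0]])  # columns are the two vectors
    logsum = np.zeros(2)
    h = step
    for k in range(n_steps):
        a0 = accel_coef[2 * k]
        am = accel_coef[2 * k + 1]
        a1 = accel_coef[2 * k + 2]
        k1 = np.vstack([u[1], a0 * u[0]])
        v = u + 0.5 * h * k1
        k2 = np.vstack([v[1], am * v[0]])
        v = u + 0.5 * h * k2
        k3 = np.vstack([v[1], am * v[0]])
        v = u + h * k3
        k4 = np.vstack([v[1], a1 * v[0]])
        u = u + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        norms = np.sqrt((u**2).sum(axis=0))
        logsum += np.log(norms)
        u /= norms
    return float(logsum.max() / (n_steps * step))


def global_lyapunov(
    strategy: Strategy,
    params: ModelParams = ModelParams(),
    duration: float = 60.0,
    step: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> float:
    """Largest finite-time Lyapunov exponent of the driven ball (1/s).

    Integrates the tangent (variational) dynamics along the reference ball
    trajectory with Jacobian ``[[0, 1], [(x''*(-sin th) - g*cos th)/l, 0]]``,
    renormalising every ``step``; the exponent is the average log growth,
    computed separately from unit vectors along theta and theta' and
    reported as the larger.  Finite-time estimates carry a transient bias of
    order ``ln(omega_pendulum)/duration`` (about 0.03 1/s at 60 s), which
    matters when resolving near-zero exponents; use a longer duration there.
    """
    if duration < 10.0:
        raise ValueError("duration < 10 s gives unreliable exponent estimates")
    n_steps = int(round(duration / step))
    t_half = np.arange(2 * n_steps + 1) * (step / 2.0)
    w = 2.0 * math.pi * strategy.frequency
    a = strategy.amplitude_pp / 2.0
    from .dynamics import _ball_rhs_factory

    sol = solve_ivp(
        _ball_rhs_factory(strategy, params),
        (0.0, float(t_half[-1])),
        (strategy.theta0, strategy.omega0),
        t_eval=t_half,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    th = sol.y[0]
    xdd = -a * w * w * np.cos(w * t_half)
    accel_coef = (-xdd * np.sin(th) - params.gravity * np.cos(th)) / params.rod_length
    return _tangent_exponent(accel_coef, step, n_steps)


def global_lyapunov_batch(
    strategies,
    params: ModelParams = ModelParams(),
    duration: float = 240.0,
    step: float = 0.0025,
) -> np.ndarray:
    """Finite-time largest Lyapunov exponents for many strategies at once.

    Fixed-step RK4 (step ``step``) advances all reference ball trajectories
    and both tangent vectors per strategy simultaneously, renormalising
    every step (the renormalisation cadence does not affect the exponent —
    log growth factors telescope).  Intended for result-space maps, where
    the long horizon needed to push the finite-time transient bias below
    the smallest exponents makes per-cell adaptive integration expensive.
    """
    strategies = list(strategies)
    m = len(strategies)
    g, l = params.gravity, params.rod_length
    amp = np.array([s.amplitude_pp / 2.0 for s in strategies])
    w = np.array([2.0 * math.pi * s.frequency for s in strategies])
    th = np.array([s.theta0 for s in strategies], dtype=float)
    om = np.array([s.omega0 for s in strategies], dtype=float)
    u = np.broadcast_to(np.eye(2)[:, :, None], (2, 2, m)).copy()
    logsum = np.zeros((2, m))
    n_steps = int(round(duration / step))
    h = step

    def acc(tt, theta):
        xdd = -amp * w * w * np.cos(w * tt)
        return (xdd * np.cos(theta) - g * np.sin(theta)) / l

    def jcoef(tt, theta):
        xdd = -amp * w * w * np.cos(w * tt)
        return (-xdd * np.sin(theta) - g * np.cos(theta)) / l

    t = 0.0
    for _ in range(n_steps):
        # reference RK4
        k1t, k1o = om, acc(t, th)
        th2, om2 = th + 0.5 * h * k1t, om + 0.5 * h * k1o
        k2t, k2o = om2, acc(t + 0.5 * h, th2)
        th3, om3 = th + 0.5 * h * k2t, om + 0.5 * h * k2o
        k3t, k3o = om3, acc(t + 0.5 * h, th3)
        th4, om4 = th + h * k3t, om + h * k3o
        k4t, k4o = om4, acc(t + h, th4)
        # tangent RK4 with the Jacobian along the reference stages
        a0 = jcoef(t, th)
        am = jcoef(t + 0.5 * h, th2)
        a1 = jcoef(t + h, th4)
        K1 = np.stack([u[1], a0 * u[0]])
        v = u + 0.5 * h * K1
        K2 = np.stack([v[1], am * v[0]])
        v = u + 0.5 * h * K2
        K3 = np.stack([v[1], am * v[0]])
        v = u + h * K3
        K4 = np.stack([v[1], a1 * v[0]])
        u = u + (h / 6.0) * (K1 + 2 * K2 + 2 * K3 + K4)
        th = th + (h / 6.0) * (k1t + 2 * k2t + 2 * k3t + k4t)
        om = om + (h / 6.0) * (k1o + 2 * k2o + 2 * k3o + k4o)
        norms = np.sqrt((u**2).sum(axis=0))
        logsum += np.log(norms)
        u /= norms
        t += h
    return logsum.max(axis=0) / (n_steps * step)


def mean_squared_force(force: np.ndarray) -> float:
    """Time-averaged squared force (N^2) over the supplied span."""
    f = np.asarray(force, dtype=float)
    if f.size == 0:
        raise ValueError("empty force series")
    return float(np.mean(f**2))


def _third_derivative(signal: np.ndarray, rate: float) -> np.ndarray:
    """Repeated central differences; the 3 edge samples on each side are
    dropped (one-sided differences there would leak spurious jerk spikes)."""
    j = np.asarray(signal, dtype=float)
    for _ in range(3):
        j = np.gradient(j) * rate
    return j[3:-3] if len(j) > 8 else j


def mean_abs_jerk(signal: np.ndarray, rate: float, normalized: bool = True) -> float:
    """Mean absolute third derivative; optionally amplitude-normalised.

    Raw: mean |d^3 s/dt^3| in (signal units)/s^3.  Normalised: divided by
    the trial's maximum absolute jerk, making the measure dimensionless and
    amplitude-independent (a pure sinusoid gives 2/pi regardless of its
    amplitude and frequency).  A constant signal returns 0 in both variants.
    """
    s = np.asarray(signal, dtype=float)
    if len(s) < 4:
        raise ValueError("need >= 4 samples to estimate jerk")
    j = _third_derivative(s, rate)
    amax = np.abs(j).max()
    if amax == 0:
        return 0.0
    mean_j = float(np.abs(j).mean())
    return mean_j / float(amax) if normalized else mean_j


def spectral_arc_length(
    signal: np.ndarray,
    rate: float,
    cutoff: float = 20.0,
    amp_threshold: float = 0.05,
    zero_pad_factor: int = 4,
) -> float:
    """Spectral arc-length smoothness of a movement signal (dimensionless).

    Arc length of the max-normalised magnitude spectrum between 0 Hz and an
    adaptive cutoff (the highest frequency below ``cutoff`` whose normalised
    magnitude still exceeds ``amp_threshold``), with the frequency axis
    scaled to [0, 1].  More negative means less smooth; invariant to
    amplitude scaling of the signal.
    """
    s = np.asarray(signal, dtype=float)
    if len(s) < rate:
        raise ValueError("need at least 1 s of data")
    if np.ptp(s) == 0:
        raise ValueError("constant (or all-zero) signal has no spectrum")
    s = s - s.mean()
    nfft = int(2 ** math.ceil(math.log2(len(s)))) * zero_pad_factor
    mag = np.abs(np.fft.rfft(s, nfft))
    freq = np.fft.rfftfreq(nfft, 1.0 / rate)
    mag = mag / mag.max()
    sel = freq <= cutoff
    freq, mag = freq[sel], mag[sel]
    above = np.nonzero(mag >= amp_threshold)[0]
    if len(above) >= 2:
        freq, mag = freq[: above[-1] + 1], mag[: above[-1] + 1]
    df = np.diff(freq / freq[-1])
    dm = np.diff(mag)
    return -float(np.sqrt(df**2 + dm**2).sum())


def measure_strategy(
    strategy: Strategy,
    params: ModelParams = ModelParams(),
    duration: float = 45.0,
    rate: float = 120.0,
    gle_duration: float = 60.0,
    include_gle: bool = True,
) -> MeasureSet:
    """Simulate one strategy and fill every per-strategy measure.

    Predictability Index and Sensitivity need map-level normalisers and are
    left NaN here; see :mod:`ballincup.result_space`.
    """
    traj = simulate_strategy(strategy, params, duration, rate)
    strobe = strobe_at_cup_peaks(traj, strategy.frequency)
    fvar = traj.force.var()
    # ball smoothness is scored on the ball's translational displacement
    # (x_b = x - l sin(theta)): in-phase coordination carries the ball
    # smoothly with the cup, anti-phase makes its path rough
    ball_disp = traj.cup_pos - params.rod_length * np.sin(traj.ball_ang)
    ms = MeasureSet(
        mi=mutual_information(traj.force, traj.phase),
        msf=mean_squared_force(traj.force),
        jerk_ball_norm=mean_abs_jerk(ball_disp, rate, normalized=True),
        jerk_ball_raw=mean_abs_jerk(ball_disp, rate, normalized=False),
        jerk_force_raw=mean_abs_jerk(traj.force, rate, normalized=False),
        jerk_force_norm=mean_abs_jerk(traj.force, rate, normalized=True),
        jerk_cup_raw=mean_abs_jerk(traj.cup_pos, rate, normalized=False),
        sal=spectral_arc_length(ball_disp, rate),
        strobe_force_variance=strobe.force_variance,
        strobe_force_variance_rel=strobe.force_variance / fvar if fvar > 0 else 0.0,
    )
    if include_gle:
        ms.gle = global_lyapunov(strategy, params, duration=gle_duration)
    return ms
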