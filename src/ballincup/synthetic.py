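"""Synthetic trial and cohort generation.

No public deposit of the human recordings exists, so every pipeline stage is
exercised on synthetic subjects whose practice dynamics emulate the group
statistics of the original cohort: near-sinusoidal 1 Hz cup motion whose
peak-to-peak amplitude grows across ~50 practice trials from about 21.5 cm
toward about 28 cm, strobed ball angles settling in the anti-phase
half-plane near +0.95 rad, additive sensor and motor noise, and occasional
chaotic (in-phase) episodes early in practice.

Trials are realised physically: a feedforward force from inverse dynamics
of the per-trial target strategy plus a proportional-derivative correction
toward the target sinusoid drives the forward model, with white motor noise
added to the force.  The tracking controller is a synthesis device only —
it makes trials that look and behave like recordings — and is explicitly
not a model of the human controller.
"""

from __future__ import annotations

import math
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .dynamics import ModelParams, Strategy, simulate_strategy
from .experiment import TrialRecord

__all__ = [
    "CohortConfig",
    "generate_clean_trial",
    "generate_synthetic_subject",
    "generate_cohort",
    "sample_trial_targets",
]


@dataclass(frozen=True)
class CohortConfig:
    """Statistical structure of a synthetic practice cohort.

    Defaults emulate the original study's conditions: 8 subjects, 50 trials
    of 45 s at 120 Hz, amplitude learning from 21.45 cm to 28.03 cm
    peak-to-peak with a ~12-trial timescale, anti-phase target ball angle
    0.95 rad, and a 20 % chance of a chaotic (in-phase) episode in the
    earliest trials, decaying on the same timescale.
    """

    n_subjects: int = 8
    n_trials: int = 50
    trial_duration: float = 45.0
    rate: float = 120.0
    amplitude_start: float = 0.2145   # m, peak-to-peak
    amplitude_end: float = 0.2803     # m, peak-to-peak
    theta0_start: float = 0.85        # rad
    theta0_target: float = 0.95       # rad
    learning_timescale: float = 12.0  # trials
    amplitude_jitter_sd: float = 0.02   # m, trial-to-trial
    theta0_jitter_sd: float = 0.15      # rad, trial-to-trial
    motor_noise_sd: float = 1.0         # N
    sensor_noise_sd_pos: float = 0.001  # m
    sensor_noise_sd_ang: float = 0.005  # rad
    chaotic_episode_prob_early: float = 0.2
    chaotic_theta0: float = -1.2        # rad, in-phase episode target
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chaotic_episode_prob_early <= 1.0:
            raise ValueError("chaotic_episode_prob_early must be in [0, 1]")
        for name in ("amplitude_jitter_sd", "theta0_jitter_sd", "motor_noise_sd",
                     "sensor_noise_sd_pos", "sensor_noise_sd_ang"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("cohort must have >= 1 subject and >= 1 trial")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _metronome(duration: float, frequency: float = 1.0) -> np.ndarray:
    """2 Hz beep times aligned with the cup extrema of a peak-aligned cosine."""
    half = 0.5 / frequency
    return np.arange(0.0, duration + half / 2, half)


def generate_clean_trial(
    strategy: Strategy,
    duration: float = 45.0,
    rate: float = 120.0,
    params: ModelParams = ModelParams(),
    subject_id: str = "sim",
    trial_index: int = 0,
) -> TrialRecord:
    """Noiseless trial realised by inverse dynamics of one strategy."""
    traj = simulate_strategy(strategy, params, duration, rate)
    return TrialRecord(
        subject_id=subject_id,
        trial_index=trial_index,
        time=traj.time,
        force=traj.force,
        cup_pos=traj.cup_pos,
        ball_ang=traj.ball_ang,
        rate=rate,
        cup_vel=traj.cup_vel,
        ball_angvel=traj.ball_angvel,
        metronome_times=_metronome(duration, strategy.frequency),
    )


def sample_trial_targets(config: CohortConfig, rng: np.random.Generator):
    """Per-trial target strategies of one subject's practice trajectory.

    Amplitude follows an exponential learning curve from ``amplitude_start``
    to ``amplitude_end`` with the configured timescale plus Gaussian
    trial-to-trial jitter; the target ball angle approaches
    ``theta0_target`` the same way.  Early trials may be replaced by chaotic
    in-phase episodes with probability ``chaotic_episode_prob_early *
    exp(-(j-1)/timescale)``.  Returns a list of (Strategy, is_chaotic).
    """
    tau = config.learning_timescale
    targets = []
    for j in range(config.n_trials):
        decay = math.exp(-j / tau)
        a = config.amplitude_end + (config.amplitude_start - config.amplitude_end) * decay
        a += rng.normal(0.0, config.amplitude_jitter_sd)
        a = float(np.clip(a, 0.08, 0.44))
        chaotic = rng.random() < config.chaotic_episode_prob_early * decay
        if chaotic:
            th = config.chaotic_theta0 + rng.normal(0.0, config.theta0_jitter_sd)
        else:
            th = (config.theta0_target
                  + (config.theta0_start - config.theta0_target) * decay
                  + rng.normal(0.0, config.theta0_jitter_sd))
        th = float(np.clip(th, -math.pi / 2, math.pi / 2))
        targets.append((Strategy(a, 1.0, th, 0.0), chaotic))
    return targets


def _tracking_trials_batch(
    targets: list,
    params: ModelParams,
    duration: float,
    rate: float,
    motor_noise_sd: float,
    rng: np.random.Generator,
    kp: float = 1600.0,
    kd: float = 120.0,
    k_ball: float = 1.0,
    substeps: int = 2,
) -> tuple:
    """Forward-simulate a batch of trials under feedforward + PD control.

    The applied force is the inverse-dynamics feedforward of each trial's
    target strategy, a proportional-derivative correction toward the target
    sinusoid, a weak ball-swing damping term ``-k_ball * theta'`` (emulating
    the stabilising corrections human subjects apply — without it the
    undamped pendulum slowly absorbs motor-noise energy until it rotates),
    and white Gaussian motor noise.  Integration is fixed-step RK4 at
    ``substeps * rate``, vectorised across trials; bit-reproducible for a
    given generator state.

    Returns arrays (time (n,), force (m,n), cup_pos, cup_vel, ball_ang,
    ball_angvel) with ``m = len(targets)`` trials.
    """
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    m = len(targets)
    g, l = params.gravity, params.rod_length
    mb, mtr = params.m_ball, params.translating_mass
    # fine grid for the integrator
    nf = (n - 1) * substeps + 1
    tf = np.arange(nf) / (rate * substeps)
    ff = np.empty((m, nf))
    noise = np.empty((m, nf))
    x_t = np.empty((m, nf))
    xd_t = np.empty((m, nf))
    for j, target in enumerate(targets):
        clean = simulate_strategy(target, params, duration, rate)
        ff[j] = np.interp(tf, t, clean.force)
        noise[j] = np.interp(tf, t, rng.normal(0.0, motor_noise_sd, n))
        w = 2 * math.pi * target.frequency
        a = target.amplitude_pp / 2
        x_t[j] = a * np.cos(w * tf)
        xd_t[j] = -a * w * np.sin(w * tf)
    h = 1.0 / (rate * substeps)
    x = np.array([tg.amplitude_pp / 2 for tg in targets])
    xd = np.zeros(m)
    th = np.array([tg.theta0 for tg in targets])
    om = np.array([tg.omega0 for tg in targets])
    out = np.empty((4, m, n))
    out[:, :, 0] = (x, xd, th, om)
    f_rec = np.empty((m, n))

    def deriv(state, drive):
        x, xd, th, om = state
        f_ff, f_ns, xt, xdt = drive
        f = f_ff + f_ns + kp * (xt - x) + kd * (xdt - xd) - k_ball * om
        s, c = np.sin(th), np.cos(th)
        xdd = (f - mb * s * (g * c + l * om * om)) / (mtr + mb * s * s)
        return np.array([xd, xdd, om, (xdd * c - g * s) / l]), f

    state = np.array([x, xd, th, om])
    drive0 = np.array([ff[:, 0], noise[:, 0], x_t[:, 0], xd_t[:, 0]])
    f_rec[:, 0] = deriv(state, drive0)[1]
    for k in range(nf - 1):
        d0 = np.array([ff[:, k], noise[:, k], x_t[:, k], xd_t[:, k]])
        d1 = np.array([ff[:, k + 1], noise[:, k + 1], x_t[:, k + 1], xd_t[:, k + 1]])
        dm = 0.5 * (d0 + d1)
        k1, _ = deriv(state, d0)
        k2, _ = deriv(state + 0.5 * h * k1, dm)
        k3, _ = deriv(state + 0.5 * h * k2, dm)
        k4, _ = deriv(state + h * k3, d1)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if (k + 1) % substeps == 0:
            i = (k + 1) // substeps
            out[:, :, i] = state
            f_rec[:, i] = deriv(state, d1)[1]
    return t, f_rec, out[0], out[1], out[2], out[3]


def generate_synthetic_subject(
    config: CohortConfig,
    subject_seed: int,
    subject_id: str | None = None,
    params: ModelParams = ModelParams(),
) -> list:
    """All practice trials of one synthetic subject (seeded, reproducible)."""
    rng = np.random.default_rng(subject_seed)
    if subject_id is None:
        subject_id = f"S{subject_seed:04d}"
    targets = sample_trial_targets(config, rng)
    t, f, x, xd, th, om = _tracking_trials_batch(
        [tg for tg, _ in targets], params,
        config.trial_duration, config.rate, config.motor_noise_sd, rng,
    )
    trials = []
    for j in range(len(targets)):
        x_rec = x[j] + rng.normal(0.0, config.sensor_noise_sd_pos, len(t))
        # the recorded ball coordinate is its angular position on the cup
        # arc, wrapped to (-pi, pi]; chaotic episodes can pass over the top
        th_rec = th[j] + rng.normal(0.0, config.sensor_noise_sd_ang, len(t))
        th_rec = np.mod(th_rec + math.pi, 2 * math.pi) - math.pi
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                trial_index=j + 1,
                time=t,
                force=f[j],
                cup_pos=x_rec,
                ball_ang=th_rec,
                rate=config.rate,
                cup_vel=xd[j],
                ball_angvel=om[j],
                metronome_times=_metronome(config.trial_duration),
            )
        )
    return trials


def subject_seeds(config: CohortConfig) -> list:
    """Per-subject integer seeds derived from the cohort seed."""
    root = np.random.SeedSequence(config.seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(config.n_subjects)]


def generate_cohort(config: CohortConfig, out_dir) -> pd.DataFrame:
    """Write a full cohort to disk; returns the manifest.

    Layout: ``<out_dir>/<subject>/trial_NN.csv`` (+ ``trial_NN.beeps.txt``),
    a ``manifest.csv`` (subject_id, trial_index, path), the config as YAML,
    and the generator's per-trial target strategies (ground truth) as CSV
    for recovery tests.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    truth_rows = []
    for s_idx, sseed in enumerate(subject_seeds(config), start=1):
        sid = f"S{s_idx:02d}"
        rng = np.random.default_rng(sseed)
        targets = sample_trial_targets(config, rng)
        # regenerate with the same rng stream used inside the subject
        trials = generate_synthetic_subject(config, sseed, subject_id=sid)
        sdir = os.path.join(out_dir, sid)
        os.makedirs(sdir, exist_ok=True)
        for trial, (target, chaotic) in zip(trials, targets):
            name = f"trial_{trial.trial_index:02d}.csv"
            path = os.path.join(sdir, name)
            trial.save(path, metronome_path=path.replace(".csv", ".beeps.txt"))
            rows.append((sid, trial.trial_index, os.path.join(sid, name)))
            truth_rows.append(
                (sid, trial.trial_index, target.amplitude_pp, target.frequency,
                 target.theta0, target.omega0, chaotic)
            )
    manifest = pd.DataFrame(rows, columns=["subject_id", "trial_index", "path"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    config.to_yaml(os.path.join(out_dir, "cohort_config.yaml"))
    pd.DataFrame(
        truth_rows,
        columns=["subject_id", "trial_index", "amplitude_pp", "frequency",
                 "theta0", "omega0", "chaotic_episode"],
    ).to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    return manifest
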