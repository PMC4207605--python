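"""Analysis pipeline for experimental-style 45 s rhythmic trials.

A trial is a 120 Hz recording of hand force, cup position and ball angle
while a subject oscillates the virtual ball-and-cup object between two
targets, paced by a 2 Hz metronome (one beep per half cycle).  The pipeline

* detects cup-position extrema (with sub-sample refinement),
* strobes the ball state at positive maxima to estimate the per-cycle
  execution variables (f_k, A_k, theta0_k, omega0_k) and their window means,
* computes the strategy measures directly from the continuous data,
* looks up the simulation-based measures in a result-space map at the mean
  strategy, and
* summarises practice effects with early-vs-late paired t-tests and
  metronome-asynchrony statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt
from scipy.stats import pearsonr, ttest_rel

from .dynamics import ModelParams
from .measures import (
    MeasureSet,
    mean_abs_jerk,
    mean_squared_force,
    mutual_information,
    spectral_arc_length,
)
from .result_space import MeasureMap

__all__ = [
    "TrialRecord",
    "TrialSummary",
    "detect_cycle_peaks",
    "estimate_execution_variables",
    "trial_strategy_measures",
    "map_lookup_measures",
    "early_late_comparison",
    "asynchrony_stats",
]

TRIAL_COLUMNS = ["time_s", "force_N", "cup_pos_m", "ball_ang_rad"]


@dataclass
class TrialRecord:
    """One experimental-style recording plus its metronome schedule."""

    subject_id: str
    trial_index: int
    time: np.ndarray
    force: np.ndarray
    cup_pos: np.ndarray
    ball_ang: np.ndarray
    rate: float = 120.0
    cup_vel: np.ndarray | None = None
    ball_angvel: np.ndarray | None = None
    metronome_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("force", "cup_pos", "ball_ang"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time length")
        for name in ("cup_vel", "ball_angvel"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"channel {name} length != time length")
        if self.duration < 45.0 - 1e-9:
            warnings.warn(
                f"trial duration {self.duration:.1f}s < 45 s: "
                "standard analysis windows may be truncated"
            )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.time,
                "force_N": self.force,
                "cup_pos_m": self.cup_pos,
                "ball_ang_rad": self.ball_ang,
            }
        )
        if self.cup_vel is not None:
            df["cup_vel_mps"] = self.cup_vel
        if self.ball_angvel is not None:
            df["ball_angvel_radps"] = self.ball_angvel
        return df

    def save(self, path, metronome_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if self.metronome_times is not None and metronome_path is not None:
            np.savetxt(metronome_path, self.metronome_times, fmt="%.6f",
                       header="metronome_time_s", comments="")

    @classmethod
    def load(cls, path, subject_id="?", trial_index=0, metronome_path=None):
        df = pd.read_csv(path)
        rate = 1.0 / float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
        beeps = None
        if metronome_path is not None:
            beeps = np.loadtxt(metronome_path, skiprows=1, ndmin=1)
        return cls(
            subject_id=subject_id,
            trial_index=trial_index,
            time=df["time_s"].to_numpy(float),
            force=df["force_N"].to_numpy(float),
            cup_pos=df["cup_pos_m"].to_numpy(float),
            ball_ang=df["ball_ang_rad"].to_numpy(float),
            rate=rate,
            cup_vel=df["cup_vel_mps"].to_numpy(float) if "cup_vel_mps" in df else None,
            ball_angvel=(
                df["ball_angvel_radps"].to_numpy(float)
                if "ball_angvel_radps" in df else None
            ),
            metronome_times=beeps,
        )


@dataclass
class TrialSummary:
    """Per-cycle execution variables and their analysis-window means."""

    subject_id: str
    trial_index: int
    peak_times: np.ndarray          # refined times of positive maxima
    f_k: np.ndarray                 # per-cycle frequency (Hz)
    a_k: np.ndarray                 # per-cycle peak-to-peak amplitude (m)
    theta0_k: np.ndarray            # ball angle at each maximum (rad)
    omega0_k: np.ndarray            # ball angular velocity at each maximum
    window: tuple = (25.0, 45.0)
    f_mean: float = np.nan
    a_mean: float = np.nan
    theta0_mean: float = np.nan
    omega0_mean: float = np.nan
    n_window_cycles: int = 0
    low_cycle_count: bool = False
    measures_experimental: MeasureSet | None = None
    measures_map: MeasureSet | None = None
    asynchrony_mean_abs: float = np.nan
    asynchrony_sd: float = np.nan


def lowpass(signal: np.ndarray, rate: float, cutoff: float = 10.0, order: int = 4):
    """Zero-phase Butterworth low-pass (applied forward and backward)."""
    sos = butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sosfiltfilt(sos, signal)


def filtered_derivative(
    signal: np.ndarray, rate: float, cutoff: float = 10.0
) -> np.ndarray:
    """Fourth-order central-difference derivative of the low-passed signal."""
    s = lowpass(signal, rate, cutoff)
    d = np.empty_like(s)
    # (-s[i+2] + 8 s[i+1] - 8 s[i-1] + s[i-2]) / (12 h)
    d[2:-2] = (-s[4:] + 8 * s[3:-1] - 8 * s[1:-3] + s[:-4]) * (rate / 12.0)
    d[:2] = np.gradient(s[:5])[:2] * rate
    d[-2:] = np.gradient(s[-5:])[-2:] * rate
    return d


def _parabolic_refine(x: np.ndarray, i: int):
    """Sub-sample vertex of the parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(x) - 1:
        return float(i), float(x[i])
    num = x[i - 1] - x[i + 1]
    den = x[i - 1] - 2 * x[i] + x[i + 1]
    if den == 0:
        return float(i), float(x[i])
    delta = 0.5 * num / den
    delta = float(np.clip(delta, -0.5, 0.5))
    val = x[i] - 0.25 * (x[i - 1] - x[i + 1]) * delta
    return i + delta, float(val)


def detect_cycle_peaks(
    cup_pos: np.ndarray,
    rate: float,
    nominal_f: float = 1.0,
    prominence_frac: float = 0.25,
):
    """Indices and refined times of cup-position maxima and minima.

    Extrema must be separated by at least half a nominal period and have
    prominence of at least ``prominence_frac`` of the running peak-to-peak
    excursion (median cycle amplitude).  Endpoint samples that are closed-
    interval maxima/minima are included.  Returns a dict with integer
    indices and parabolic sub-sample refined times/values for both signs.
    """
    x = np.asarray(cup_pos, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant cup position: no cycles to detect")
    if len(x) < 3 * rate / nominal_f:
        raise ValueError("need at least 3 nominal cycles of data")
    min_sep = int(0.5 * rate / nominal_f)
    out = {}
    for sign, key in ((+1.0, "max"), (-1.0, "min")):
        y = sign * x
        idx, _ = find_peaks(y, distance=min_sep)
        ends = [e for e in (0, len(y) - 1)
                if (e == 0 and y[0] >= y[1]) or (e == len(y) - 1 and y[-1] >= y[-2])]
        idx = np.sort(np.unique(np.concatenate([idx, ends]).astype(int)))
        # prominence filter against the running amplitude
        pp = np.median(np.abs(np.diff(y[idx]))) if len(idx) > 1 else np.ptp(y)
        keep = y[idx] >= np.median(y) + (prominence_frac - 0.5) * 0 + 0 * pp
        # a peak qualifies if it rises at least prominence_frac * pp above
        # the midline between the surrounding troughs; approximate with the
        # signal median as the midline reference
        keep = y[idx] - np.median(y) >= prominence_frac * pp / 2.0
        idx = idx[keep]
        # enforce separation after endpoint merge
        if len(idx) > 1:
            filtered = [idx[0]]
            for i in idx[1:]:
                if i - filtered[-1] >= min_sep:
                    filtered.append(i)
            idx = np.asarray(filtered)
        times = np.empty(len(idx))
        values = np.empty(len(idx))
        for j, i in enumerate(idx):
            di, vi = _parabolic_refine(x if sign > 0 else x, int(i))
            times[j] = di / rate
            values[j] = vi
        out[f"{key}_idx"] = idx
        out[f"{key}_times"] = times
        out[f"{key}_values"] = values
    if len(out["max_idx"]) < 2:
        raise ValueError("fewer than two cup-position maxima detected")
    return out


def estimate_execution_variables(
    trial: TrialRecord,
    window=(25.0, 45.0),
    cutoff: float = 10.0,
) -> TrialSummary:
    """Per-cycle execution variables strobed at cup-position maxima.

    f_k is the inverse spacing of successive maxima; A_k the peak-to-trough
    excursion of each cycle; theta0_k / omega0_k the ball angle and angular
    velocity interpolated at each refined maximum time.  Window means use
    the cycles whose strobe time lies in the closed ``window`` interval.
    The cup channel is low-passed (zero-phase, ``cutoff`` Hz) before peak
    detection; the ball velocity is derived the same way when not recorded.
    """
    x = lowpass(trial.cup_pos, trial.rate, cutoff)
    nominal_f = 1.0
    peaks = detect_cycle_peaks(x, trial.rate, nominal_f)
    tmax = peaks["max_times"]
    vmax = peaks["max_values"]
    f_k = 1.0 / np.diff(tmax)
    # per-cycle amplitude: refined peak minus the minimum trough value
    # between this maximum and the next
    a_k = np.empty(len(tmax) - 1)
    tmin, vmin = peaks["min_times"], peaks["min_values"]
    for k in range(len(tmax) - 1):
        sel = (tmin > tmax[k]) & (tmin < tmax[k + 1])
        if sel.any():
            a_k[k] = vmax[k] - vmin[sel].min()
        else:
            lo, hi = int(tmax[k] * trial.rate), int(tmax[k + 1] * trial.rate) + 1
            a_k[k] = vmax[k] - x[lo:hi].min()
    omega = (
        trial.ball_angvel
        if trial.ball_angvel is not None
        else filtered_derivative(trial.ball_ang, trial.rate, cutoff)
    )
    theta0_k = np.interp(tmax, trial.time, trial.ball_ang)
    omega0_k = np.interp(tmax, trial.time, omega)
    in_win = (tmax >= window[0]) & (tmax <= window[1])
    in_win_cycle = in_win[:-1]  # cycles keyed to their starting maximum
    n_win = int(in_win.sum())
    low = n_win < 5
    if low:
        warnings.warn(
            f"only {n_win} strobe(s) inside window {window}: means unreliable"
        )
    summary = TrialSummary(
        subject_id=trial.subject_id,
        trial_index=trial.trial_index,
        peak_times=tmax,
        f_k=f_k,
        a_k=a_k,
        theta0_k=theta0_k,
        omega0_k=omega0_k,
        window=tuple(window),
        n_window_cycles=n_win,
        low_cycle_count=low,
    )
    if n_win:
        summary.f_mean = float(f_k[in_win_cycle].mean()) if in_win_cycle.any() else np.nan
        summary.a_mean = float(a_k[in_win_cycle].mean()) if in_win_cycle.any() else np.nan
        summary.theta0_mean = float(theta0_k[in_win].mean())
        summary.omega0_mean = float(omega0_k[in_win].mean())
    return summary


def _cycle_phase(time: np.ndarray, peak_times: np.ndarray) -> np.ndarray:
    """Piecewise-linear cup phase, 0 -> 2*pi between successive maxima."""
    cycle = np.searchsorted(peak_times, time, side="right") - 1
    cycle = np.clip(cycle, 0, len(peak_times) - 2)
    t0 = peak_times[cycle]
    t1 = peak_times[cycle + 1]
    return 2.0 * math.pi * np.clip((time - t0) / (t1 - t0), 0.0, 1.0 - 1e-12)


def _cycle_average(signal, time, peak_times, n_samples: int = 120):
    """Average the signal across cycles after resampling each to n_samples."""
    prof = np.zeros(n_samples)
    u = np.linspace(0.0, 1.0, n_samples, endpoint=False)
    count = 0
    for k in range(len(peak_times) - 1):
        t0, t1 = peak_times[k], peak_times[k + 1]
        prof += np.interp(t0 + u * (t1 - t0), time, signal)
        count += 1
    return prof / max(count, 1)


def trial_strategy_measures(
    trial: TrialRecord,
    summary: TrialSummary | None = None,
    n_cycle_samples: int = 120,
    params: ModelParams = ModelParams(),
) -> MeasureSet:
    """Strategy measures computed from the continuous experimental data.

    MI uses the raw continuous force against the piecewise-linear cup phase
    (restricted to the span between the first and last detected maximum);
    MSF uses the whole continuous force.  Smoothness measures (jerk, SAL)
    are computed on cycle-averaged profiles: each cycle is linearly
    time-normalised to ``n_cycle_samples`` samples and averaged, isolating
    the intended strategy from cycle-to-cycle variability.
    """
    if summary is None:
        summary = estimate_execution_variables(trial)
    pk = summary.peak_times
    span = (trial.time >= pk[0]) & (trial.time <= pk[-1])
    phase = _cycle_phase(trial.time[span], pk)
    mi = mutual_information(trial.force[span], phase)
    msf = mean_squared_force(trial.force[span])
    f_bar = summary.f_mean if np.isfinite(summary.f_mean) else 1.0
    cyc_rate = n_cycle_samples * f_bar
    ball_disp = trial.cup_pos - params.rod_length * np.sin(trial.ball_ang)
    ball_prof = _cycle_average(ball_disp, trial.time, pk, n_cycle_samples)
    force_prof = _cycle_average(trial.force, trial.time, pk, n_cycle_samples)
    cup_prof = _cycle_average(trial.cup_pos, trial.time, pk, n_cycle_samples)

    def wrap_pad(prof, n=3):
        # the averaged cycle is periodic; wrap-padding lets the jerk
        # estimator's trimmed interior cover exactly one full cycle
        return np.concatenate([prof[-n:], prof, prof[:n]])

    return MeasureSet(
        mi=mi,
        msf=msf,
        jerk_ball_norm=mean_abs_jerk(wrap_pad(ball_prof), cyc_rate, normalized=True),
        jerk_ball_raw=mean_abs_jerk(wrap_pad(ball_prof), cyc_rate, normalized=False),
        jerk_force_raw=mean_abs_jerk(wrap_pad(force_prof), cyc_rate, normalized=False),
        jerk_force_norm=mean_abs_jerk(wrap_pad(force_prof), cyc_rate, normalized=True),
        jerk_cup_raw=mean_abs_jerk(wrap_pad(cup_prof), cyc_rate, normalized=False),
        sal=spectral_arc_length(np.tile(ball_prof, 8), cyc_rate),
    )


def map_lookup_measures(summary: TrialSummary, mmap: MeasureMap) -> MeasureSet:
    """Bilinear lookup of the simulation map at the trial's mean strategy.

    Strategies outside the map domain are clipped to the boundary (logged
    via a warning).
    """
    if not mmap.surfaces:
        raise ValueError("empty measure map")
    a = summary.a_mean
    th = summary.theta0_mean
    a_cl = float(np.clip(a, mmap.amplitude_grid[0], mmap.amplitude_grid[-1]))
    th_cl = float(np.clip(th, mmap.theta0_grid[0], mmap.theta0_grid[-1]))
    if a_cl != a or th_cl != th:
        warnings.warn(
            f"mean strategy (A={a:.3f}, theta0={th:.3f}) clipped to map domain"
        )
    ms = MeasureSet()
    for name in mmap.surfaces:
        if hasattr(ms, name):
            setattr(ms, name, mmap.interpolate(name, a_cl, th_cl))
    return ms


def early_late_comparison(values_by_subject: dict, n_edge: int = 5) -> dict:
    """Early-vs-late practice comparison by a paired t-test across subjects.

    ``values_by_subject`` maps subject id -> per-trial value sequence.  The
    per-subject means of the first and last ``n_edge`` trials are compared
    with a two-sided paired t-test; significance is flagged at both the 0.05
    and 0.10 levels.
    """
    if len(values_by_subject) < 2:
        raise ValueError("need at least 2 subjects for a paired comparison")
    early, late = [], []
    for sid, vals in values_by_subject.items():
        v = np.asarray(list(vals), dtype=float)
        if len(v) < 2 * n_edge:
            raise ValueError(f"subject {sid}: need >= {2*n_edge} trials")
        early.append(v[:n_edge].mean())
        late.append(v[-n_edge:].mean())
    early = np.asarray(early)
    late = np.asarray(late)
    if np.allclose(early, late):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = ttest_rel(late, early)
    return {
        "early_mean": float(early.mean()),
        "early_sd": float(early.std(ddof=1)),
        "late_mean": float(late.mean()),
        "late_sd": float(late.std(ddof=1)),
        "t": float(t_stat),
        "df": len(early) - 1,
        "p": float(p),
        "significant_05": bool(p < 0.05),
        "significant_10": bool(p < 0.10),
    }


def asynchrony_stats(trial: TrialRecord, window=(20.0, 45.0)) -> dict:
    """Metronome asynchrony of the cup extrema (maxima and minima).

    Each beep inside the closed window is matched to the nearest cup
    extremum; the signed differences (extremum time minus beep time) are
    summarised as mean absolute asynchrony and the SD of the signed values.
    """
    if trial.metronome_times is None or len(trial.metronome_times) == 0:
        raise ValueError("trial has no metronome times")
    beeps = np.asarray(trial.metronome_times, dtype=float)
    beeps = beeps[(beeps >= window[0]) & (beeps <= window[1])]
    if len(beeps) == 0:
        raise ValueError("no metronome beeps inside the analysis window")
    x = lowpass(trial.cup_pos, trial.rate, 10.0)
    peaks = detect_cycle_peaks(x, trial.rate)
    extrema = np.sort(np.concatenate([peaks["max_times"], peaks["min_times"]]))
    idx = np.searchsorted(extrema, beeps)
    idx = np.clip(idx, 1, len(extrema) - 1)
    left = extrema[idx - 1]
    right = extrema[idx]
    nearest = np.where(np.abs(beeps - left) <= np.abs(right - beeps), left, right)
    d = nearest - beeps
    return {
        "mean_abs_asynchrony": float(np.abs(d).mean()),
        "sd_asynchrony": float(d.std()),
        "n_beeps": int(len(beeps)),
    }


def asynchrony_amplitude_correlation(per_trial: list) -> dict:
    """Correlate per-trial asynchrony SD with mean movement amplitude.

    ``per_trial`` holds (asynchrony_sd, mean_amplitude) pairs across trials.
    """
    arr = np.asarray(per_trial, dtype=float)
    if len(arr) < 3:
        raise ValueError("need >= 3 trials to correlate")
    r, p = pearsonr(arr[:, 0], arr[:, 1])
    return {"r": float(r), "p": float(p), "n": len(arr)}
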