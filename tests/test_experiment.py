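import math
import warnings

import numpy as np
import pytest

from ballincup import (
    Strategy,
    asynchrony_stats,
    detect_cycle_peaks,
    early_late_comparison,
    estimate_execution_variables,
    generate_clean_trial,
    map_lookup_measures,
    trial_strategy_measures,
)
from ballincup.experiment import TrialRecord
from ballincup.result_space import MeasureMap

from conftest import PERIOD1


def _cosine_trial(amplitude_pp=0.28, noise_sd=0.0, seed=0, theta_const=0.0):
    """A trial whose cup is an exact 1 Hz peak-aligned cosine."""
    rng = np.random.default_rng(seed)
    t = np.arange(0, 45 * 120 + 1) / 120
    x = amplitude_pp / 2 * np.cos(2 * np.pi * t) + rng.normal(0, noise_sd, len(t))
    return TrialRecord(
        subject_id="T", trial_index=1, time=t,
        force=np.sin(2 * np.pi * t), cup_pos=x,
        ball_ang=np.full_like(t, theta_const),
        metronome_times=np.arange(0, 45.1, 0.5),
    )


class TestDetectCyclePeaks:
    def test_clean_cosine_has_46_maxima(self):
        t = np.arange(0, 45 * 120 + 1) / 120
        pk = detect_cycle_peaks(0.14 * np.cos(2 * np.pi * t), 120.0)
        assert len(pk["max_idx"]) == 46

    def test_21_maxima_in_closed_25_45_window(self):
        t = np.arange(0, 45 * 120 + 1) / 120
        pk = detect_cycle_peaks(0.14 * np.cos(2 * np.pi * t), 120.0)
        tw = pk["max_times"]
        assert ((tw >= 25.0) & (tw <= 45.0)).sum() == 21

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_cycle_peaks(np.ones(5401), 120.0)

    def test_subsample_refinement_beats_grid(self):
        # peaks placed off the sample grid: refined times within 1 ms
        t = np.arange(0, 20 * 120 + 1) / 120
        shift = 0.00371
        pk = detect_cycle_peaks(0.1 * np.cos(2 * np.pi * (t - shift)), 120.0)
        interior = pk["max_times"][1:-1]
        err = np.abs(interior - (np.round(interior - shift) + shift))
        assert err.max() < 1e-3


class TestExecutionVariables:
    def test_noiseless_recovery_of_period1_strategy(self):
        # at the period-1 fixed point the strobed states equal the strategy
        trial = generate_clean_trial(PERIOD1)
        s = estimate_execution_variables(trial)
        assert s.f_mean == pytest.approx(1.0, abs=1e-3)
        assert s.a_mean == pytest.approx(0.10, abs=1e-3)
        assert s.theta0_mean == pytest.approx(1.0, abs=0.02)
        assert s.omega0_mean == pytest.approx(0.0, abs=0.05)
        assert s.n_window_cycles == 21

    def test_per_cycle_estimates_match_true_strobes(self):
        # general (quasi-periodic) strategy: the estimator must read back the
        # trajectory's true strobed ball states cycle by cycle
        from ballincup import simulate_strategy, strobe_at_cup_peaks

        strat = Strategy(0.28, 1.0, 0.95, 0.0)
        trial = generate_clean_trial(strat)
        s = estimate_execution_variables(trial)
        truth = strobe_at_cup_peaks(simulate_strategy(strat), 1.0)
        assert len(s.theta0_k) == len(truth.ball_ang_at_peak)
        assert np.abs(s.theta0_k - truth.ball_ang_at_peak).max() < 1e-3
        assert np.abs(s.omega0_k - truth.ball_angvel_at_peak).max() < 0.02

    def test_resting_ball_reads_zero(self):
        trial = _cosine_trial(theta_const=0.0)
        s = estimate_execution_variables(trial)
        assert s.theta0_mean == 0.0
        assert abs(s.omega0_mean) < 1e-9

    def test_amplitude_bias_small_under_sensor_noise(self):
        clean = estimate_execution_variables(_cosine_trial(noise_sd=0.0))
        noisy = estimate_execution_variables(_cosine_trial(noise_sd=0.002, seed=4))
        assert abs(noisy.a_mean - clean.a_mean) / clean.a_mean < 0.02

    def test_few_window_cycles_flagged(self):
        t = np.arange(0, 8 * 120 + 1) / 120
        trial = TrialRecord(
            subject_id="T", trial_index=1, time=t,
            force=np.zeros_like(t), cup_pos=0.1 * np.cos(2 * np.pi * t),
            ball_ang=np.zeros_like(t),
        )
        with pytest.warns(UserWarning):
            s = estimate_execution_variables(trial)
        assert s.low_cycle_count


class TestTrialMeasures:
    def test_constant_force_msf(self):
        trial = _cosine_trial()
        trial.force = np.full_like(trial.time, 2.0)
        ms = trial_strategy_measures(trial)
        assert ms.msf == pytest.approx(4.0)

    def test_cycle_averaged_sinusoid_jerk(self):
        # cup cosine, ball fixed: the averaged ball-displacement profile is
        # sinusoidal, so its normalized jerk is 2/pi
        trial = _cosine_trial()
        ms = trial_strategy_measures(trial)
        assert ms.jerk_ball_norm == pytest.approx(2 / math.pi, abs=5e-3)

    def test_periodic_like_trial_has_higher_mi_than_chaotic(self):
        from conftest import CHAOTIC

        ms_p = trial_strategy_measures(generate_clean_trial(PERIOD1))
        ms_c = trial_strategy_measures(generate_clean_trial(CHAOTIC))
        assert ms_p.mi > ms_c.mi


@pytest.fixture(scope="module")
def tiny_map():
    from ballincup.result_space import evaluate_result_space

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_result_space(
            np.array([0.08, 0.12]),
            np.array([0.8, 1.2]),
            measures=("mi", "msf", "predictability_index"),
        )


class TestMapLookup:

    def test_node_lookup_is_exact(self, tiny_map):
        s = estimate_execution_variables(
            generate_clean_trial(Strategy(0.10, 1.0, 1.0, 0.0))
        )
        s.a_mean, s.theta0_mean = 0.08, 0.8
        ms = map_lookup_measures(s, tiny_map)
        assert ms.mi == pytest.approx(tiny_map.surfaces["mi"][0, 0], rel=1e-12)

    def test_out_of_domain_clipped_with_warning(self, tiny_map):
        s = estimate_execution_variables(
            generate_clean_trial(Strategy(0.10, 1.0, 1.0, 0.0))
        )
        s.a_mean, s.theta0_mean = 0.50, 1.0
        with pytest.warns(UserWarning, match="clipped"):
            map_lookup_measures(s, tiny_map)


class TestEarlyLate:
    def test_identical_early_late_gives_null(self):
        vals = {f"S{i}": np.ones(12) for i in range(4)}
        comp = early_late_comparison(vals)
        assert comp["t"] == 0.0 and comp["p"] == 1.0

    def test_programmed_increase_detected(self):
        rng = np.random.default_rng(5)
        vals = {
            f"S{i}": np.linspace(0.21, 0.28, 50) + rng.normal(0, 0.01, 50)
            for i in range(8)
        }
        comp = early_late_comparison(vals)
        assert comp["significant_05"]
        assert comp["late_mean"] > comp["early_mean"]

    def test_type_i_error_near_nominal(self):
        # null cohorts: rejection rate ~ alpha over 1000 replicates
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = {f"S{i}": rng.normal(0.25, 0.02, 20) for i in range(8)}
            if early_late_comparison(vals)["significant_05"]:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_insufficient_subjects_rejected(self):
        with pytest.raises(ValueError):
            early_late_comparison({"S0": np.ones(12)})


class TestAsynchrony:
    def test_extrema_on_beeps_gives_zero(self):
        trial = _cosine_trial()
        st = asynchrony_stats(trial)
        assert st["mean_abs_asynchrony"] < 1e-6
        assert st["sd_asynchrony"] < 1e-6

    def test_uniform_shift_recovered(self):
        trial = _cosine_trial()
        trial.metronome_times = np.arange(0.5, 44.5, 0.5) - 0.030
        st = asynchrony_stats(trial)
        assert st["mean_abs_asynchrony"] == pytest.approx(0.030, abs=1e-3)
        assert st["sd_asynchrony"] < 1e-3

    def test_missing_beeps_rejected(self):
        trial = _cosine_trial()
        trial.metronome_times = None
        with pytest.raises(ValueError):
            asynchrony_stats(trial)

    def test_null_amplitude_coupling_correlation(self):
        # zero-coupling synthetic cohort: asynchrony SD unrelated to amplitude
        from ballincup.experiment import asynchrony_amplitude_correlation

        rng = np.random.default_rng(9)
        pairs = [(rng.uniform(0.01, 0.03), rng.uniform(0.2, 0.3)) for _ in range(120)]
        out = asynchrony_amplitude_correlation(pairs)
        assert abs(out["r"]) < 0.2
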