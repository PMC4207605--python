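"""End-to-end practice analysis on a synthetic cohort.

Generates a small cohort (4 subjects x 20 trials, ~1 minute), estimates
each trial's execution variables, and tests whether movement amplitude
increased from early to late practice with a paired t-test.
"""

import warnings

import numpy as np

from ballincup import (
    early_late_comparison,
    estimate_execution_variables,
    generate_synthetic_subject,
)
from ballincup.synthetic import CohortConfig, subject_seeds

warnings.filterwarnings("ignore")

config = CohortConfig(n_subjects=4, n_trials=20, seed=11)
amplitudes = {}
for i, sseed in enumerate(subject_seeds(config)):
    trials = generate_synthetic_subject(config, sseed, subject_id=f"S{i+1:02d}")
    amps = [estimate_execution_variables(t).a_mean for t in trials]
    amplitudes[f"S{i+1:02d}"] = amps
    print(f"S{i+1:02d}: first trial A = {amps[0]*100:.1f} cm, "
          f"last trial A = {amps[-1]*100:.1f} cm")

comp = early_late_comparison(amplitudes)
print()
print(f"early mean {comp['early_mean']*100:.2f} cm (SD {comp['early_sd']*100:.2f})")
print(f"late  mean {comp['late_mean']*100:.2f} cm (SD {comp['late_sd']*100:.2f})")
print(f"paired t({comp['df']}) = {comp['t']:.2f}, p = {comp['p']:.4f}, "
      f"significant at 0.05: {comp['significant_05']}")
print()
print("The generator programs an amplitude increase across practice; the")
print("pipeline recovers it as a significant early-vs-late difference.")
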