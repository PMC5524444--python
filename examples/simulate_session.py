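"""Simulate one observer session and summarize first-order performance.

The observer judges the average color of eight patches (red vs blue)
under a 2 (evidence mean) x 2 (evidence variance) difficulty design,
then rates confidence on a 1-6 scale.  This script prints the per-cell
error rates, mean correct RTs and efficiency scores: errors and RTs
should rise from the easy cell (high mean, low variance) through the two
medium cells to the difficult cell (low mean, high variance).
"""

import numpy as np

from metaconf import DesignSpec, ObserverParams, cell_performance, simulate_session

design = DesignSpec()
observer = ObserverParams()
trials = simulate_session(design, observer, np.random.default_rng(0))

print(f"{design.n_blocks} blocks x {design.trials_per_block} trials "
      f"= {len(trials)} rows; miss rate {trials['miss'].mean():.1%}\n")
print(f"{'cell':<24}{'error %':>9}{'mean RT':>9}{'efficiency':>12}")
for m, v, label in [("high", "low", "easy"),
                    ("high", "high", "medium (high variance)"),
                    ("low", "low", "medium (low mean)"),
                    ("low", "high", "difficult")]:
    perf = cell_performance(trials, mean_level=m, variance_level=v)
    print(f"{label:<24}{100 * (1 - perf.accuracy):>8.1f}"
          f"{perf.mean_correct_rt:>9.0f}{perf.efficiency:>12.0f}")

print("\nEfficiency = median correct RT / accuracy (ms): one number that")
print("rises with difficulty whether the cost is paid in time or errors.")
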