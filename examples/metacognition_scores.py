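"""Type II SDT scores: how well (and how boldly) confidence tracks accuracy.

A_ROC is the area under the Type II ROC — the probability that a random
correct trial carries a higher rating than a random error (0.5 = chance,
1 = perfect error monitoring).  B_ROC is a criterion-based bias index:
positive when the observer leans toward calling their responses correct.
We score one session per difficulty cell and also print the pooled
error rate per confidence level, which should fall monotonically.
"""

import numpy as np

from metaconf import (
    DesignSpec,
    ObserverParams,
    confidence_error_profile,
    score_metacognition,
    simulate_session,
)

trials = simulate_session(DesignSpec(), ObserverParams(),
                          np.random.default_rng(7))

print(f"{'cell':<24}{'A_ROC':>8}{'B_ROC':>8}{'n':>7}")
for m, v, label in [("high", "low", "easy"),
                    ("high", "high", "medium (high variance)"),
                    ("low", "low", "medium (low mean)"),
                    ("low", "high", "difficult")]:
    sc = score_metacognition(trials, mean_level=m, variance_level=v)
    print(f"{label:<24}{sc.a_roc:>8.3f}{sc.b_roc:>8.3f}{sc.n_trials:>7}")

rates, rho, p = confidence_error_profile(trials)
print("\nerror rate by confidence level (1 = certainly wrong ... 6 = certainly correct):")
print("  " + "  ".join(f"{r:.2f}" if np.isfinite(r) else " -- " for r in rates))
print(f"Spearman rho = {rho:.2f} (p = {p:.2g}): strongly negative, i.e.")
print("higher expressed confidence predicts fewer errors.")
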