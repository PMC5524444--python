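"""Which cues drive confidence? Per-participant regressions and BIC.

Each simulated participant contributes 8 condition cells (2 mean x 2
variance x 2 colors).  Mean confidence per cell is regressed on nested
predictor sets: accuracy (log-odds errors, sign-flipped), correct RT,
and the mean / variance condition codes.  Standardized betas are
averaged across participants with second-order t tests; BIC compares
the models (lower = better).  With a variance-sensitive readout the
variance predictor earns a reliable negative beta over and above the
performance predictors, while the mean predictor does not.
"""

import numpy as np

from metaconf import (
    DesignSpec,
    MODELS,
    aggregate_cells,
    drift_matched_design,
    fit_condition_regression,
    one_sample_t,
    simulate_experiment,
    variance_readout_observer,
)

observer = variance_readout_observer()
design = drift_matched_design(DesignSpec(), observer)

# one cohort's model-comparison table, then three replicate cohorts for
# the second-order beta tests (a single 20-participant cohort is noisy)
all_fits = []
for seed in (2026, 3026, 4026):
    trials = simulate_experiment(20, design, observer,
                                 np.random.default_rng(seed))
    cells = aggregate_cells(trials)
    all_fits.append({
        model: [fit_condition_regression(g, model)
                for _, g in cells.groupby("participant")]
        for model in MODELS
    })

print(f"{'model':<6}{'predictors':<34}{'mean R2':>9}{'mean BIC':>10}")
for model, results in all_fits[0].items():
    r2 = np.mean([r.r2 for r in results])
    bic = np.mean([r.bic for r in results])
    print(f"{model:<6}{'+'.join(MODELS[model]):<34}{r2:>9.3f}{bic:>10.2f}")

for model, pred in [("M2a", "mean"), ("M2b", "variance")]:
    stats = [one_sample_t([r.betas[pred] for r in fits[model]])
             for fits in all_fits]
    ts = sorted(t for t, _, _ in stats)
    print(f"\n{model} {pred:<9} second-order t across 3 cohorts: "
          + ", ".join(f"{t:+.2f}" for t, _, _ in stats)
          + f"  (median {ts[1]:+.2f})")
print("\nThe variance beta is consistently, reliably negative (unreliable")
print("evidence lowers confidence beyond its accuracy/RT cost); the mean")
print("beta hovers around the significance threshold without a stable sign"
      "\nof its own — it inherits part of the variance effect through the"
      "\ncollinearity of the performance predictors with the design codes.")
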