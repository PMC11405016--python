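#!/usr/bin/env python
"""Calibration of the statistical procedures used by the figure pipelines."""

import json
from pathlib import Path

from evquant import stats, validation

results = Path("results")
results.mkdir(exist_ok=True)

rate = validation.t_test_type_i_rate(seed=42, n_sim=10_000, n_per_group=3)
print(f"t-test type-I error at alpha 0.05 (null, n=3 vs 3, 10k sims): {rate:.4f}")

mw = stats.mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
print(f"Mann-Whitney exact two-sided p, n=3 vs 3 complete separation: {mw.p_value}")

thresholds = {
    "alpha 0.05, m 11": stats.format_threshold(stats.bonferroni_threshold(0.05, 11)),
    "alpha 0.01, m 11": stats.format_threshold(stats.bonferroni_threshold(0.01, 11)),
    "alpha 0.001, m 11": stats.format_threshold(stats.bonferroni_threshold(0.001, 11)),
    "alpha 0.05, m 7": stats.format_threshold(stats.bonferroni_threshold(0.05, 7)),
}
for k, v in thresholds.items():
    print(f"Bonferroni display ({k}): {v}")

fold, sd = stats.ratio_with_sd(8.8, 1.0, 1.0, 0.05)
print(f"ratio propagation example: {fold:.1f} +- {sd:.2f}")

(results / "stats_calibration.json").write_text(json.dumps({
    "t_test_type_i_rate": rate,
    "mann_whitney_exact_p_n3_separation": mw.p_value,
    "bonferroni_displays": thresholds,
}, indent=2))
print(f"-> {results/'stats_calibration.json'}")
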