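"""Treatment effects, correlation grid, and stepwise predictor analysis.

Reads the metric table written by 04_run_study.py, then reproduces the
study's statistical machinery: paired pre/post comparisons per metric and
scenario, the 8 x 5 x 6 weighted-Pearson correlation grid between stress
metrics and radiographic measures (pre/post pooled, group-balanced
weights), and forward stepwise regression (F-in 3.84, F-out 2.71) of each
metric on the radiographic + personal candidates in the dysplasia-specific
harris_like/nishii scenario.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import hipdea as h  # noqa: E402
from hipdea.stats import StudyResult, candidate_matrix  # noqa: E402

SEED = 1
N_SUBJECTS = 22

out_dir = ROOT / "results"
metrics = pd.read_csv(out_dir / "metrics.csv")
divergences = pd.read_csv(out_dir / "divergences.csv")
result = StudyResult(metrics, divergences)
cohort = h.generate_cohort(N_SUBJECTS, seed=SEED, bilateral=True)

# -- paired treatment effects ------------------------------------------------
effects = h.summarize_treatment_effects(result)
effects.to_csv(out_dir / "effects.csv", index=False)
print("mean relative change post vs pre, averaged across scenarios:")
for metric in h.METRIC_NAMES:
    sub = effects[effects.metric == metric]
    n_sig = int((sub.p < 0.05).sum())
    print(f"  {metric:<28} {sub.relative_change_pct.mean():+7.1f}%   "
          f"significant in {n_sig}/{len(sub)} scenarios")

# -- correlation grid --------------------------------------------------------
grid = h.correlation_grid(result, cohort)
grid.to_csv(out_dir / "correlations.csv", index=False)
n_sig = int(grid.significant.sum())
print(f"\ncorrelation grid: {len(grid)} cells, {n_sig} significant at alpha=0.05")
print("mean R across scenarios (stress metric vs coverage angle):")
for metric in ("average_stress", "maxian_overdose", "average_contact_area"):
    parts = []
    for measure in ("LCEA", "AI", "ACEA"):
        sub = grid[(grid.metric == metric) & (grid.measure == measure)]
        parts.append(f"{measure} {sub.R.mean():+.2f}")
    print(f"  {metric:<24} {'  '.join(parts)}")

# -- stepwise predictors in the dysplasia-specific scenario ------------------
hn = metrics[(metrics.cartilage == "nishii") & (metrics.glp == "harris_like")]
X_all = candidate_matrix(cohort, treatment="pre").set_index(["id", "side"])
rows = []
print("\nforward stepwise predictors of pre-op metrics (harris_like/nishii):")
for metric in h.METRIC_NAMES:
    pre = hn[hn.treatment == "pre"].set_index(["id", "side"])[metric]
    X = X_all.loc[pre.index].reset_index(drop=True)
    sw = h.forward_stepwise(pre.to_numpy(), X)
    for step in sw.steps:
        rows.append(dict(metric=metric, **step))
    label = ", ".join(sw.selected) if sw.selected else "(none entered)"
    print(f"  {metric:<28} -> {label}   (R2 = {sw.r_squared:.3f})")
pd.DataFrame(rows).to_csv(out_dir / "stepwise.csv", index=False)

print(f"\nwrote effects.csv, correlations.csv, stepwise.csv to {out_dir}")
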