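"""Sweep wake thresholds 2-25 on the training group and select the optimum.

Writes the per-threshold pooled ROC table (sensitivity, specificity,
Youden's J) to results/threshold_sweep.csv and prints the threshold that
balances sensitivity and specificity.
"""

import pandas as pd

from cohort import RESULTS, study_cohort
from somnoscore.thresholds import sweep_thresholds


def main():
    training, _ = study_cohort()
    sweep = sweep_thresholds(training)
    df = pd.DataFrame({
        "threshold": sweep.thresholds,
        "pooled_sensitivity": sweep.pooled_sensitivity(),
        "pooled_specificity": sweep.pooled_specificity(),
        "youden_j": sweep.criterion_values,
        "mean_accuracy": [c.mean["accuracy"] for c in sweep.per_threshold],
    })
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "threshold_sweep.csv", index=False)
    best = df[df.threshold == sweep.optimal_threshold].iloc[0]
    print(f"optimal wake threshold: {sweep.optimal_threshold:g} units "
          f"(J = {best.youden_j:.3f}, sens = {best.pooled_sensitivity:.3f}, "
          f"spec = {best.pooled_specificity:.3f})")


if __name__ == "__main__":
    main()
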