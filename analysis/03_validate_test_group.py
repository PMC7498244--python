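"""Validate the trained threshold on the held-out test group.

Re-trains on the training group, scores every test night at the trained
threshold, and writes per-participant and pooled concordance (accuracy,
sleep sensitivity, sleep specificity) to results/test_concordance.csv.
"""

import pandas as pd

from cohort import RESULTS, study_cohort
from somnoscore.concordance import cohort_concordance, collapse_hypnogram
from somnoscore.scoring import ScoringConfig, score_sleep_wake
from somnoscore.thresholds import sweep_thresholds


def main():
    training, test = study_cohort()
    threshold = sweep_thresholds(training).optimal_threshold
    cfg = ScoringConfig(wake_threshold=threshold)
    pairs = [(collapse_hypnogram(h), score_sleep_wake(a, cfg)) for a, h in test]
    conc = cohort_concordance(pairs)

    rows = [{"participant_id": psg.participant_id,
             "tp": m.tp, "fn": m.fn, "fp": m.fp, "tn": m.tn,
             "accuracy": s.accuracy, "sensitivity": s.sensitivity,
             "specificity": s.specificity}
            for (psg, _), m, s in zip(pairs, conc.matrices, conc.per_participant)]
    pm, ps = conc.pooled_matrix, conc.pooled
    rows.append({"participant_id": "POOLED", "tp": pm.tp, "fn": pm.fn,
                 "fp": pm.fp, "tn": pm.tn, "accuracy": ps.accuracy,
                 "sensitivity": ps.sensitivity, "specificity": ps.specificity})
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "test_concordance.csv", index=False)

    print(f"trained threshold: {threshold:g} units")
    print(f"test group, pooled over {ps.n_epochs} epochs: "
          f"accuracy {100 * ps.accuracy:.1f}%, sensitivity {100 * ps.sensitivity:.1f}%, "
          f"specificity {100 * ps.specificity:.1f}%")
    print("test group, participant mean +/- SD: "
          + ", ".join(f"{k} {100 * conc.mean[k]:.1f}% +/- {100 * conc.sd[k]:.1f}%"
                      for k in ("accuracy", "sensitivity", "specificity")))


if __name__ == "__main__":
    main()
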