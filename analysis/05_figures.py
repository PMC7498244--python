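"""Render the study figures: ROC of the threshold sweep, Bland-Altman
scatters for TST and WASO, and per-participant metric box plots.

Images go to results/figures/.
"""

from cohort import RESULTS, study_cohort
from somnoscore.concordance import cohort_concordance, collapse_hypnogram
from somnoscore.plots import plot_bland_altman, plot_metric_boxes, plot_roc
from somnoscore.scoring import ScoringConfig, score_sleep_wake
from somnoscore.summary import cohort_bias
from somnoscore.thresholds import sweep_thresholds


def main():
    training, test = study_cohort()
    sweep = sweep_thresholds(training)
    cfg = ScoringConfig(wake_threshold=sweep.optimal_threshold)
    pairs = [(collapse_hypnogram(h), score_sleep_wake(a, cfg)) for a, h in test]
    conc = cohort_concordance(pairs)
    tst, waso = cohort_bias([(dev, psg) for psg, dev in pairs])

    out = RESULTS / "figures"
    out.mkdir(parents=True, exist_ok=True)
    plot_roc(sweep).savefig(out / "roc_training.png", dpi=150)
    plot_bland_altman(tst, "TST").savefig(out / "bland_altman_tst.png", dpi=150)
    plot_bland_altman(waso, "WASO").savefig(out / "bland_altman_waso.png", dpi=150)
    boxes = {m: [getattr(s, m) for s in conc.per_participant]
             for m in ("accuracy", "sensitivity", "specificity")}
    plot_metric_boxes(boxes, "proportion (test group)").savefig(
        out / "metric_boxes_test.png", dpi=150)
    print(f"wrote 4 figures to {out}")


if __name__ == "__main__":
    main()
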