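"""Bland-Altman agreement of device TST and WASO against PSG on the test group.

Writes per-participant (mean, difference) pairs and the bias / limits of
agreement to results/bland_altman.csv; the sign convention is device minus
PSG, so a positive TST bias means the device overestimates sleep.
"""

import pandas as pd

from cohort import RESULTS, study_cohort
from somnoscore.concordance import collapse_hypnogram
from somnoscore.scoring import ScoringConfig, score_sleep_wake
from somnoscore.summary import cohort_bias
from somnoscore.thresholds import sweep_thresholds


def main():
    training, test = study_cohort()
    threshold = sweep_thresholds(training).optimal_threshold
    cfg = ScoringConfig(wake_threshold=threshold)
    pairs = [(score_sleep_wake(a, cfg), collapse_hypnogram(h)) for a, h in test]
    tst, waso = cohort_bias(pairs)

    rows = []
    for name, ba in (("tst", tst), ("waso", waso)):
        for (_, psg), mean, diff in zip(pairs, ba.means, ba.diffs):
            rows.append({"parameter": name, "participant_id": psg.participant_id,
                         "pair_mean_min": mean, "device_minus_psg_min": diff})
    summary = pd.DataFrame([
        {"parameter": n, "bias_min": b.bias, "sd_min": b.sd_diff,
         "loa_low_min": b.loa_low, "loa_high_min": b.loa_high, "n": b.n}
        for n, b in (("tst", tst), ("waso", waso))])
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "bland_altman_pairs.csv", index=False)
    summary.to_csv(RESULTS / "bland_altman.csv", index=False)

    for name, ba in (("TST", tst), ("WASO", waso)):
        print(f"{name}: bias {ba.bias:+.1f} +/- {ba.sd_diff:.1f} min "
              f"(limits {ba.loa_low:.1f} to {ba.loa_high:.1f})")


if __name__ == "__main__":
    main()
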