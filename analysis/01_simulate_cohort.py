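"""Generate the synthetic study cohort and summarize its sleep architecture.

Writes per-night TST/WASO of the PSG reference to
results/cohort_architecture.csv and prints the cohort means, which should
sit near the emulation targets (TST ~478 +/- 75 min, WASO ~21 min).
"""

import numpy as np
import pandas as pd

from cohort import N_TRAINING, RESULTS, study_cohort
from somnoscore.concordance import collapse_hypnogram
from somnoscore.summary import summarize_night


def main():
    training, test = study_cohort()
    rows = []
    for group, nights in (("training", training), ("test", test)):
        for _, h in nights:
            s = summarize_night(collapse_hypnogram(h))
            rows.append({"participant_id": h.participant_id, "group": group,
                         "tst_min": s.tst_min, "waso_min": s.waso_min,
                         "sleep_onset_min": s.onset_index})
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "cohort_architecture.csv", index=False)
    print(f"{len(df)} nights ({N_TRAINING} training / {len(df) - N_TRAINING} test)")
    print(f"PSG TST  {df.tst_min.mean():.1f} +/- {df.tst_min.std(ddof=1):.1f} min")
    print(f"PSG WASO {df.waso_min.mean():.1f} +/- {df.waso_min.std(ddof=1):.1f} min")


if __name__ == "__main__":
    main()
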