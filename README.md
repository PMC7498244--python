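# somnoscore

Actigraphy sleep/wake scoring validated against polysomnography.

Wrist-worn accelerometers infer sleep from the absence of movement. This
package implements the full validation workflow for such a device: weighted
moving-average (Cole-Kripke style) scoring of minute-epoch activity counts,
PSG-trained wake-threshold optimization, epoch-by-epoch concordance
statistics, and night-level TST/WASO agreement — plus a synthetic generator
of paired PSG/actigraphy nights so the whole pipeline is testable without
any recordings.

## The model

For minute-epoch activity counts `c_i`, the weighted total activity is

    A_i = c_i + 0.2 (c_{i-1} + c_{i+1}) + 0.04 (c_{i-2} + c_{i+2})

and minute *i* is scored **sleep** iff `A_i ≤ T`, where the wake threshold
`T` is selected on a training cohort by sweeping integer thresholds 2–25
units and maximizing Youden's J = sensitivity + specificity − 1 on pooled
metrics (sleep is the positive class, PSG the ground truth; the 30-s PSG
hypnogram is collapsed to minutes with a wake-if-any rule). The trained
threshold is then applied unchanged to a held-out test group for all final
performance measures, including Bland-Altman bias (device − PSG) for total
sleep time (TST) and wake after sleep onset (WASO).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from somnoscore import (SimulationConfig, generate_cohort, clean_default_runs,
                        ScoringConfig, score_sleep_wake, collapse_hypnogram,
                        cohort_concordance, sweep_thresholds)

cohort = [(clean_default_runs(a)[0], h)
          for a, h in generate_cohort(SimulationConfig(n_participants=41, seed=1))]
train, test = cohort[:20], cohort[20:]

sweep = sweep_thresholds(train)                      # integer grid 2..25
print("trained threshold:", sweep.optimal_threshold)

cfg = ScoringConfig(wake_threshold=sweep.optimal_threshold)
pairs = [(collapse_hypnogram(h), score_sleep_wake(a, cfg)) for a, h in test]
c = cohort_concordance(pairs)
print(f"test accuracy {c.pooled.accuracy:.3f}, "
      f"sensitivity {c.pooled.sensitivity:.3f}, "
      f"specificity {c.pooled.specificity:.3f}")
```

prints

```
trained threshold: 5.0
test accuracy 0.918, sensitivity 0.936, specificity 0.560
```

— the threshold of 5 units balanced sensitivity and specificity best on the
training nights; on the held-out test nights the device then catches 93.6%
of PSG sleep minutes but only 56.0% of PSG wake minutes. That asymmetry is
the characteristic actigraphy failure mode: quiet wakefulness (lying still
while awake) is indistinguishable from sleep by movement alone.

The same workflow is available as numbered drivers (`analysis/01_…` through
`05_…`), which write their tables and figures under `results/`, and as a CLI:

```sh
somnoscore simulate --n-participants 41 --seed 1 --out-dir data/
somnoscore run-study --manifest data/manifest.csv --out-dir results/study
```

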