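# Methods

## Problem and pipeline

`somnoscore` implements the analysis used to validate a consumer wrist
wearable's sleep/wake output against polysomnography (PSG): minute-epoch
accelerometer activity counts are smoothed with a weighted moving-average
kernel, thresholded into sleep/wake, and compared epoch-by-epoch against a
PSG hypnogram collapsed to the same minute grid. The wake threshold is
trained on one group of nights and all final performance measures are
computed on a held-out test group.

The pipeline stages are:

1. **Ingest and clean** (`epoch_data`). Activity CSVs are read onto a dense
   contiguous minute grid; absent minutes become missing epochs rather than
   shortening the series, so index arithmetic for the ±2-minute kernel stays
   valid across gaps. Idle devices emit runs of a default output value
   (20 units); every maximal run of exact-20 counts at least `min_run = 5`
   minutes long is marked missing. The run-length rule is our design choice:
   an isolated genuine count of 20 is kept, while ≥5 consecutive identical
   counts from a wrist device are implausible as real movement.
2. **Score** (`scoring`). Weighted total activity of minute *i* is
   `A_i = c_i + 0.2 (c_{i−1} + c_{i+1}) + 0.04 (c_{i−2} + c_{i+2})`, with
   out-of-range neighbours contributing zero. The epoch is sleep iff
   `A_i ≤ T` for wake threshold `T`; ties score sleep. Missing neighbours
   contribute zero by default (`missing_policy="zero"`); `"propagate"`
   instead marks any epoch whose ±2 window touches a gap as undefined, for
   users who prefer not to score across cleaned-out regions.
3. **Collapse and compare** (`concordance`). 30-s PSG stages are paired
   (1,2), (3,4), … from the recording start; a minute containing any scored
   wake is wake. Minutes whose two constituents disagree are *hybrid* and
   can be excluded (`exclude_hybrid`). PSG is ground truth and sleep the
   positive class: accuracy = (TP+TN)/total, sleep sensitivity = TP/(TP+FN),
   sleep specificity = TN/(TN+FP). Undefined metrics (e.g. a night without
   any PSG wake) are NaN, never 0, and are omitted from cohort means so they
   do not bias them downward. Cohort summaries report both the unweighted
   participant mean ± sample SD (n−1) and pooled metrics from the summed
   confusion matrix.
4. **Train the threshold** (`thresholds`). Candidate thresholds (integers
   2–25 units by default) are swept on the training group; "balancing
   sensitivity and specificity equally" is operationalized as maximizing
   Youden's J = sensitivity + specificity − 1 on pooled metrics, with ties
   broken toward the smaller threshold (the more wake-conservative choice).
   Minimum distance to the ROC corner (0, 1) is available as an alternative
   criterion, and participant-mean metrics as an alternative aggregation;
   both are defensible readings of "balanced", and on our synthetic cohorts
   they select the same or adjacent thresholds.
5. **Sleep parameters** (`summary`). TST is the count of sleep minutes over
   the jointly valid window; WASO counts wake minutes strictly between sleep
   onset and the last sleep epoch. Sleep onset is the first sleep-scored
   minute (`onset_k = 1`); a binary minute series carries no latency-rule
   information, so the minimal assumption is the default and a
   k-consecutive-minutes rule is configurable. Agreement across nights is
   summarized Bland-Altman style: bias = mean(device − PSG) with limits at
   ±1.96 sample SD.

## Synthetic cohort generator

No raw recordings ship with the package, so `simulate` generates paired
nights with the statistical structure the analysis assumes:

- **Hypnogram**: first-order Markov chain over {W, N1, N2, N3, REM} at 30-s
  resolution, 960 epochs per 480-minute night, started awake. Default rates
  give a mean wake-bout of ~4 min (W→W 0.875) and sleep→wake escape of
  ~0.005 per epoch, yielding cohort mean TST ≈ 455 min and WASO ≈ 20 min —
  a high-sleep-efficiency clinical cohort (emulation targets: TST 478 ± 75
  min, WASO ≈ 21 min; verified by a calibration test at n = 50).
- **Activity**: a minute is wake iff either of its 30-s stages is W. Moving
  wake minutes draw lognormal counts (mean 60 units, σ = 1.3), chosen to
  overlap the 2–25 threshold grid so the ROC bends inside the grid as it
  does on real wrist data. Sleep minutes are zero except for movement
  bursts (p = 0.03 per minute, lognormal mean 40). Five minutes of the
  device-default value 20 are padded at each end.
- **Quiet wakefulness**: with probability 0.45 an entire wake bout is
  motionless (zero counts). Quiet wake is modelled per *bout*, not i.i.d.
  per minute: quiet wakefulness is a sustained behavioral state, and only
  contiguous zero-count bouts reproduce the key failure mode — the scoring
  kernel cannot rescue a quiet minute from its equally quiet neighbours, so
  specificity falls by roughly the quiet fraction while sensitivity is
  untouched. This is the lever that pins sleep specificity near 0.5.
- **Seeding**: one master seed; participant *p*'s hypnogram and activity use
  `numpy` `SeedSequence(seed, spawn_key=(p, stream))`, so cohorts are
  reproducible bit-for-bit and extensible without perturbing earlier nights.
  Fixed-size draws (quiet-bout coins, sleep bursts) are consumed before
  variable-size ones so the sleep-side realization is invariant to the
  quiet-wake setting.

What the generator does **not** emulate: ultradian stage cycling and
circadian modulation; long sleep latencies (the single transition matrix
gives the initial wake run the same ~4-min mean as later bouts, where
clinical cohorts often lie awake much longer before onset); within-night
autocorrelation of activity amplitude; inter-device variability. Passing
tests therefore demonstrate the correctness and the qualitative regime of
the method (sleep-dominant nights, high sensitivity, quiet-wake-limited
specificity), not clinical performance on any real population. In
particular the *sign* of the TST bias on synthetic cohorts can differ from
a clinical cohort's, because it is the net of false wake from movement
bursts against false sleep from quiet wake, and that balance depends on how
much wake a cohort contains.

## Numerical and degenerate-input choices

- Scoring is an exact discrete convolution; no rounding occurs anywhere
  before presentation. Concordance metrics are exact integer ratios.
- Boundary epochs use zero padding (biasing the first/last two minutes
  toward sleep); records begin and end around lights-off/on, and users who
  prefer to drop kernel-truncated epochs can mark them missing.
- A sub-minute clock offset between device and PSG grids is rejected by
  default; `round_offsets=True` snaps to the nearest minute.
- A trailing unpaired 30-s epoch decides its minute alone and is never
  hybrid. An all-wake night has TST 0, WASO 0 and no onset. A single-night
  Bland-Altman has a bias but NaN limits. Sample SDs over one participant
  are reported as 0 with the n = 1 caveat carried by the report.
- Problem sizes in the test suite and the acceptance script (cohorts of
  8–50 nights of 240–480 min; 20 replicates for threshold recovery) were
  chosen as the smallest sizes at which the stochastic properties under
  test concentrate well inside their tolerance bands.

## Known limitations

- Only the five-term weighted kernel is implemented; the original 1992
  coefficient sets and Webster rescoring rules are out of scope, as are
  epoch lengths other than 60 s and stage-level agreement.
- The comparison-device pathway accepts only pre-scored binary series;
  proprietary scoring software is not reimplemented.
- Pooled and participant-mean aggregations can disagree when night lengths
  vary; both are reported, pooled is the training default.
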