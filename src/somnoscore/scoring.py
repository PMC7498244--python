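"""Cole-Kripke weighted total-activity scoring of minute-epoch counts.

The weighted total activity of minute *i* is

    A_i = c_i + 0.2 * (c_{i-1} + c_{i+1}) + 0.04 * (c_{i-2} + c_{i+2})

and the epoch is scored SLEEP when A_i is at or below the wake threshold
value (ties score sleep), WAKE when above it.  Neighbours outside the record
contribute zero; the treatment of missing neighbours is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epoch_data import SLEEP, WAKE, ActivityEpochSeries, SleepWakeSeries

__all__ = ["KERNEL", "ScoringConfig", "total_activity", "score_sleep_wake"]

#: Symmetric five-term weights on epochs i-2 .. i+2.
KERNEL = np.array([0.04, 0.2, 1.0, 0.2, 0.04])


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the sleep/wake decision rule.

    wake_threshold
        Cutoff on weighted total activity, in device units; total activity
        less than or equal to this value scores the epoch as sleep.
    boundary_policy
        How the kernel treats neighbours outside the record; only
        ``zero_pad`` (out-of-range neighbours contribute 0) is defined.
    missing_policy
        ``zero``: missing neighbours contribute 0 to the weighted sum;
        ``propagate``: any missing neighbour makes A_i undefined.  The epoch's
        own missingness always makes A_i undefined.
    """

    wake_threshold: float
    boundary_policy: str = "zero_pad"
    missing_policy: str = "zero"

    def __post_init__(self):
        if not np.isfinite(self.wake_threshold) or self.wake_threshold < 0:
            raise ValueError("wake_threshold must be finite and >= 0")
        if self.boundary_policy != "zero_pad":
            raise ValueError(f"unknown boundary_policy {self.boundary_policy!r}")
        if self.missing_policy not in ("zero", "propagate"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


def total_activity(series: ActivityEpochSeries, config: ScoringConfig) -> np.ndarray:
    """Weighted total activity A_i per epoch; NaN where A_i is undefined."""
    counts = np.where(series.missing_mask, 0.0, series.counts)
    # explicit zero padding so out-of-range neighbours contribute 0 at any length
    padded = np.concatenate((np.zeros(2), counts, np.zeros(2)))
    a = np.convolve(padded, KERNEL, mode="valid")
    undefined = series.missing_mask.copy()
    if config.missing_policy == "propagate" and series.missing_mask.any():
        mpad = np.concatenate((np.zeros(2), series.missing_mask.astype(float), np.zeros(2)))
        undefined |= np.convolve(mpad, np.ones(5), mode="valid") > 0
    a = a.astype(float)
    a[undefined] = np.nan
    return a


def score_sleep_wake(series: ActivityEpochSeries, config: ScoringConfig) -> SleepWakeSeries:
    """Threshold total activity into a minute-epoch sleep/wake series.

    Epoch i is SLEEP iff A_i <= wake_threshold, WAKE otherwise; epochs with
    undefined A_i are missing in the output.
    """
    a = total_activity(series, config)
    undefined = np.isnan(a)
    states = np.where(np.nan_to_num(a) <= config.wake_threshold, SLEEP, WAKE).astype(np.int8)
    states[undefined] = WAKE  # placeholder under the mask
    return SleepWakeSeries(series.participant_id, series.start_time, states,
                           missing_mask=undefined)
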