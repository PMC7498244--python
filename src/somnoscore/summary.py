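"""Night-level sleep parameters and Bland-Altman agreement.

Total sleep time (TST) is the number of minutes scored sleep over the
record; wake after sleep onset (WASO) counts wake minutes strictly between
sleep onset and the final sleep epoch ("before the terminal awakening").
Sleep onset defaults to the first sleep-scored minute; a stricter rule
(first run of k consecutive sleep minutes) is available via ``onset_k``.
Device-vs-reference agreement across a cohort is summarized Bland-Altman
style: mean difference (bias, device minus reference) with 1.96-SD limits
of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .epoch_data import SLEEP, WAKE, SleepWakeSeries, align_series

__all__ = ["SleepSummary", "BlandAltmanResult", "summarize_night",
           "bland_altman", "cohort_bias"]


@dataclass(frozen=True)
class SleepSummary:
    """TST/WASO for one night.  Indices refer to the series epoch grid;
    ``onset_index`` is None for an all-wake record."""

    tst_min: int
    waso_min: int
    onset_index: int | None
    last_sleep_index: int | None


def summarize_night(s: SleepWakeSeries, onset_k: int = 1) -> SleepSummary:
    """Night-level TST and WASO from a binary minute series.

    Missing epochs are excluded from every count.  Onset is the first epoch
    of the first run of ``onset_k`` consecutive valid sleep epochs
    (default 1: the first sleep epoch); WASO counts valid wake epochs with
    index strictly between onset and the last sleep epoch.
    """
    if onset_k < 1:
        raise ValueError("onset_k must be >= 1")
    valid = ~s.missing_mask
    sleep = valid & (s.states == SLEEP)
    tst = int(sleep.sum())
    if tst == 0:
        return SleepSummary(tst_min=0, waso_min=0, onset_index=None, last_sleep_index=None)
    idx = np.flatnonzero(sleep)
    onset = None
    if onset_k == 1:
        onset = int(idx[0])
    else:
        run = 0
        for i in range(len(s)):
            run = run + 1 if sleep[i] else 0
            if run >= onset_k:
                onset = int(i - onset_k + 1)
                break
    if onset is None:
        return SleepSummary(tst_min=0, waso_min=0, onset_index=None, last_sleep_index=None)
    last = int(idx[-1])
    wake = valid & (s.states == WAKE)
    waso = int(wake[onset + 1:last].sum())
    return SleepSummary(tst_min=tst, waso_min=waso, onset_index=onset, last_sleep_index=last)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement for device minus reference differences."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray

    @property
    def n(self) -> int:
        return self.diffs.size


def bland_altman(device_values, reference_values) -> BlandAltmanResult:
    """Agreement between paired per-participant values (device - reference).

    Bias is the arithmetic mean of differences; limits of agreement are
    bias ± 1.96 times the sample SD of differences.  With a single pair the
    SD and limits are NaN (bias only).
    """
    dev = np.asarray(device_values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    if dev.shape != ref.shape or dev.ndim != 1:
        raise ValueError(f"paired sequences must have equal length, got {dev.shape} and {ref.shape}")
    if dev.size == 0:
        raise ValueError("need at least one pair")
    diffs = dev - ref
    means = (dev + ref) / 2.0
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1)) if dev.size > 1 else math.nan
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                             means=means, diffs=diffs)


def cohort_bias(pairs, onset_k: int = 1) -> tuple[BlandAltmanResult, BlandAltmanResult]:
    """TST and WASO Bland-Altman results over (device, psg) night pairs.

    Each pair is restricted to its jointly valid minutes before
    summarizing, so both members are summarized over the same window.
    Sign convention: device minus PSG, so a positive TST bias means the
    device overestimates sleep.
    """
    dev_tst, ref_tst, dev_waso, ref_waso = [], [], [], []
    for device, psg in pairs:
        table = align_series(device, psg)
        d = SleepWakeSeries(device.participant_id, table["timestamp"].iloc[0],
                            table["a"].to_numpy())
        p = SleepWakeSeries(psg.participant_id, table["timestamp"].iloc[0],
                            table["b"].to_numpy())
        sd_, sp_ = summarize_night(d, onset_k=onset_k), summarize_night(p, onset_k=onset_k)
        dev_tst.append(sd_.tst_min)
        ref_tst.append(sp_.tst_min)
        dev_waso.append(sd_.waso_min)
        ref_waso.append(sp_.waso_min)
    return bland_altman(dev_tst, ref_tst), bland_altman(dev_waso, ref_waso)
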