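"""Hypnogram collapsing and epoch-by-epoch sleep/wake concordance.

PSG hypnograms scored in 30-s epochs are collapsed to the device's minute
grid with a wake-if-any rule: a minute containing any scored wake is wake.
Minutes whose two constituent 30-s epochs disagree ("hybrid" or split
epochs) are flagged so they can optionally be excluded from agreement
statistics.  PSG is the ground truth and sleep the positive class
throughout: sleep sensitivity equals wake specificity and vice versa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .epoch_data import SLEEP, WAKE, HypnogramSeries, SleepWakeSeries, align_series

__all__ = ["ConfusionMatrix", "ConcordanceStats", "CohortConcordance",
           "collapse_hypnogram", "confusion", "metrics", "cohort_concordance"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Epoch counts with PSG as truth and sleep as the positive class."""

    tp: int  # PSG sleep, device sleep
    fn: int  # PSG sleep, device wake
    fp: int  # PSG wake, device sleep
    tn: int  # PSG wake, device wake

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)


@dataclass(frozen=True)
class ConcordanceStats:
    """Accuracy, sleep sensitivity and sleep specificity as exact ratios.

    Undefined metrics (no PSG-sleep or no PSG-wake epochs) are NaN, not 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    n_epochs: int


def collapse_hypnogram(h: HypnogramSeries, phase: int = 0) -> SleepWakeSeries:
    """Collapse a 30-s hypnogram to minute-level sleep/wake (wake if any W).

    30-s epochs are paired (1,2), (3,4), ... from the hypnogram start;
    ``phase=1`` shifts pairing by one epoch, the leading epoch then forming
    a minute by itself.  A trailing unpaired epoch decides its minute alone.
    ``hybrid_mask`` marks minutes whose two constituents disagreed; single-
    epoch minutes are never hybrid.
    """
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    w = (h.stages == "W")
    if len(h) == 1:
        log.warning("collapsing a single-epoch hypnogram to one minute")
    chunks = []
    i = 0
    if phase == 1:
        chunks.append((w[0], False))
        i = 1
    while i < len(w):
        pair = w[i:i + 2]
        chunks.append((bool(pair.any()), len(pair) == 2 and bool(pair[0] != pair[1])))
        i += 2
    states = np.array([SLEEP if not wake else WAKE for wake, _ in chunks], dtype=np.int8)
    hybrid = np.array([hy for _, hy in chunks], dtype=bool)
    return SleepWakeSeries(h.participant_id, h.start_time, states, hybrid_mask=hybrid)


def confusion(psg: SleepWakeSeries, device: SleepWakeSeries,
              exclude_hybrid: bool = False) -> ConfusionMatrix:
    """Count jointly valid minutes into the four agreement cells.

    The two series are aligned by timestamp first; with ``exclude_hybrid``,
    minutes whose PSG 30-s constituents disagreed are dropped.
    """
    table = align_series(psg, device)
    if exclude_hybrid:
        table = table[~table["hybrid_a"]]
    if len(table) == 0:
        raise ValueError("no jointly valid epochs to compare")
    p = table["a"].to_numpy()
    d = table["b"].to_numpy()
    return ConfusionMatrix(
        tp=int(((p == SLEEP) & (d == SLEEP)).sum()),
        fn=int(((p == SLEEP) & (d == WAKE)).sum()),
        fp=int(((p == WAKE) & (d == SLEEP)).sum()),
        tn=int(((p == WAKE) & (d == WAKE)).sum()),
    )


def metrics(m: ConfusionMatrix) -> ConcordanceStats:
    """Accuracy (TP+TN)/total, sensitivity TP/(TP+FN), specificity TN/(TN+FP).

    Ratios are exact (no internal rounding); a metric with an empty
    denominator is NaN.
    """
    if m.total < 1:
        raise ValueError("confusion matrix is empty")
    sens = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else math.nan
    spec = m.tn / (m.tn + m.fp) if (m.tn + m.fp) > 0 else math.nan
    return ConcordanceStats(accuracy=(m.tp + m.tn) / m.total,
                            sensitivity=sens, specificity=spec, n_epochs=m.total)


@dataclass(frozen=True)
class CohortConcordance:
    """Per-participant, mean ± SD, and pooled concordance for a cohort."""

    per_participant: list[ConcordanceStats]
    matrices: list[ConfusionMatrix]
    pooled_matrix: ConfusionMatrix
    pooled: ConcordanceStats
    mean: dict[str, float]
    sd: dict[str, float]

    @property
    def n_participants(self) -> int:
        return len(self.per_participant)


def _mean_sd(values: list[float], metric: str) -> tuple[float, float]:
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if vals.size < len(values):
        log.info("omitting %d participant(s) with undefined %s from mean/SD",
                 len(values) - vals.size, metric)
    if vals.size == 0:
        return math.nan, math.nan
    # sample SD (n-1); a single participant reports SD 0 by convention
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def cohort_concordance(pairs, exclude_hybrid: bool = False) -> CohortConcordance:
    """Concordance across a cohort of aligned (psg, device) night pairs.

    Participants are weighted equally in the mean ± SD summaries regardless
    of night length; pooled metrics come from the elementwise-summed
    confusion matrix.  Participants with an undefined metric are omitted
    from that metric's mean/SD.
    """
    if len(pairs) < 1:
        raise ValueError("cohort must contain at least one participant")
    mats, stats = [], []
    for psg, device in pairs:
        try:
            m = confusion(psg, device, exclude_hybrid=exclude_hybrid)
        except ValueError as exc:
            raise ValueError(f"participant {psg.participant_id!r}: {exc}") from exc
        mats.append(m)
        stats.append(metrics(m))
    pooled_matrix = mats[0]
    for m in mats[1:]:
        pooled_matrix = pooled_matrix + m
    mean, sd = {}, {}
    for name in ("accuracy", "sensitivity", "specificity"):
        mean[name], sd[name] = _mean_sd([getattr(s, name) for s in stats], name)
    return CohortConcordance(per_participant=stats, matrices=mats,
                             pooled_matrix=pooled_matrix, pooled=metrics(pooled_matrix),
                             mean=mean, sd=sd)
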