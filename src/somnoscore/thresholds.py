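"""Wake-threshold sweep, ROC construction and balanced threshold selection.

A training cohort of (activity, PSG) night pairs is scored at each candidate
wake threshold; the resulting cohort concordance traces a discrete ROC
curve (sensitivity rises and specificity falls monotonically in the
threshold because the decision rule is A_i <= threshold).  The operating
threshold is the one balancing sensitivity and specificity equally —
by default the maximizer of Youden's J = sensitivity + specificity - 1,
with minimum distance to the ideal (0, 1) corner offered as an alternative
balance criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .concordance import CohortConcordance, cohort_concordance, collapse_hypnogram
from .scoring import ScoringConfig, score_sleep_wake

__all__ = ["DEFAULT_GRID", "ThresholdSweepResult", "sweep_thresholds",
           "select_optimal", "roc_points"]

#: Default candidate grid: integer thresholds 2..25 device units.
DEFAULT_GRID = tuple(range(2, 26))


@dataclass(frozen=True)
class ThresholdSweepResult:
    """Per-threshold cohort concordance plus the selected operating point."""

    thresholds: tuple
    per_threshold: list[CohortConcordance]
    criterion: str
    criterion_values: np.ndarray
    optimal_threshold: float

    def pooled_sensitivity(self) -> np.ndarray:
        return np.array([c.pooled.sensitivity for c in self.per_threshold])

    def pooled_specificity(self) -> np.ndarray:
        return np.array([c.pooled.specificity for c in self.per_threshold])


def _criterion_values(sens: np.ndarray, spec: np.ndarray, criterion: str) -> np.ndarray:
    if criterion == "youden":
        return sens + spec - 1.0
    if criterion == "distance":
        # negated distance to the (FPR, sens) = (0, 1) corner, so argmax applies
        return -np.hypot(1.0 - spec, 1.0 - sens)
    raise ValueError(f"unknown balance criterion {criterion!r}")


def sweep_thresholds(cohort, thresholds=DEFAULT_GRID, exclude_hybrid: bool = False,
                     criterion: str = "youden", per_participant: bool = False,
                     missing_policy: str = "zero") -> ThresholdSweepResult:
    """Score every night at every candidate threshold and select the optimum.

    ``cohort`` is a sequence of (ActivityEpochSeries, HypnogramSeries) pairs;
    hypnograms are collapsed to minute-level wake-if-any series internally.
    The balance criterion is evaluated on pooled metrics by default, or on
    participant-mean metrics with ``per_participant``.
    """
    thresholds = tuple(thresholds)
    if len(thresholds) == 0:
        raise ValueError("threshold grid is empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if len(cohort) < 1:
        raise ValueError("cohort must contain at least one participant")

    collapsed = [collapse_hypnogram(h) for _, h in cohort]
    per_threshold = []
    for thr in thresholds:
        cfg = ScoringConfig(wake_threshold=float(thr), missing_policy=missing_policy)
        try:
            pairs = [(psg, score_sleep_wake(act, cfg))
                     for (act, _), psg in zip(cohort, collapsed)]
            per_threshold.append(cohort_concordance(pairs, exclude_hybrid=exclude_hybrid))
        except ValueError as exc:
            raise ValueError(f"threshold {thr}: {exc}") from exc

    if per_participant:
        sens = np.array([c.mean["sensitivity"] for c in per_threshold])
        spec = np.array([c.mean["specificity"] for c in per_threshold])
    else:
        sens = np.array([c.pooled.sensitivity for c in per_threshold])
        spec = np.array([c.pooled.specificity for c in per_threshold])
    if np.isnan(sens).any() or np.isnan(spec).any():
        bad = thresholds[int(np.flatnonzero(np.isnan(sens) | np.isnan(spec))[0])]
        raise ValueError(f"undefined pooled sensitivity/specificity at threshold {bad}")
    crit = _criterion_values(sens, spec, criterion)
    optimal = thresholds[int(np.argmax(crit))]  # argmax takes the first = smallest tie
    return ThresholdSweepResult(thresholds=thresholds, per_threshold=per_threshold,
                                criterion=criterion, criterion_values=crit,
                                optimal_threshold=float(optimal))


def select_optimal(sweep: ThresholdSweepResult) -> float:
    """The threshold maximizing the balance criterion; ties go to the smallest."""
    return float(sweep.thresholds[int(np.argmax(sweep.criterion_values))])


def roc_points(sweep: ThresholdSweepResult) -> np.ndarray:
    """(1 - specificity, sensitivity) per threshold, ordered by threshold."""
    return np.column_stack([1.0 - sweep.pooled_specificity(), sweep.pooled_sensitivity()])
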