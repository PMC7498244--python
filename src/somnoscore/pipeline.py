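"""End-to-end study workflow: clean, score, train, validate, summarize.

Mirrors the validation-study design: participants are split into a training
group, used only to select the wake threshold, and a test group on which
every final performance measure is computed with that trained threshold.
The report carries pooled and per-participant concordance, TST/WASO
Bland-Altman agreement, the ROC table of the training sweep, optional
side-by-side metrics for a pre-scored comparison device, and a structured
log of every parameter and file consumed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import (CohortConcordance, cohort_concordance, collapse_hypnogram)
from .epoch_data import (ActivityEpochSeries, HypnogramSeries, SleepWakeSeries,
                         clean_default_runs, read_activity_csv,
                         read_hypnogram_csv, read_sleepwake_csv)
from .scoring import ScoringConfig, score_sleep_wake
from .summary import cohort_bias
from .thresholds import DEFAULT_GRID, ThresholdSweepResult, roc_points, sweep_thresholds

__all__ = ["StudyManifest", "StudyOptions", "run_study", "load_manifest"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyParticipant:
    participant_id: str
    group: str  # "training" or "test"
    activity: ActivityEpochSeries
    hypnogram: HypnogramSeries
    comparison: SleepWakeSeries | None = None


@dataclass(frozen=True)
class StudyManifest:
    participants: list[StudyParticipant]

    def __post_init__(self):
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique")

    def group(self, name: str) -> list[StudyParticipant]:
        return [p for p in self.participants if p.group == name]


@dataclass(frozen=True)
class StudyOptions:
    thresholds: tuple = DEFAULT_GRID
    criterion: str = "youden"
    exclude_hybrid: bool = False
    default_value: float = 20.0
    min_run: int = 5
    missing_policy: str = "zero"


def load_manifest(path) -> StudyManifest:
    """Read a manifest CSV (participant_id, group, activity_path,
    hypnogram_path, comparison_path) and load every referenced file."""
    df = pd.read_csv(path, dtype=str).fillna("")
    base = Path(path).parent
    participants = []
    for _, row in df.iterrows():
        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p
        comparison = None
        if row.get("comparison_path", ""):
            comparison = read_sleepwake_csv(_resolve(row["comparison_path"]),
                                            participant_id=row["participant_id"])
        participants.append(StudyParticipant(
            participant_id=row["participant_id"],
            group=row["group"],
            activity=read_activity_csv(_resolve(row["activity_path"]),
                                       participant_id=row["participant_id"]),
            hypnogram=read_hypnogram_csv(_resolve(row["hypnogram_path"]),
                                         participant_id=row["participant_id"]),
            comparison=comparison,
        ))
    return StudyManifest(participants)


def _concordance_dict(c: CohortConcordance) -> dict:
    m = c.pooled_matrix
    return {
        "pooled_matrix": {"tp": m.tp, "fn": m.fn, "fp": m.fp, "tn": m.tn},
        "pooled": {"accuracy": c.pooled.accuracy, "sensitivity": c.pooled.sensitivity,
                   "specificity": c.pooled.specificity, "n_epochs": c.pooled.n_epochs},
        "mean": c.mean, "sd": c.sd,
        "per_participant": [
            {"tp": mm.tp, "fn": mm.fn, "fp": mm.fp, "tn": mm.tn,
             "accuracy": s.accuracy, "sensitivity": s.sensitivity,
             "specificity": s.specificity, "n_epochs": s.n_epochs}
            for mm, s in zip(c.matrices, c.per_participant)],
    }


def _ba_dict(ba) -> dict:
    return {"bias": ba.bias, "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": ba.n,
            "means": ba.means.tolist(), "diffs": ba.diffs.tolist()}


def run_study(manifest: StudyManifest, options: StudyOptions = StudyOptions(),
              output_dir=None) -> dict:
    """Train the wake threshold on the training group, validate on the test
    group, and return (optionally write) the full study report.

    Per-participant failures are logged and excluded, incrementing the
    report's warning count; a missing group is an error.
    """
    report: dict = {"options": {
        "thresholds": list(options.thresholds), "criterion": options.criterion,
        "exclude_hybrid": options.exclude_hybrid,
        "default_value": options.default_value, "min_run": options.min_run,
        "missing_policy": options.missing_policy,
    }, "warnings": 0, "log": []}

    groups: dict[str, list] = {"training": [], "test": []}
    comparisons: list[tuple[str, SleepWakeSeries, HypnogramSeries]] = []
    for p in manifest.participants:
        if p.group not in groups:
            report["log"].append(f"participant {p.participant_id}: unknown group {p.group!r}, skipped")
            report["warnings"] += 1
            continue
        try:
            cleaned, removed = clean_default_runs(p.activity, options.default_value,
                                                  options.min_run)
            report["log"].append(
                f"participant {p.participant_id}: {len(p.activity)} activity epochs, "
                f"{removed} device-default epochs removed")
            groups[p.group].append((p.participant_id, cleaned, p.hypnogram))
            if p.comparison is not None:
                comparisons.append((p.participant_id, p.comparison, p.hypnogram))
        except ValueError as exc:
            log.warning("participant %s excluded: %s", p.participant_id, exc)
            report["log"].append(f"participant {p.participant_id} excluded: {exc}")
            report["warnings"] += 1
    for name, members in groups.items():
        if not members:
            raise ValueError(f"no usable participants in the {name} group")

    train_pairs = [(act, hyp) for _, act, hyp in groups["training"]]
    sweep = sweep_thresholds(train_pairs, thresholds=options.thresholds,
                             exclude_hybrid=options.exclude_hybrid,
                             criterion=options.criterion,
                             missing_policy=options.missing_policy)
    threshold = sweep.optimal_threshold
    report["trained_threshold"] = threshold
    report["roc"] = [
        {"threshold": t, "sensitivity": s, "specificity": sp, "criterion": c}
        for t, s, sp, c in zip(sweep.thresholds, sweep.pooled_sensitivity(),
                               sweep.pooled_specificity(), sweep.criterion_values)]
    idx = list(sweep.thresholds).index(threshold)
    report["training_concordance"] = _concordance_dict(sweep.per_threshold[idx])

    cfg = ScoringConfig(wake_threshold=threshold, missing_policy=options.missing_policy)

    def _evaluate(members):
        scored = [(collapse_hypnogram(hyp), score_sleep_wake(act, cfg))
                  for _, act, hyp in members]
        conc = cohort_concordance(scored, exclude_hybrid=options.exclude_hybrid)
        tst_ba, waso_ba = cohort_bias([(dev, psg) for psg, dev in scored])
        return conc, tst_ba, waso_ba

    test_conc, tst_ba, waso_ba = _evaluate(groups["test"])
    report["test_concordance"] = _concordance_dict(test_conc)
    report["bland_altman"] = {"tst": _ba_dict(tst_ba), "waso": _ba_dict(waso_ba)}

    if comparisons:
        pairs = [(collapse_hypnogram(hyp), dev) for _, dev, hyp in comparisons]
        comp = cohort_concordance(pairs, exclude_hybrid=options.exclude_hybrid)
        ctst, cwaso = cohort_bias([(dev, psg) for psg, dev in pairs])
        report["comparison_device"] = {
            "concordance": _concordance_dict(comp),
            "bland_altman": {"tst": _ba_dict(ctst), "waso": _ba_dict(cwaso)},
        }

    if output_dir is not None:
        _write_report(report, Path(output_dir))
    return report


def _write_report(report: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=True, default=_json_default)
        fh.write("\n")
    pd.DataFrame(report["roc"]).to_csv(out / "roc.csv", index=False)
    for key in ("training_concordance", "test_concordance"):
        pd.DataFrame(report[key]["per_participant"]).to_csv(
            out / f"{key}_per_participant.csv", index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
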