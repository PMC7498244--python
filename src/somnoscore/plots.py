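"""Plot helpers: ROC curve, Bland-Altman scatter, metric box plots.

All functions draw onto a freshly created matplotlib Figure and return it;
callers save or show.  Uses the Agg-safe pyplot API only, so headless runs
need no display.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .summary import BlandAltmanResult  # noqa: E402
from .thresholds import ThresholdSweepResult, roc_points  # noqa: E402

__all__ = ["plot_roc", "plot_bland_altman", "plot_metric_boxes"]


def plot_roc(sweep: ThresholdSweepResult, annotate: bool = True):
    """ROC of the threshold sweep; one point per candidate threshold."""
    pts = roc_points(sweep)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(pts[:, 0], pts[:, 1], "o-", ms=4)
    if annotate:
        for thr, (x, y) in zip(sweep.thresholds, pts):
            ax.annotate(f"{thr:g}", (x, y), fontsize=7,
                        textcoords="offset points", xytext=(4, -4))
    ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
    opt = list(sweep.thresholds).index(sweep.optimal_threshold)
    ax.plot(pts[opt, 0], pts[opt, 1], "r*", ms=12,
            label=f"selected threshold = {sweep.optimal_threshold:g}")
    ax.set_xlabel("1 - specificity (false wake-as-sleep rate)")
    ax.set_ylabel("sensitivity (sleep detected as sleep)")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    fig.tight_layout()
    return fig


def plot_bland_altman(result: BlandAltmanResult, parameter: str = "TST"):
    """Difference-vs-mean scatter with bias and 1.96-SD agreement limits."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18)
    ax.axhline(result.bias, color="k", lw=1, label=f"bias {result.bias:.1f} min")
    for lim in (result.loa_low, result.loa_high):
        ax.axhline(lim, color="k", ls=":", lw=1)
    ax.set_xlabel(f"mean of device and PSG {parameter} (min)")
    ax.set_ylabel(f"device - PSG {parameter} (min)")
    ax.legend(loc="upper right")
    fig.tight_layout()
    return fig


def plot_metric_boxes(metric_values: dict, ylabel: str):
    """Box plots of a per-participant metric, one box per labelled source."""
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(metric_values), 4))
    ax.boxplot(list(metric_values.values()), tick_labels=list(metric_values.keys()))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return fig
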