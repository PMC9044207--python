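"""Figure export for method comparisons: metric box plots and CD diagrams.

Matplotlib is imported lazily so the core pipeline has no hard plotting
dependency.
"""

from __future__ import annotations

import numpy as np

from .errors import StatsError
from .stats import ResultsTable, StatReport

__all__ = ["boxplot_metric", "cd_diagram"]


def boxplot_metric(table: ResultsTable, metric: str, path=None, ax=None):
    """Box plot of the per-video metric distribution of each method."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    wide = table.matrix(metric)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * wide.shape[1] + 2, 4))
    ax.boxplot([wide[c] for c in wide.columns], tick_labels=list(wide.columns))
    ax.set_ylabel(metric)
    ax.set_xlabel("method")
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(ax.figure)
    return ax


def cd_diagram(report: StatReport, path=None, ax=None):
    """Critical-difference diagram: mean ranks with bars joining tied groups.

    Methods within one critical difference of each other (from the Nemenyi
    analysis) are connected; only meaningful after a Friedman comparison.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if report.cd is None:
        raise StatsError("report carries no critical-difference data "
                         "(Friedman path only)")
    ranks = report.group_stats["MR"].sort_values()
    names = list(ranks.index)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 1.2 + 0.4 * len(names)))
    ax.set_xlim(0.5, len(names) + 0.5)
    for i, (name, r) in enumerate(ranks.items()):
        y = -i
        ax.plot([r], [y], "o", color="k")
        ax.annotate(f"{name} ({r:.2f})", (r, y), textcoords="offset points",
                    xytext=(6, 4), fontsize=9)
    groups = report.cd_groups or []
    for j, g in enumerate(g for g in groups if len(g) > 1):
        rs = [ranks[m] for m in g]
        ax.plot([min(rs), max(rs)], [0.5 + 0.25 * j] * 2, lw=3, color="0.4")
    ax.axhline(0.4, color="none")
    ax.set_yticks([])
    ax.set_xlabel(f"mean rank (CD = {report.cd:.3f} at alpha = {report.alpha})")
    for spine in ("left", "right", "top"):
        ax.spines[spine].set_visible(False)
    if path:
        ax.figure.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(ax.figure)
    return ax
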