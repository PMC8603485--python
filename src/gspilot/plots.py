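"""Generic trial plots: adherence spaghetti and posterior interval plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["spaghetti_plot", "posterior_interval_plot"]


def spaghetti_plot(adherence: pd.DataFrame, value_col: str = "pill_count_pct",
                   ax=None):
    """Per-participant adherence trajectories, one panel, colored by arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    colors = {"placebo": "tab:blue", "mph": "tab:orange"}
    for (pid, arm), grp in adherence.groupby(["participant_id", "arm"]):
        grp = grp.sort_values("visit_week")
        ax.plot(grp["visit_week"], grp[value_col], marker="o", alpha=0.5,
                color=colors.get(arm, "gray"),
                label=arm if pid.endswith("001") else None)
    means = (adherence.groupby(["arm", "visit_week"])[value_col]
             .mean().reset_index())
    for arm, grp in means.groupby("arm"):
        ax.plot(grp["visit_week"], grp[value_col], lw=3,
                color=colors.get(arm, "gray"))
    ax.set_xlabel("week")
    ax.set_ylabel(value_col)
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys())
    return ax


def posterior_interval_plot(summary, ax=None):
    """Median with 80%/95% credible bars for each fixed effect."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    names = list(summary.coef_names)
    for i, nm in enumerate(names):
        lo95, hi95 = summary.ci95[nm]
        lo80, hi80 = summary.ci80[nm]
        ax.plot([lo95, hi95], [i, i], lw=1.5, color="tab:blue")
        ax.plot([lo80, hi80], [i, i], lw=4, color="tab:blue")
        ax.plot(summary.medians[nm], i, "o", color="black")
    ax.axvline(0, color="gray", ls=":")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("coefficient")
    return ax
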