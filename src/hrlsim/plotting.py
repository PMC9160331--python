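"""Convenience plots of cohort summaries (regulation-timeline panels).

Not part of the tested contract; a thin wrapper over matplotlib for
eyeballing runs: internal state, action values, intake probability and
reward per trial, with mean +/- 2 SD bands across the cohort.
"""

from __future__ import annotations

from .experiments import CohortSummary

__all__ = ["plot_cohort_summary"]


def plot_cohort_summary(summary: CohortSummary, setpoint: float | None = None):
    """Plot the per-trial panels for one cohort; returns the Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = {
        "internal state H": [c for c in summary.mean.columns if c.startswith("H_")],
        "action value Q": [c for c in summary.mean.columns if c.startswith("Q_")],
        "choice probability P": [c for c in summary.mean.columns if c.startswith("P_")],
        "reward R": ["reward"],
    }
    fig, axes = plt.subplots(len(groups), 1, figsize=(7, 9), sharex=True)
    trials = summary.mean.index.to_numpy()
    for ax, (title, cols) in zip(axes, groups.items()):
        for col in cols:
            m = summary.mean[col].to_numpy()
            s = summary.sd[col].to_numpy()
            ax.plot(trials, m, label=col)
            ax.fill_between(trials, m - 2 * s, m + 2 * s, alpha=0.2)
        if title.startswith("internal state") and setpoint is not None:
            ax.axhline(setpoint, ls=":", color="k", lw=1)
        ax.set_ylabel(title)
        ax.legend(fontsize=8, loc="best")
    axes[-1].set_xlabel("trial")
    fig.suptitle(summary.label or "cohort")
    fig.tight_layout()
    return fig
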