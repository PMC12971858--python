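"""Grouped bar charts of Monte Carlo median errors."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_summary"]


def plot_summary(summary: pd.DataFrame, path) -> None:
    """Bar chart of median errors per (pair, rsd), one panel per load type.

    ``summary`` is the long-format table from
    :func:`phagedyn.montecarlo.compile_summary`.
    """
    loads = sorted(summary["load"].unique())
    fig, axes = plt.subplots(
        1, len(loads), figsize=(6 * len(loads), 4), squeeze=False, sharey=True
    )
    for ax, load in zip(axes[0], loads):
        sub = summary[summary["load"] == load]
        pairs = sorted(sub["pair"].unique())
        rsds = sorted(sub["rsd_tau"].unique())
        width = 0.8 / len(pairs)
        x = np.arange(len(rsds))
        for i, pair in enumerate(pairs):
            vals = [
                float(sub[(sub["pair"] == pair) & (sub["rsd_tau"] == r)]
                      ["median_error_pct"].iloc[0])
                if ((sub["pair"] == pair) & (sub["rsd_tau"] == r)).any()
                else np.nan
                for r in rsds
            ]
            ax.bar(x + i * width, vals, width, label=pair)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels([f"{100 * r:.0f}%" for r in rsds])
        ax.set_xlabel("latent-period relative SD")
        ax.set_title(f"{load} load")
    axes[0][0].set_ylabel("median error (%)")
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
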