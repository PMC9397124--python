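"""Event-locked trajectory plots: group means, SEM bands, significance stars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_trajectories(
    elm: pd.DataFrame,
    stats: pd.DataFrame | None,
    metric: str,
    level: str,
    site: str,
    outpath: str | Path,
    alpha: float = 0.05,
) -> Path:
    """One panel per unit: per-group mean trajectory over the bins -2..+3.

    Shaded bands are +/- the standard error of the mean over subjects; stars
    mark bins whose FDR-corrected p (from ``stats``) falls below ``alpha``.
    With no stats table, no markers are drawn.
    """
    sel = elm[
        (elm["metric"] == metric) & (elm["level"] == level) & (elm["site"] == site)
    ]
    units = list(pd.unique(sel["unit"]))
    if not units:
        raise ValueError(f"no event-locked data for metric={metric}, level={level}")
    bins = sorted(sel["bin"].unique())
    ncol = min(4, len(units))
    nrow = int(np.ceil(len(units) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False, sharex=True
    )
    for ax, unit in zip(axes.ravel(), units):
        usel = sel[sel["unit"] == unit]
        ymax = -np.inf
        for group, gsel in usel.groupby("group"):
            wide = gsel.pivot_table(index="subject", columns="bin", values="value")
            mean = wide.mean(axis=0).reindex(bins)
            sem = wide.sem(axis=0).reindex(bins)
            ax.plot(bins, mean, marker="o", ms=3, label=str(group))
            ax.fill_between(bins, mean - sem, mean + sem, alpha=0.25)
            ymax = max(ymax, float((mean + sem).max()))
        if stats is not None and "p_fdr" in stats.columns:
            sig = stats[(stats["unit"] == unit) & (stats["p_fdr"] < alpha)]
            for b in sig["bin"]:
                ax.annotate(
                    "*", (b, ymax), ha="center", fontsize=12, color="black"
                )
        ax.set_title(str(unit), fontsize=9)
        ax.set_xticks(bins)
        ax.set_xticklabels([f"+{b}" if b > 0 else str(b) for b in bins])
    for ax in axes.ravel()[len(units):]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=8, frameon=False)
    fig.supxlabel("TR relative to stimulus onset")
    fig.supylabel({"pc": "participation coefficient", "z": "within-module z"}.get(
        metric, metric
    ))
    fig.tight_layout()
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(outpath, dpi=150)
    plt.close(fig)
    return outpath
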