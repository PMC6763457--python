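"""Figure helpers for visual QC: template maps, characteristic box plots,
moderation scatter plots. All functions write to a path and close the figure."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import CohortTable, TemplateSet


def plot_templates(sets: dict[str, TemplateSet], path: str | Path) -> Path:
    """One row of interpolated scalp maps per template set (head from above)."""
    names = list(sets)
    k = sets[names[0]].k
    fig, axes = plt.subplots(len(names), k, figsize=(2.2 * k, 2.2 * len(names)),
                             squeeze=False)
    for r, name in enumerate(names):
        ts = sets[name]
        xy = ts.montage.pos
        for c in range(k):
            ax = axes[r][c]
            ax.tricontourf(xy[:, 0], xy[:, 1], ts.maps[c], levels=24, cmap="RdBu_r")
            ax.add_patch(plt.Circle((0, 0), 1.02, fill=False, lw=1))
            ax.scatter(xy[:, 0], xy[:, 1], s=2, c="k")
            ax.set_aspect("equal")
            ax.axis("off")
            if r == 0:
                ax.set_title(ts.labels[c])
        axes[r][0].text(-1.6, 0, name, rotation=90, va="center")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_characteristic_boxes(ct: CohortTable, dv: str, path: str | Path) -> Path:
    """Grouped box plots of one temporal characteristic per microstate class."""
    long = ct.long(dv)
    groups = sorted(long["group"].unique())
    levels = sorted(long["level"].unique())
    fig, ax = plt.subplots(figsize=(1.1 * len(levels) + 2, 4))
    width = 0.35
    for gi, g in enumerate(groups):
        data = [long[(long["group"] == g) & (long["level"] == lv)]["value"].dropna()
                for lv in levels]
        pos = np.arange(len(levels)) + (gi - 0.5) * width * 1.1
        bp = ax.boxplot(data, positions=pos, widths=width, patch_artist=True,
                        whis=(2.5, 97.5))
        for box in bp["boxes"]:
            box.set_facecolor(["0.7", "0.3"][gi % 2])
    ax.set_xticks(np.arange(len(levels)))
    ax.set_xticklabels(levels, rotation=45 if len(levels) > 6 else 0)
    ax.set_ylabel(dv)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_moderation(
    ct: CohortTable, outcome: str, moderator: str, path: str | Path
) -> Path:
    """Per-group scatter of moderator vs outcome with least-squares lines."""
    df = ct.subjects.dropna(subset=[outcome, moderator])
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for g, colour in zip(sorted(df["group"].unique()), ("0.2", "0.6")):
        sub = df[df["group"] == g]
        ax.scatter(sub[moderator], sub[outcome], s=14, color=colour, label=g)
        if len(sub) > 2:
            b = np.polyfit(sub[moderator], sub[outcome], 1)
            xs = np.linspace(sub[moderator].min(), sub[moderator].max(), 20)
            ax.plot(xs, np.polyval(b, xs), color=colour)
    ax.set_xlabel(moderator)
    ax.set_ylabel(outcome)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
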