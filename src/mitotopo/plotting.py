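"""Minimal plotting helpers for feature curves and group summaries."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .features import FeatureCurve

__all__ = ["plot_curve_groups", "plot_summary_boxplot"]

_COLORS = {"A": "tab:blue", "B": "tab:orange"}


def plot_curve_groups(
    groups: Mapping[str, Sequence[FeatureCurve]], out: str | Path, title: str = ""
) -> Path:
    """Overlay per-image curves per group plus the group mean (NaN-skipping)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, (label, curves) in enumerate(groups.items()):
        color = f"C{k}"
        stack = []
        for c in curves:
            ax.plot(c.domain, c.values, color=color, alpha=0.3, lw=0.8)
            stack.append(c.values)
        if stack:
            mean = np.nanmean(np.asarray(stack, dtype=float), axis=0)
            ax.plot(curves[0].domain, mean, color=color, lw=2.0, label=f"{label} mean")
    ax.set_xlabel("domain index")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    ax.legend()
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


def plot_summary_boxplot(
    summaries: Mapping[str, Sequence[float]], out: str | Path, title: str = ""
) -> Path:
    """Side-by-side boxplot of per-image summary values for each group."""
    fig, ax = plt.subplots(figsize=(4, 4))
    labels = list(summaries)
    ax.boxplot([summaries[k] for k in labels], tick_labels=labels)
    ax.set_ylabel("summary value")
    if title:
        ax.set_title(title)
    out = Path(out)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out
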