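"""Plotting helpers: metric boxplots and histogram-overlay panels."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .distances import compare_samples


def metric_boxplots(
    metrics: pd.DataFrame, out_path: str | Path, title: str = ""
) -> Path:
    """Boxplots of both metrics per group (median, quartile box,
    1.5·IQR whiskers, outliers as points)."""
    out_path = Path(out_path)
    metrics = metrics.dropna(subset=["value_um"])
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=False)
    for ax, metric in zip(axes, ("reference", "spread")):
        sub = metrics[metrics["metric"] == metric]
        groups = list(sub["group"].unique())
        data = [sub.loc[sub["group"] == g, "value_um"].to_numpy() for g in groups]
        ax.boxplot(data, tick_labels=groups, whis=1.5)
        ax.set_title(f"{metric} metric")
        ax.set_ylabel("distance (µm)")
        ax.tick_params(axis="x", rotation=30)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def histogram_overlay(
    experimental: Sequence[float],
    simulated: Sequence[float],
    out_path: str | Path,
    label: str = "x",
) -> Path:
    """Overlaid experimental vs simulated histograms with the three
    similarity scores in the panel title."""
    out_path = Path(out_path)
    report = compare_samples(experimental, simulated)
    edges = np.asarray(report.bin_edges)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(experimental, bins=edges, color="black", alpha=0.55,
            label="experimental", density=True)
    ax.hist(simulated, bins=edges, color="tab:orange", alpha=0.55,
            label="simulated", density=True)
    ax.set_xlabel(label)
    ax.set_ylabel("density")
    ax.set_title(
        f"cos={report.cosine_distance:.3f}  "
        f"overlap={report.histogram_overlap:.3f}  "
        f"H={report.hellinger:.3f}",
        fontsize=9,
    )
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
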