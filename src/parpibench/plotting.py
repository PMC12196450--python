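"""Minimal plotting helpers: running-sum curve and GSEF box plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import GSEFResult
from .gsea import GSEAResult

__all__ = ["plot_running_sum", "plot_gsef"]


def plot_running_sum(result: GSEAResult, title: str = "", ax=None):
    """Enrichment running-sum curve with the ES extremum marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    running = result.running_sum
    ax.plot(np.arange(len(running)), running, lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    idx = int(np.argmax(np.abs(running)))
    ax.plot([idx], [running[idx]], "ro", ms=4)
    ax.set_xlabel("rank in gene list")
    ax.set_ylabel("running enrichment")
    ax.set_title(title or f"ES = {result.es:.3f}, NES = {result.nes:.3f}")
    return ax


def plot_gsef(results: list[GSEFResult], ax=None):
    """Paired box plot of per-module enrichment fractions per comparison."""
    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 * max(len(results), 1) + 2, 3.5))
    data, labels = [], []
    for g in results:
        data.extend([g.fractions_ref, g.fractions_other])
        labels.extend(g.biomarker_pair)
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("gene set enrichment fraction")
    ax.tick_params(axis="x", rotation=45)
    return ax
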