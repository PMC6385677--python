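"""Plots for half-time tables and pairwise z-score matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from modetime.interpret import HalfTimeTable, PairwiseScan

__all__ = ["plot_half_times", "plot_zscore_heatmap"]


def plot_half_times(
    table: HalfTimeTable, path: str | Path, reference: str = "ground"
) -> None:
    """Bar chart of ensemble half-times with 95% CI error bars."""
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(table.labels)), 3.2))
    x = np.arange(len(table.labels))
    err = np.vstack(
        [table.half_times - table.ci_low, table.ci_high - table.half_times]
    )
    colors = ["0.35" if lb == reference else "C0" for lb in table.labels]
    ax.bar(x, table.half_times, yerr=err, color=colors, capsize=3)
    if reference in table.labels:
        ax.axhline(table[reference], color="0.35", ls="--", lw=0.8)
    ax.set_xticks(x)
    ax.set_xticklabels(table.labels, rotation=45, ha="right")
    ax.set_ylabel("dissociation half-time / fs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_zscore_heatmap(scan: PairwiseScan, z: np.ndarray, path: str | Path) -> None:
    """Heat map of pairwise-excitation z-scores (columns = conditioning mode)."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    vmax = np.nanmax(np.abs(z)) or 1.0
    im = ax.imshow(z, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ticks = np.arange(scan.modes.size)
    ax.set_xticks(ticks, [str(m) for m in scan.modes])
    ax.set_yticks(ticks, [str(m) for m in scan.modes])
    ax.set_xlabel("conditioning mode")
    ax.set_ylabel("added excitation")
    fig.colorbar(im, ax=ax, label="half-time z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
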