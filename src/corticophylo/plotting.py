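"""Optional matplotlib renderings: rainfall plot and oncoplot."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mutation_summary import GeneSampleMatrix, RainfallTrack

__all__ = ["plot_rainfall", "plot_oncoplot"]

_SNV_COLORS = {
    "C>A": "#1f77b4", "C>G": "#000000", "C>T": "#d62728",
    "T>A": "#7f7f7f", "T>C": "#2ca02c", "T>G": "#e377c2",
}


def plot_rainfall(track: RainfallTrack, out: str | Path) -> None:
    """Genome-wide inter-mutation distance scatter (log10 y) for one sample."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for chrom in track.positions:
        pos = np.asarray(track.positions[chrom])
        d = np.asarray(track.distances[chrom], dtype=float)
        if len(d):
            ax.scatter(offset + pos[1:], np.log10(np.maximum(d, 1)), s=4)
        span = (pos.max() - pos.min() + 1) if len(pos) else 1
        ticks.append(offset + span / 2)
        labels.append(chrom)
        offset += span + 1
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("log10 inter-mutation distance (bp)")
    ax.set_title(f"Rainfall: {track.sample_id}")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_oncoplot(matrix: GeneSampleMatrix, out: str | Path) -> None:
    """Gene x sample presence heatmap with per-gene carrier counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * len(matrix.samples), 1 + 0.4 * len(matrix.genes))
    )
    ax.imshow(matrix.present, cmap="Greys", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(len(matrix.samples)))
    ax.set_xticklabels(matrix.samples, rotation=90, fontsize=7)
    counts = matrix.carrier_counts()
    ax.set_yticks(range(len(matrix.genes)))
    ax.set_yticklabels(
        [f"{g}  ({counts[g]})" for g in matrix.genes], fontsize=7
    )
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
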