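"""Optional figure output: stacked success-rate bars and synergy heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

# Success bars follow the conventional colouring: acceptable yellow,
# medium orange, high red.
QUALITY_COLOURS = {"acceptable": "#f2c94c", "medium": "#f2813c", "high": "#d83a2b"}


def plot_success_bars(table: pd.DataFrame, path: str | Path, top_n: int = 10) -> None:
    """Stacked bars of success counts at one top-N, one bar per metric."""
    sub = table[table["top_n"] == top_n]
    metrics = sub["metric"].unique()
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(metrics)), 4))
    counts = {q: [] for q in ("acceptable", "medium", "high")}
    for m in metrics:
        rows = sub[sub["metric"] == m].set_index("quality")["count"]
        high = rows.get("high", 0)
        medium = rows.get("medium", 0) - high
        acceptable = rows.get("acceptable", 0) - medium - high
        counts["high"].append(high)
        counts["medium"].append(medium)
        counts["acceptable"].append(acceptable)
    bottom = np.zeros(len(metrics))
    for q in ("high", "medium", "acceptable"):
        ax.bar(metrics, counts[q], bottom=bottom, color=QUALITY_COLOURS[q], label=q)
        bottom += np.array(counts[q], dtype=float)
    ax.set_ylabel(f"complexes with a solution in the top {top_n}")
    ax.legend()
    plt.setp(ax.get_xticklabels(), rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cardinality_heatmap(matrix: pd.DataFrame, path: str | Path,
                             title: str = "") -> None:
    """Heatmap of a pairwise cardinality matrix (already ordered)."""
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(matrix)),) * 2)
    im = ax.imshow(matrix.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix)), matrix.index, fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
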