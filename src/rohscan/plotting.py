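"""Plots: per-breed Manhattan-style ROH incidence with the hotspot threshold."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .data import chromosome_sort_key


def incidence_manhattan(
    incidence: pd.DataFrame,
    threshold: float,
    path: str,
    title: str = "ROH incidence",
) -> None:
    """Per-SNP ROH incidence along the genome, hotspot threshold dashed.

    ``incidence`` needs columns (chromosome, position, fraction).
    """
    chroms = sorted(incidence["chromosome"].unique(), key=chromosome_sort_key)
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, tick_labels = [], []
    for i, chrom in enumerate(chroms):
        sub = incidence[incidence["chromosome"] == chrom]
        x = sub["position"].to_numpy() + offset
        ax.scatter(x, sub["fraction"], s=2,
                   color="#1f77b4" if i % 2 == 0 else "#ff7f0e",
                   rasterized=True)
        ticks.append(offset + sub["position"].max() / 2)
        tick_labels.append(str(chrom))
        offset += sub["position"].max()
    ax.axhline(threshold, linestyle="--", color="red", linewidth=1,
               label=f"top-percentile threshold ({threshold:.3f})")
    ax.set_xticks(ticks)
    ax.set_xticklabels(tick_labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("fraction of individuals in ROH")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
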