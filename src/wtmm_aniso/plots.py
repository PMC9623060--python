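"""Optional figure export: group median curves with a per-scale p-value track."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_comparison", "plot_chain_overlay"]


def plot_comparison(
    medians: pd.DataFrame,
    ptrack: Optional[pd.DataFrame],
    path: str | Path,
    scale_column: str = "scale_px",
) -> Path:
    """Median Fa per group (left axis) and raw p-values (right axis, log)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, df in medians.groupby("group"):
        ax.plot(df[scale_column], df["median_fa"], marker="o", ms=3, label=str(label))
    ax.set_xscale("log")
    ax.set_xlabel("wavelet scale (um)" if scale_column == "scale_um" else "wavelet scale (px)")
    ax.set_ylabel("median anisotropy factor Fa")
    ax.legend(loc="best", fontsize=8)
    if ptrack is not None and len(ptrack):
        ax2 = ax.twinx()
        ax2.plot(ptrack[scale_column], ptrack["p_raw"], color="tab:brown", lw=1, label="p")
        ax2.axhline(0.05, color="tab:brown", ls="--", lw=0.8)
        ax2.set_yscale("log")
        ax2.set_ylabel("rank-sum p", color="tab:brown")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_chain_overlay(image_values, mask, path: str | Path) -> Path:
    """Maxima chains of one scale overlaid on the image, for visual QC."""
    import numpy as np

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image_values, cmap="gray", interpolation="nearest")
    rr, cc = np.nonzero(mask)
    ax.scatter(cc, rr, s=0.3, c="lime", marker=".")
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
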