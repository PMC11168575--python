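"""Optional scan plots: window Delta-index with simulated threshold lines."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_scan(windows: pd.DataFrame, out_path: str | Path, stat: str = "mean_delta") -> None:
    """One panel per chromosome: windowed statistic with 95%/99% bounds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c, g in windows.groupby("chromosome", sort=False)]
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 1.6 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        grp = windows[(windows["chromosome"] == chrom) & (windows["n_sites"] > 0)]
        x = grp["midpoint"] / 1e6
        ax.plot(x, grp[stat], color="black", lw=0.8)
        if stat == "mean_delta" and "ci95_high" in grp:
            ax.plot(x, grp["ci95_high"], color="tab:blue", lw=0.6)
            ax.plot(x, grp["ci95_low"], color="tab:blue", lw=0.6)
            ax.plot(x, grp["ci99_high"], color="tab:purple", lw=0.6)
            ax.plot(x, grp["ci99_low"], color="tab:purple", lw=0.6)
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle(stat)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
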