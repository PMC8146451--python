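"""Plots of SNP-index tracks, ΔSNP-index and null confidence bands."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_bsa_panels(
    mut_windows: pd.DataFrame,
    normal_windows: pd.DataFrame,
    delta_windows: pd.DataFrame,
    bands: pd.DataFrame | None = None,
    chrom: str | None = None,
    out: str | Path | None = None,
):
    """Three stacked panels per the classic bulked-segregant layout:
    mutant-bulk SNP-index, normal-bulk SNP-index, and ΔSNP-index with the
    null confidence bands (0.05 green, 0.01 yellow)."""

    def sel(df):
        return df[df["chrom"] == chrom] if chrom else df

    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    for ax, (df, col, title) in zip(
        axes,
        [
            (sel(mut_windows), "snp_index", "mutant bulk SNP-index"),
            (sel(normal_windows), "snp_index", "normal bulk SNP-index"),
            (sel(delta_windows), "delta", "ΔSNP-index"),
        ],
    ):
        ax.plot(df["mid"] / 1e6, df[col], color="tab:red", lw=1.2)
        ax.set_ylabel(col)
        ax.set_title(title, fontsize=9)
    if bands is not None:
        b = sel(bands)
        x = b["mid"] / 1e6
        if "upper_0.05" in b:
            axes[2].fill_between(
                x, b["lower_0.05"], b["upper_0.05"], color="green", alpha=0.25,
                label="null 0.05",
            )
        if "upper_0.01" in b:
            axes[2].fill_between(
                x, b["lower_0.01"], b["upper_0.01"], color="yellow", alpha=0.25,
                label="null 0.01",
            )
        axes[2].legend(loc="upper left", fontsize=8)
    axes[2].set_xlabel("position (Mb)")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
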