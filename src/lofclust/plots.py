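"""Basic per-gene density and rug plots of variant positions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .transcripts import TranscriptModel


def gene_profile_plot(
    variants: pd.DataFrame,
    model: TranscriptModel,
    alt_start_codons: list[int] | None = None,
    out_path: str | Path | None = None,
):
    """Density + rug plot of relative variant positions for one transcript.

    One rug track per consequence class and dataset; optional markers for
    in-frame ATG codons and a bar over the final exon.
    """
    L = model.cds_length
    df = variants[variants["transcript_id"] == model.transcript_id]
    groups = list(df.groupby(["consequence_class", "dataset"], observed=True))
    n_tracks = max(len(groups), 1)
    fig, axes = plt.subplots(
        n_tracks + 1,
        1,
        figsize=(7, 1.6 + 0.5 * n_tracks),
        sharex=True,
        gridspec_kw={"height_ratios": [3] + [1] * n_tracks},
    )
    axes = np.atleast_1d(axes)
    top = axes[0]
    for (cls, ds), grp in groups:
        rel = (grp["cds_pos"].to_numpy(float) - 1) / L
        if len(rel) >= 2 and np.ptp(rel) > 0:
            from scipy.stats import gaussian_kde

            grid = np.linspace(0, 1, 200)
            top.plot(grid, gaussian_kde(rel)(grid), label=f"{cls} ({ds})")
    top.set_ylabel("density")
    top.set_title(f"{model.gene_id} / {model.transcript_id}")
    if groups:
        top.legend(fontsize=6)
    for ax, ((cls, ds), grp) in zip(axes[1:], groups):
        rel = (grp["cds_pos"].to_numpy(float) - 1) / L
        ax.vlines(rel, 0, 1, lw=0.5)
        ax.set_yticks([])
        ax.set_ylabel(f"{cls[:3]}/{ds[:3]}", rotation=0, ha="right", fontsize=6)
    bottom = axes[-1]
    if alt_start_codons:
        xs = [(3 * (c - 1)) / L for c in alt_start_codons]
        bottom.plot(xs, [0.5] * len(xs), "v", color="green", ms=4)
    final_start = (model.final_exon_cds_start() - 1) / L
    bottom.axvspan(final_start, 1.0, color="0.2", alpha=0.15)
    bottom.set_xlim(0, 1)
    bottom.set_xlabel("relative CDS position")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=100)
        plt.close(fig)
    return fig
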