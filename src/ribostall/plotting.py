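"""Minimal figures: metagene profiles and occupancy ratio scatters."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metagene import MetageneProfile, PeakCall


def plot_metagene(profile: MetageneProfile, peaks: list[PeakCall] | None = None, ax=None):
    """Mean normalized density vs codon offset, with called peaks marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.positions, profile.density, lw=1.2, color="0.2")
    ax.axhline(1.0, ls=":", color="0.6")
    if peaks:
        for p in peaks:
            if p.passes_threshold:
                ax.axvline(p.position, ls="--", color="firebrick", alpha=0.6)
    ax.set_xlabel("codon offset from %s A-site" % profile.target_codon)
    ax.set_ylabel("mean normalized RPF density")
    ax.set_title(f"{profile.target_codon} metagene (n={profile.n_occurrences})")
    return ax


def plot_occupancy_comparison(ratio: pd.DataFrame, highlight: str = "TGG", ax=None):
    """Rank-ordered log2 occupancy ratios with one codon highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = ratio.dropna(subset=["log2_ratio"]).sort_values("log2_ratio")
    x = np.arange(len(df))
    ax.scatter(x, df["log2_ratio"], s=12, color="0.4")
    hl = df["codon"] == highlight
    if hl.any():
        ax.scatter(x[hl.to_numpy()], df.loc[hl, "log2_ratio"], s=30, color="firebrick",
                   label=highlight)
        ax.legend()
    ax.axhline(0.0, ls=":", color="0.6")
    ax.set_xlabel("codon rank")
    ax.set_ylabel("log2 occupancy ratio (stress / control)")
    return ax
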