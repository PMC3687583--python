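"""Plot variant-frequency tracks with smoothing and called regions."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .poolseq import VariantFrequencyTrack
from .qtl_map import QtlRegion, SmoothedTrack


def plot_variant_track(track: VariantFrequencyTrack, smoothed: SmoothedTrack | None = None,
                       regions: Sequence[QtlRegion] = (), path: str | None = None):
    """One panel per chromosome: raw variant frequency (grey), smoothed
    frequency with its 95 % band, the neutral 0.5 line, and called regions
    shaded (superior linkage above 0.5 in red, inferior in blue)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = np.unique(track.chrom)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.6 * len(chroms)),
                             sharey=True, squeeze=False)
    for ax, c in zip(axes[:, 0], chroms):
        sel = track.chrom == c
        ax.plot(track.pos[sel], track.freq[sel], ".", ms=2, color="0.7", label="raw")
        if smoothed is not None:
            ss = smoothed.chrom == c
            ax.plot(smoothed.pos[ss], smoothed.smoothed[ss], color="crimson", lw=1.2,
                    label="smoothed")
            ax.fill_between(smoothed.pos[ss], smoothed.lower[ss], smoothed.upper[ss],
                            color="crimson", alpha=0.2, lw=0)
        for r in regions:
            if r.chrom == c:
                color = "red" if r.direction == "superior" else "blue"
                ax.axvspan(r.start, r.end, color=color, alpha=0.25)
        ax.axhline(0.5, color="k", lw=0.6, ls="--")
        ax.set_ylim(0, 1)
        ax.set_ylabel(f"chr {c}", rotation=0, ha="right", va="center", fontsize=8)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.suptitle("superior-parent variant frequency")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
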