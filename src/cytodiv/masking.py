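"""Project bin clusters to a 2-D mask and overlay it on cytograms.

The bin clusters live in the full n-channel bin space; for display they
are projected onto one channel pair as a single masking image (an
nbins x nbins grid of cluster labels) that is identical for every
sample.  When more than two channels were binned, several n-D bins
project onto each 2-D cell; the cell takes the label of the cluster
holding the largest total corrected count there (count-weighted
majority).  Cells with zero total count are left unlabeled (0).

Overlays render each sample's 2-D event density in grayscale with the
mask's cluster colors alpha-blended on top; the label grid is also
written as CSV so tests can assert on it without decoding pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap, to_rgba

from .errors import ConfigError
from .binning import CountMatrix
from .fcs import EventTable

__all__ = ["MaskGrid", "build_mask", "overlay"]

_DEFAULT_PALETTE = plt.get_cmap("tab10").colors


@dataclass
class MaskGrid:
    channel_pair: tuple[str, str]
    labels: np.ndarray  # nbins x nbins ints; 0 = empty, 1..K = cluster ids
    breakpoints: tuple[np.ndarray, np.ndarray]
    palette: dict[int, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.palette:
            ids = sorted(set(self.labels.ravel()) - {0})
            self.palette = {
                cid: to_rgba(_DEFAULT_PALETTE[(cid - 1) % len(_DEFAULT_PALETTE)])
                for cid in ids
            }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels)


def build_mask(
    cluster_labels: np.ndarray,
    counts: CountMatrix,
    channel_pair: tuple[str, str],
) -> MaskGrid:
    """Count-weighted majority projection of bin clusters onto a channel pair.

    ``cluster_labels`` holds one 0-based cluster id per bin row of
    ``counts`` (NaN for unplaced all-zero bins, which carry no weight
    anyway).  With exactly two binned channels this reduces to the
    direct bin -> cell map.
    """
    for ch in channel_pair:
        if ch not in counts.channels:
            raise ConfigError(
                f"channel {ch!r} was not binned; binned channels: {counts.channels}"
            )
    ci = counts.channels.index(channel_pair[0])
    cj = counts.channels.index(channel_pair[1])
    nbins = counts.nbins
    K = int(np.nanmax(cluster_labels)) + 1 if len(cluster_labels) else 0
    weight = np.zeros((nbins, nbins, K))
    totals = counts.F.sum(axis=1)
    for row, (idx, w) in enumerate(zip(counts.bin_index, totals)):
        lab = cluster_labels[row]
        if w <= 0 or not np.isfinite(lab):
            continue
        weight[idx[ci], idx[cj], int(lab)] += w
    labels = np.where(
        weight.sum(axis=2) > 0, np.argmax(weight, axis=2) + 1, 0
    ).astype(int)
    return MaskGrid(
        channel_pair=tuple(channel_pair),
        labels=labels,
        breakpoints=(counts.breakpoints[ci], counts.breakpoints[cj]),
    )


def overlay(
    table: EventTable,
    mask: MaskGrid,
    out_path: str | Path,
    alpha: float = 0.35,
) -> Path:
    """Write a PNG of the sample's 2-D density with the mask blended on top.

    The density is the per-cell event count on the mask's own grid
    (log-shaded grayscale); mask colors are alpha-blended per cell and a
    legend maps colors to cluster ids.  Deterministic given inputs.
    """
    out_path = Path(out_path)
    x = table.channel(mask.channel_pair[0])
    y = table.channel(mask.channel_pair[1])
    bx, by = mask.breakpoints
    density, _, _ = np.histogram2d(x, y, bins=[bx, by])

    fig, ax = plt.subplots(figsize=(6, 5))
    extent = (bx[0], bx[-1], by[0], by[-1])
    # transpose: histogram rows are x-bins, imshow rows are y
    ax.imshow(
        np.log1p(density).T, origin="lower", extent=extent, cmap="Greys",
        aspect="auto", interpolation="nearest",
    )
    ids = sorted(mask.palette)
    if ids:
        lut = [(0, 0, 0, 0)] + [
            (*mask.palette[cid][:3], alpha) for cid in ids
        ]
        remap = np.zeros(max(ids) + 1, dtype=int)
        for pos, cid in enumerate(ids, start=1):
            remap[cid] = pos
        shown = np.where(mask.labels > 0, remap[mask.labels], 0)
        ax.imshow(
            shown.T, origin="lower", extent=extent,
            cmap=ListedColormap(lut), vmin=0, vmax=len(ids),
            aspect="auto", interpolation="nearest",
        )
        handles = [
            plt.Rectangle((0, 0), 1, 1, color=mask.palette[cid]) for cid in ids
        ]
        ax.legend(handles, [f"cluster {cid}" for cid in ids],
                  loc="upper right", fontsize=8)
    ax.set_xlabel(mask.channel_pair[0])
    ax.set_ylabel(mask.channel_pair[1])
    ax.set_title(table.sample_id)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
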