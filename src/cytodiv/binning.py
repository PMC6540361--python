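"""Channel ranges, Freedman-Diaconis bin counts, n-D contingency tables,
vectorization and volume correction.

Every selected channel is cut into the same number of equal-width bins
over either dynamic ranges (pooled min/max of the post-normalization
values) or user-fixed limits.  Events are cross-tabulated into an
n-dimensional contingency table (one axis per channel); tables are
vectorized in row-major order into the columns of a bins x samples count
matrix W, which is volume-corrected to F = W · D_cf with
d_j = min(volume) / volume_j.  The minimum is used so counts are scaled
down, never inflated (down-weighting background accumulated in long
runs).  Empty bins are retained so all samples share one bin universe.

Conventions (documented because oracles depend on them):

* the interquartile range uses linear-interpolation ("type 7") quantiles;
* bins are half-open ``[edge_k, edge_{k+1})`` with the last bin closed;
* the mean bin suggestion is rounded half *up*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
import warnings

import numpy as np

from .errors import ConfigError, NumericError
from .fcs import EventTable

__all__ = [
    "ChannelRanges",
    "BinGrid",
    "CountMatrix",
    "compute_ranges",
    "fd_bins",
    "optimal_bins",
    "build_contingency",
    "vectorize",
    "unvectorize",
    "volume_correct",
    "build_count_matrix",
]


@dataclass
class ChannelRanges:
    mode: str  # "dynamic" | "fixed"
    limits: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for ch, (lo, hi) in self.limits.items():
            if not lo < hi:
                raise ConfigError(f"channel {ch!r}: range low ({lo}) must be < high ({hi})")


@dataclass
class BinGrid:
    """Per-sample n-D contingency table over a common breakpoint grid."""

    sample_id: str
    channels: list[str]
    nbins: int
    breakpoints: list[np.ndarray]  # per channel, nbins+1 strictly increasing
    counts: np.ndarray  # n-D, shape (nbins,) * n_channels
    out_of_range: int


@dataclass
class CountMatrix:
    """Bins x samples matrices: raw (W) and volume-corrected (F).

    ``bin_index`` lists one n-tuple of channel-bin coordinates per row,
    in row-major order over the channels in their configured order — the
    documented vectorization order.
    """

    samples: list[str]
    channels: list[str]
    breakpoints: list[np.ndarray]
    bin_index: list[tuple[int, ...]]
    W: np.ndarray
    F: np.ndarray
    volumes: np.ndarray
    d: np.ndarray

    @property
    def nbins(self) -> int:
        return len(self.breakpoints[0]) - 1

    def midpoints(self) -> np.ndarray:
        """Bin-center coordinates, one row per bin (for counts.csv)."""
        mids = [(b[:-1] + b[1:]) / 2 for b in self.breakpoints]
        idx = np.array(self.bin_index)
        return np.column_stack([mids[k][idx[:, k]] for k in range(len(mids))])


def compute_ranges(
    tables: list[EventTable],
    channels: list[str],
    mode: str = "dynamic",
    fixed_limits: dict[str, tuple[float, float]] | None = None,
) -> ChannelRanges:
    """Per-channel binning limits: pooled min/max (dynamic) or user-fixed."""
    if mode == "fixed":
        if not fixed_limits or any(ch not in fixed_limits for ch in channels):
            raise ConfigError("fixed ranges require limits for every channel")
        return ChannelRanges(
            mode="fixed",
            limits={ch: (float(fixed_limits[ch][0]), float(fixed_limits[ch][1]))
                    for ch in channels},
        )
    if mode != "dynamic":
        raise ConfigError(f"unknown range mode {mode!r}")
    if not tables or all(t.n_events == 0 for t in tables):
        raise NumericError("dynamic ranges require at least one event")
    limits = {}
    for ch in channels:
        pooled = np.concatenate([t.channel(ch) for t in tables if t.n_events])
        lo, hi = float(pooled.min()), float(pooled.max())
        if lo == hi:
            raise NumericError(
                f"channel {ch!r} is constant ({lo}); dynamic range is "
                "degenerate — supply fixed limits"
            )
        limits[ch] = (lo, hi)
    return ChannelRanges(mode="dynamic", limits=limits)


def fd_bins(values: np.ndarray) -> int:
    """Freedman-Diaconis bin count: ceil(range / (2 · IQR · n^(-1/3))).

    The IQR uses linear-interpolation quantiles.  Raises
    :class:`NumericError` when the IQR is zero (bin width undefined);
    supply ``nbins`` manually in that case.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise NumericError("fd_bins needs at least 2 values")
    q25, q75 = np.quantile(v, [0.25, 0.75])  # linear interpolation (type 7)
    iqr = q75 - q25
    if iqr <= 0:
        raise NumericError(
            "IQR is zero: Freedman-Diaconis width undefined; supply nbins manually"
        )
    width = 2.0 * iqr * v.size ** (-1.0 / 3.0)
    return int(math.ceil((v.max() - v.min()) / width))


def optimal_bins(tables: list[EventTable], channels: list[str]) -> int:
    """Round-half-up mean of fd_bins over every (channel, sample) pair.

    Degenerate pairs (zero IQR) are excluded with a warning; if every
    pair is degenerate the data cannot suggest a bin count.
    """
    suggestions = []
    for t in tables:
        for ch in channels:
            try:
                suggestions.append(fd_bins(t.channel(ch)))
            except NumericError:
                warnings.warn(
                    f"sample {t.sample_id!r}, channel {ch!r}: degenerate "
                    "IQR, excluded from the bin-count mean",
                    stacklevel=2,
                )
    if not suggestions:
        raise NumericError("every (channel, sample) pair is degenerate; supply nbins")
    mean = sum(suggestions) / len(suggestions)
    return int(math.floor(mean + 0.5))  # round half up


def _edges(ranges: ChannelRanges, channels: list[str], nbins: int) -> list[np.ndarray]:
    return [np.linspace(*ranges.limits[ch], nbins + 1) for ch in channels]


def build_contingency(
    table: EventTable, ranges: ChannelRanges, nbins: int, channels: list[str] | None = None
) -> BinGrid:
    """Cross-tabulate one sample's events into an n-D contingency table.

    Bins are equal-width and half-open, the last bin closed at the channel
    maximum (numpy's histogram convention), so in-range events map to
    exactly one cell.  Out-of-range events are dropped and tallied.
    """
    if nbins < 1:
        raise ConfigError("nbins must be >= 1")
    channels = channels or list(ranges.limits)
    edges = _edges(ranges, channels, nbins)
    cols = np.column_stack([table.channel(ch) for ch in channels])
    counts, _ = np.histogramdd(cols, bins=edges)
    counts = counts.astype(np.int64)
    return BinGrid(
        sample_id=table.sample_id,
        channels=list(channels),
        nbins=nbins,
        breakpoints=edges,
        counts=counts,
        out_of_range=int(table.n_events - counts.sum()),
    )


def vectorize(grid: BinGrid) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Flatten the n-D table to a vector (row-major over the channel order),
    with the one-to-one list of bin coordinate tuples."""
    vec = grid.counts.ravel(order="C")
    index = list(product(*(range(grid.nbins) for _ in grid.channels)))
    return vec, index


def unvectorize(vec: np.ndarray, nbins: int, n_channels: int) -> np.ndarray:
    """Inverse of :func:`vectorize`."""
    return np.asarray(vec).reshape((nbins,) * n_channels, order="C")


def volume_correct(W: np.ndarray, volumes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F column j = W column j · min(volumes)/volume_j.

    Returns (F, d).  Every d_j lies in (0, 1] and at least one equals 1;
    within-sample relative abundances are unchanged.
    """
    volumes = np.asarray(volumes, dtype=float)
    if (volumes <= 0).any():
        raise ConfigError("volumes must all be positive")
    d = volumes.min() / volumes
    return W * d[None, :], d


def build_count_matrix(
    grids: list[BinGrid], volumes: list[float]
) -> CountMatrix:
    """Assemble per-sample contingency tables into W and F matrices.

    All grids must share breakpoints (same ranges and nbins).  Empty bins
    are kept so the bin universe is common to all samples.
    """
    ref = grids[0]
    for g in grids[1:]:
        if g.nbins != ref.nbins or g.channels != ref.channels:
            raise ConfigError("all samples must be binned on the same grid")
    vecs, index = [], None
    for g in grids:
        v, index = vectorize(g)
        vecs.append(v)
    W = np.column_stack(vecs).astype(float)
    F, d = volume_correct(W, np.asarray(volumes, dtype=float))
    return CountMatrix(
        samples=[g.sample_id for g in grids],
        channels=list(ref.channels),
        breakpoints=ref.breakpoints,
        bin_index=index,
        W=W,
        F=F,
        volumes=np.asarray(volumes, dtype=float),
        d=d,
    )
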