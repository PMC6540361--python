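"""Bead-anchored alignment and asinh variance stabilization.

Differently acquired cytograms are brought to a common perspective by a
pure translation: for each channel i and sample j the shift is

    shift[i, j] = grand_mean[i] - bead_mean[i, j]

where ``bead_mean[i, j]`` is the arithmetic mean of the internal-standard
bead events of sample j on channel i, and ``grand_mean[i]`` is the mean
of those per-sample bead means over all n samples.  Adding the shift to
every event of sample j makes the per-sample bead means exactly equal
across samples, channel by channel — the module's correctness oracle.

Variance stabilization then applies ``asinh(v / c_i)`` per channel with a
cofactor ``c_i`` chosen to homogenize the variances of the channel's
1-D modes (grid search minimizing Bartlett's statistic over KDE-detected
modes, a simplification of the flowVS approach).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import ConfigError, NumericError
from .fcs import EventTable

__all__ = [
    "ShiftTable",
    "CofactorTable",
    "compute_bead_shifts",
    "translate_events",
    "estimate_asinh_cofactors",
    "asinh_transform",
]


@dataclass
class ShiftTable:
    """Per-channel, per-sample bead means and the translation shifts."""

    channels: list[str]
    samples: list[str]
    bead_means: np.ndarray  # channels x samples
    grand_means: np.ndarray  # channels
    shifts: np.ndarray  # channels x samples

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def shifts_for(self, sample_id: str) -> dict[str, float]:
        j = self.samples.index(sample_id)
        return {ch: float(self.shifts[i, j]) for i, ch in enumerate(self.channels)}


@dataclass
class CofactorTable:
    """Per-channel asinh cofactors and how they were obtained."""

    cofactors: dict[str, float]
    method: str  # "user" or "bartlett-grid"

    def __post_init__(self) -> None:
        for ch, c in self.cofactors.items():
            if not c > 0:
                raise ConfigError(f"cofactor for channel {ch!r} must be positive")


def compute_bead_shifts(
    bead_tables: list[EventTable], channels: list[str]
) -> ShiftTable:
    """Shifts aligning every sample's bead means to the grand mean.

    ``bead_tables`` are the event tables restricted to the bead gate, one
    per sample.  Every table must contain bead events: the translation is
    undefined without an internal standard.
    """
    for t in bead_tables:
        if t.n_events == 0:
            raise NumericError(
                f"sample {t.sample_id!r}: empty bead gate — beads are "
                "required for normalization"
            )
    samples = [t.sample_id for t in bead_tables]
    bead_means = np.array(
        [[t.channel(ch).mean() for t in bead_tables] for ch in channels]
    )
    grand = bead_means.mean(axis=1)
    shifts = grand[:, None] - bead_means
    return ShiftTable(
        channels=list(channels),
        samples=samples,
        bead_means=bead_means,
        grand_means=grand,
        shifts=shifts,
    )


def translate_events(
    table: EventTable, shifts_for_sample: dict[str, float]
) -> EventTable:
    """Add the per-channel shift to every event value; count unchanged."""
    events = table.events.copy()
    for ch, delta in shifts_for_sample.items():
        idx = table.channel_names.index(ch) if ch in table.channel_names else None
        if idx is None:
            raise ConfigError(
                f"sample {table.sample_id!r}: shift given for unknown channel {ch!r}"
            )
        events[:, idx] += delta
    return table.with_events(events)


# ---------------------------------------------------------------------------
# asinh cofactors
# ---------------------------------------------------------------------------

def _default_grid() -> list[float]:
    return [10.0 ** e for e in range(-1, 6)]


def _bartlett_score(pooled: np.ndarray, cofactor: float) -> float | None:
    """Bartlett statistic over KDE-detected modes of asinh(x/c).

    Returns None when fewer than two usable modes are found (the
    candidate carries no variance-homogeneity information).
    """
    z = np.arcsinh(pooled / cofactor)
    if np.ptp(z) == 0:
        return None
    kde = stats.gaussian_kde(z, bw_method="silverman")
    grid = np.linspace(z.min(), z.max(), 512)
    dens = kde(grid)
    # prominence floor keeps noise wiggles of a unimodal density from
    # being mistaken for modes
    peaks, _ = signal.find_peaks(dens, prominence=0.05 * dens.max())
    if len(peaks) < 2:
        return None
    modes = grid[peaks]
    assign = np.argmin(np.abs(z[:, None] - modes[None, :]), axis=1)
    groups = [z[assign == k] for k in range(len(modes))]
    groups = [g for g in groups if len(g) >= 2 and np.var(g) > 0]
    if len(groups) < 2:
        return None
    stat, _ = stats.bartlett(*groups)
    return float(stat)


def estimate_asinh_cofactors(
    tables: list[EventTable],
    channels: list[str],
    candidate_grid: list[float] | None = None,
    user_cofactors: dict[str, float] | None = None,
    refine: bool = True,
) -> CofactorTable:
    """Per-channel cofactor minimizing Bartlett's statistic over 1-D modes.

    The channel is pooled over all samples, asinh-transformed at each
    candidate cofactor, its modes detected by Gaussian-KDE peak finding
    (Silverman bandwidth), events assigned to the nearest mode, and
    Bartlett's test statistic computed over the groups; the candidate
    with the smallest statistic wins.  The default grid spans powers of
    ten from 1e-1 to 1e5 and is refined once geometrically around the
    winner.  Deterministic given the grid.

    If every candidate yields fewer than two modes on a channel, the
    user-supplied cofactor for that channel is used; without one, a
    :class:`NumericError` instructs the user to supply it.
    """
    if user_cofactors and all(ch in user_cofactors for ch in channels):
        return CofactorTable(
            cofactors={ch: float(user_cofactors[ch]) for ch in channels},
            method="user",
        )
    grid = sorted(candidate_grid) if candidate_grid else _default_grid()
    if not grid:
        raise ConfigError("candidate grid must be non-empty")

    chosen: dict[str, float] = {}
    for ch in channels:
        pooled = np.concatenate([t.channel(ch) for t in tables])
        scores = {c: _bartlett_score(pooled, c) for c in grid}
        valid = {c: s for c, s in scores.items() if s is not None}
        if not valid:
            if user_cofactors and ch in user_cofactors:
                chosen[ch] = float(user_cofactors[ch])
                continue
            raise NumericError(
                f"channel {ch!r}: fewer than 2 modes detected at every "
                "candidate cofactor; supply a cofactor for this channel "
                "explicitly"
            )
        best = min(valid, key=lambda c: (valid[c], c))
        if refine:
            ref = [best * 10.0 ** e for e in (-0.5, -0.25, 0.25, 0.5)]
            for c in ref:
                s = _bartlett_score(pooled, c)
                if s is not None and s < valid[best]:
                    valid[c] = s
            best = min(valid, key=lambda c: (valid[c], c))
        chosen[ch] = float(best)
    return CofactorTable(cofactors=chosen, method="bartlett-grid")


def asinh_transform(table: EventTable, cofactors: CofactorTable) -> EventTable:
    """Replace each value v on channel i by asinh(v / c_i).

    Monotone on each channel and defined for negative values, so event
    ordering within a channel is preserved.
    """
    events = table.events.copy()
    for ch, c in cofactors.cofactors.items():
        if ch not in table.channel_names:
            continue
        idx = table.channel_names.index(ch)
        events[:, idx] = np.arcsinh(events[:, idx] / c)
    return table.with_events(events)
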