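"""Alpha and beta diversity of binned cytograms.

Bins play the role of non-taxonomic "species": a sample's column of the
volume-corrected count matrix F is its community profile.  Alpha indices
(richness, Shannon in nats, Simpson, inverse Simpson, Pielou's evenness)
are computed per column; beta diversity comes either from abundances
(Bray-Curtis, with Baselga's partition into balanced variation /
turnover and abundance gradients / nestedness) or from incidences (the
24 pairwise measures reviewed by Koleff, computed from the matching
components a, b, c).

Bray-Curtis partition, with A = sum(min(x, y)), B = sum(x - min),
C = sum(y - min):

    bray     = (B + C) / (2A + B + C)
    balanced = min(B, C) / (A + min(B, C))   (turnover component)
    gradient = bray - balanced               (nestedness component)

Community-matrix standardizations mirror the conventions of vegan's
``decostand``: total / hellinger / pa / log act per sample (column);
max / range / standardize act per bin (row).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, NumericError

__all__ = [
    "AlphaTable",
    "DistanceMatrix",
    "BrayPartition",
    "alpha_indices",
    "alpha_table",
    "bray_curtis",
    "bray_partition",
    "koleff_index",
    "KOLEFF_IDS",
    "matching_components",
    "distance_matrix",
    "transform_counts",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

@dataclass
class AlphaTable:
    """Per-sample alpha indices (a thin frame wrapper with fixed columns)."""

    frame: pd.DataFrame  # index: sample ids; columns: the five indices

    def __getitem__(self, column: str) -> pd.Series:
        return self.frame[column]


def alpha_indices(column: np.ndarray, sample_id: str = "?") -> dict[str, float]:
    """Richness, Shannon (nats), Simpson, inverse Simpson, Pielou.

    With p_i = x_i / sum(x) over positive bins: shannon = -sum p ln p,
    simpson = 1 - sum p^2, inv_simpson = 1 / sum p^2, richness = #{x>0},
    pielou = shannon / ln(richness) (NaN when richness <= 1, since the
    evenness of a single bin is undefined).
    """
    x = np.asarray(column, dtype=float)
    if (x < 0).any():
        raise ConfigError("abundances must be non-negative")
    pos = x[x > 0]
    if pos.size == 0:
        raise NumericError(f"sample {sample_id!r}: all-zero abundance column")
    p = pos / pos.sum()
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p**2).sum())
    richness = int(pos.size)
    if richness > 1:
        pielou = shannon / math.log(richness)
    else:
        pielou = float("nan")
    return {
        "richness": richness,
        "shannon": shannon,
        "simpson": 1.0 - sum_p2,
        "inv_simpson": 1.0 / sum_p2,
        "pielou": pielou,
    }


def alpha_table(F: np.ndarray, samples: list[str]) -> AlphaTable:
    """Alpha indices for every column of a bins x samples matrix."""
    rows = [alpha_indices(F[:, j], samples[j]) for j in range(F.shape[1])]
    return AlphaTable(frame=pd.DataFrame(rows, index=list(samples)))


# ---------------------------------------------------------------------------
# Abundance-based beta diversity
# ---------------------------------------------------------------------------

@dataclass
class BrayPartition:
    bray: float
    balanced: float  # turnover component
    gradient: float  # nestedness component


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError(f"vector length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ConfigError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise NumericError("both vectors are all-zero")
    return x, y


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def bray_partition(x: np.ndarray, y: np.ndarray) -> BrayPartition:
    """Partition Bray-Curtis into balanced-variation and gradient parts.

    The balanced component captures bin-for-bin substitution (turnover);
    the gradient component captures one profile being a scaled-down
    subset of the other (nestedness).  The identity
    ``balanced + gradient = bray`` holds exactly.
    """
    x, y = _check_pair(x, y)
    m = np.minimum(x, y)
    A = float(m.sum())
    B = float((x - m).sum())
    C = float((y - m).sum())
    bray = (B + C) / (2 * A + B + C)
    denom = A + min(B, C)
    balanced = (min(B, C) / denom) if denom > 0 else 0.0
    return BrayPartition(bray=bray, balanced=balanced, gradient=bray - balanced)


# ---------------------------------------------------------------------------
# Incidence-based (Koleff) beta diversity
# ---------------------------------------------------------------------------

def matching_components(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """(a, b, c): bins shared, only in x, only in y — presences are x > 0."""
    px = np.asarray(x) > 0
    py = np.asarray(y) > 0
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))
    c = int(np.sum(~px & py))
    return a, b, c


# Pairwise forms of the 24 incidence measures tabulated by Koleff et al.,
# keyed by the ids used in vegan::betadiver.  Several ids share one
# pairwise formula (their multi-site forms differ).
def _beta_I(a, b, c):
    t = 2 * a + b + c
    return (
        math.log(t)
        - 2 * a * math.log(2) / t
        - ((a + b) * math.log(a + b) + (a + c) * math.log(a + c)) / t
    )


KOLEFF_FORMULAS = {
    "w": lambda a, b, c: (b + c) / (2 * a + b + c),
    "-1": lambda a, b, c: (b + c) / (2 * a + b + c),
    "c": lambda a, b, c: (b + c) / 2,
    "wb": lambda a, b, c: b + c,
    "r": lambda a, b, c: 2 * b * c / ((a + b + c) ** 2 - 2 * b * c),
    "I": _beta_I,
    "e": lambda a, b, c: math.exp(_beta_I(a, b, c)) - 1,
    "t": lambda a, b, c: (b + c) / (2 * a + b + c),
    "me": lambda a, b, c: (b + c) / (2 * a + b + c),
    "j": lambda a, b, c: a / (a + b + c),
    "sor": lambda a, b, c: 2 * a / (2 * a + b + c),
    "m": lambda a, b, c: (2 * a + b + c) * (b + c) / (a + b + c),
    "-2": lambda a, b, c: min(b, c) / (max(b, c) + a),
    "co": lambda a, b, c: (a * c + a * b + 2 * b * c) / (2 * (a + b) * (a + c)),
    "cc": lambda a, b, c: (b + c) / (a + b + c),
    "g": lambda a, b, c: (b + c) / (a + b + c),
    "-3": lambda a, b, c: min(b, c) / (a + b + c),
    "l": lambda a, b, c: (b + c) / 2,
    "19": lambda a, b, c: 2 * (b * c + 1) / ((a + b + c) * (a + b + c - 1)),
    "hk": lambda a, b, c: (b + c) / (2 * a + b + c),
    "rlb": lambda a, b, c: a / (a + c),
    "sim": lambda a, b, c: min(b, c) / (min(b, c) + a),
    "gl": lambda a, b, c: 2 * abs(b - c) / (2 * a + b + c),
    "z": lambda a, b, c: (math.log(2) - math.log(2 * a + b + c) + math.log(a + b + c))
    / math.log(2),
}

KOLEFF_IDS = tuple(KOLEFF_FORMULAS)


def koleff_index(x: np.ndarray, y: np.ndarray, index_id: str) -> float:
    """One of the 24 pairwise incidence beta measures, from (a, b, c).

    Returns NaN where the published formula is undefined for the given
    matching components (division by zero, log of zero).
    """
    if index_id not in KOLEFF_FORMULAS:
        raise ConfigError(
            f"unknown beta index {index_id!r}; valid ids: {sorted(KOLEFF_FORMULAS)}"
        )
    a, b, c = matching_components(x, y)
    try:
        return float(KOLEFF_FORMULAS[index_id](a, b, c))
    except (ZeroDivisionError, ValueError):
        return float("nan")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(
    F: np.ndarray, samples: list[str], index: str = "bray"
) -> dict[str, DistanceMatrix]:
    """Pairwise beta-diversity over all sample pairs.

    index="bray" returns three matrices — "bray", "balanced", "gradient"
    — satisfying balanced + gradient = bray elementwise.  A Koleff id
    returns a single incidence-based matrix computed on F > 0.
    """
    n = F.shape[1]
    if n < 2:
        raise ConfigError("beta diversity needs at least 2 samples")
    if index == "bray":
        mats = {k: np.zeros((n, n)) for k in ("bray", "balanced", "gradient")}
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    p = bray_partition(F[:, i], F[:, j])
                except NumericError as e:
                    raise NumericError(
                        f"pair ({samples[i]}, {samples[j]}): {e}"
                    ) from e
                for k, v in (("bray", p.bray), ("balanced", p.balanced),
                             ("gradient", p.gradient)):
                    mats[k][i, j] = mats[k][j, i] = v
        return {
            k: DistanceMatrix(labels=list(samples), values=m,
                              index_name="bray" if k == "bray" else f"bray_{k}")
            for k, m in mats.items()
        }
    if index not in KOLEFF_FORMULAS:
        raise ConfigError(
            f"unknown beta index {index!r}; valid: 'bray' or {sorted(KOLEFF_FORMULAS)}"
        )
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = koleff_index(F[:, i], F[:, j], index)
    return {index: DistanceMatrix(labels=list(samples), values=m, index_name=index)}


# ---------------------------------------------------------------------------
# Standardizations
# ---------------------------------------------------------------------------

def transform_counts(F: np.ndarray, method: str) -> np.ndarray:
    """Community-matrix standardization of a bins x samples matrix."""
    F = np.asarray(F, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "total":
            out = F / F.sum(axis=0, keepdims=True)
        elif method == "max":
            out = F / F.max(axis=1, keepdims=True)
        elif method == "pa":
            out = (F > 0).astype(float)
        elif method == "hellinger":
            out = np.sqrt(F / F.sum(axis=0, keepdims=True))
        elif method == "log":
            if (F < 0).any():
                raise ConfigError("log standardization requires non-negative entries")
            out = np.where(F > 0, np.log2(F) + 1.0, 0.0)
        elif method == "range":
            lo = F.min(axis=1, keepdims=True)
            hi = F.max(axis=1, keepdims=True)
            out = (F - lo) / (hi - lo)
        elif method == "standardize":
            mu = F.mean(axis=1, keepdims=True)
            sd = F.std(axis=1, ddof=1, keepdims=True)
            out = (F - mu) / sd
        else:
            raise ConfigError(
                f"unknown standardization {method!r}; valid: total, max, pa, "
                "hellinger, log, range, standardize"
            )
    return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
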