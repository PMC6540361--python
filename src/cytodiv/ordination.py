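"""Non-metric multidimensional scaling, bin scores and bin clustering.

The beta-diversity matrix is embedded in 2-D by nMDS: embedded distances
are required only to be monotone in the input dissimilarities, so any
(semi)metric the diversity module produces can be ordinated.  The
implementation is SMACOF majorization with Kruskal's monotone regression
(pool-adjacent-violators) for the disparities; fit quality is Kruskal
stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

and the best of one metric-scaling (classical MDS) start plus a number
of seeded random restarts is kept, so results are deterministic given
the seed.

Bins are then given biplot scores (abundance-weighted averages of the
sample scores, the weighted-averages convention for species scores) and
clustered by K-means; the number of clusters is chosen by maximizing the
Calinski-Harabasz criterion

    C = ((n - K) / (K - 1)) * (BG_SS / WG_SS)

over K in a pragmatic range (2..10 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .errors import ConfigError, NumericError
from .diversity import DistanceMatrix

__all__ = [
    "OrdinationResult",
    "ClusterModel",
    "KSelection",
    "nmds",
    "bin_scores",
    "kmeans",
    "calinski_harabasz",
    "choose_k",
]


@dataclass
class OrdinationResult:
    sample_labels: list[str]
    sample_scores: np.ndarray  # samples x dims, centered
    stress: float  # Kruskal stress-1
    seed: int
    n_restarts: int
    converged: bool
    bin_scores: np.ndarray | None = None  # bins x dims, NaN rows = all-zero bins


@dataclass
class ClusterModel:
    K: int
    centers: np.ndarray
    assignments: np.ndarray  # 0-based labels, length n
    objective: float  # within-cluster sum of squared distances (J)
    ch_score: float = float("nan")


@dataclass
class KSelection:
    K: int
    table: pd.DataFrame  # columns: K, C
    models: dict[int, ClusterModel] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# nMDS
# ---------------------------------------------------------------------------

def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)[None, :]


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _disparities(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone (isotonic) regression of embedded distances on the
    dissimilarity order — Kruskal's primary approach to ties."""
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    return dhat


def _smacof_once(
    D_cond: np.ndarray, X: np.ndarray, order: np.ndarray,
    max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool]:
    n = X.shape[0]
    n_pairs = len(D_cond)
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(X)
        dhat = _disparities(d, order)
        stress = _stress1(d, dhat)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # scale-normalized disparities guard against configuration collapse
        scale = np.sqrt(n_pairs / max((dhat**2).sum(), 1e-300))
        disp = squareform(dhat * scale)
        dfull = squareform(d)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dfull > 0, disp / dfull, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
    d = pdist(X)
    return X, _stress1(d, _disparities(d, order)), converged


def nmds(
    D: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Embed a dissimilarity matrix by non-metric MDS (best of restarts).

    One start from classical metric scaling plus ``restarts`` random
    starts; the configuration with the lowest Kruskal stress-1 wins.
    Scores are centered.  Deterministic given ``seed``.
    """
    M = np.asarray(D.values, dtype=float)
    n = M.shape[0]
    if n < 3:
        raise ConfigError("nMDS needs at least 3 samples")
    D_cond = squareform(M, checks=False)
    order = np.argsort(D_cond, kind="stable")
    rng = np.random.default_rng(seed)

    inits = [_classical_mds(M, dims)]
    inits += [rng.standard_normal((n, dims)) for _ in range(restarts)]

    best_X, best_stress, best_conv = None, np.inf, False
    for X0 in inits:
        X, stress, conv = _smacof_once(D_cond, X0.copy(), order, max_iter, tol)
        if stress < best_stress:
            best_X, best_stress, best_conv = X, stress, conv
    if not best_conv:
        warnings.warn("nMDS did not converge; returning best configuration found",
                      stacklevel=2)
    best_X = best_X - best_X.mean(axis=0, keepdims=True)
    return OrdinationResult(
        sample_labels=list(D.labels),
        sample_scores=best_X,
        stress=best_stress,
        seed=seed,
        n_restarts=restarts,
        converged=best_conv,
    )


def bin_scores(result: OrdinationResult, F: np.ndarray) -> np.ndarray:
    """Biplot scores for bins: abundance-weighted means of sample scores.

    Row b of F weights the sample scores; all-zero bins get NaN scores
    (no evidence to place them) and are excluded from clustering.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[1] != result.sample_scores.shape[0]:
        raise ConfigError("F columns must match the ordinated samples")
    totals = F.sum(axis=1)
    scores = np.full((F.shape[0], result.sample_scores.shape[1]), np.nan)
    nz = totals > 0
    scores[nz] = (F[nz] @ result.sample_scores) / totals[nz, None]
    if (~nz).any():
        warnings.warn(
            f"{int((~nz).sum())} all-zero bins have undefined scores and are "
            "excluded from clustering",
            stacklevel=2,
        )
    return scores


# ---------------------------------------------------------------------------
# K-means and the Calinski-Harabasz criterion
# ---------------------------------------------------------------------------

def kmeans(points: np.ndarray, K: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """K-means (k-means++ seeding, Lloyd iterations, best of ``n_init``)."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if not 2 <= K <= n:
        raise ConfigError(f"need 2 <= K <= n points, got K={K}, n={n}")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init,
                random_state=seed).fit(pts)
    model = ClusterModel(
        K=K,
        centers=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        objective=float(km.inertia_),
    )
    model.ch_score = calinski_harabasz(pts, model)
    return model


def calinski_harabasz(points: np.ndarray, model: ClusterModel) -> float:
    """C = ((n-K)/(K-1)) · BG_SS/WG_SS over the fitted partition.

    BG_SS = sum_k n_k ||mu_k - mu||^2, WG_SS = sum_k sum_{x in k}
    ||x - mu_k||^2.  When every point sits on its center (WG_SS = 0) the
    criterion diverges; +inf is returned with a warning.
    """
    pts = np.asarray(points, dtype=float)
    labels = model.assignments
    n, K = pts.shape[0], model.K
    if K < 2:
        raise ConfigError("Calinski-Harabasz is undefined for K < 2")
    grand = pts.mean(axis=0)
    bg = wg = 0.0
    for k in range(K):
        members = pts[labels == k]
        if len(members) == 0:
            continue
        mu = members.mean(axis=0)
        bg += len(members) * float(((mu - grand) ** 2).sum())
        wg += float(((members - mu) ** 2).sum())
    if wg == 0:
        warnings.warn("WG_SS = 0: all points coincide with their centers; "
                      "Calinski-Harabasz is infinite", stacklevel=2)
        return float("inf")
    return (n - K) / (K - 1) * bg / wg


def choose_k(
    points: np.ndarray,
    kmin: int = 2,
    kmax: int = 10,
    seed: int = 0,
    n_init: int = 10,
    rule: str = "max",
) -> KSelection:
    """Pick the number of bin clusters by the Calinski-Harabasz criterion.

    Fits K-means for every K in [kmin, kmax] and returns the K that
    maximizes C (ties toward smaller K).  ``rule="min"`` selects the
    minimizing K instead, preserving the literal published suggestion;
    the default maximizes, since C as defined grows with partition
    quality.  The full (K, C) table is returned for logging.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[~np.isnan(pts).any(axis=1)]
    n = pts.shape[0]
    if n < 3:
        raise ConfigError("cluster selection needs at least 3 points")
    if np.allclose(pts, pts[0]):
        raise NumericError("all points identical: no cluster structure to select")
    if n <= kmax:
        warnings.warn(f"only {n} points; lowering kmax to {n - 1}", stacklevel=2)
        kmax = n - 1
    if rule not in ("max", "min"):
        raise ConfigError("ch_rule must be 'max' or 'min'")

    rng = np.random.default_rng(seed)
    rows, models = [], {}
    for K in range(kmin, kmax + 1):
        model = kmeans(pts, K, seed=int(rng.integers(2**31 - 1)), n_init=n_init)
        models[K] = model
        rows.append({"K": K, "C": model.ch_score})
    table = pd.DataFrame(rows)
    cs = table["C"].to_numpy()
    pick = int(np.argmax(cs)) if rule == "max" else int(np.argmin(cs))
    return KSelection(K=int(table["K"][pick]), table=table, models=models)
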