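"""Proteome pseudotime: spectral embedding, principal path, LOESS staging.

Pipeline: top principal components of the (estimated) proteome -> k-nearest
neighbor graph on Euclidean distances -> 2-D spectral embedding from the
normalized graph Laplacian -> a principal path through k-means cluster
centers, iteratively refined toward local means along the path -> pseudotime
as normalized arc-length position of each sample's projection.

Clinical curves and module expression along pseudotime are smoothed with a
degree-2 tricube local polynomial (LOESS); the pseudotime at which a curve
first alters 25% of its overall variation defines its milestone, and module
milestones relative to the amyloid/tau/cognition milestones assign
early/mid/late stages (non-monotone modules are "unspecified").  The LMG
variance decomposition apportions outcome R^2 among predictors by averaging
sequential gains over all predictor orderings.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "TrajectoryResult",
    "StageAssignment",
    "top_pcs",
    "knn_graph",
    "spectral_embedding",
    "fit_trajectory",
    "compute_pseudotime",
    "loess_fit",
    "milestone_pseudotime",
    "classify_stage",
    "relative_importance",
    "pseudotime_robustness",
]


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectoryResult:
    embedding: np.ndarray      # samples x 2
    path: np.ndarray           # ordered polyline vertices in embedding space
    pseudotime: np.ndarray     # per sample, in [0, 1]
    parameters: dict = field(default_factory=dict)


@dataclass
class StageAssignment:
    module_id: str
    crossing_pseudotime: float | None
    stage: str                 # early | mid | late | unspecified
    monotone: bool


def top_pcs(values: np.ndarray, n: int = 40) -> np.ndarray:
    """Centered PCA scores (samples x n), components by decreasing variance.

    ``values`` is samples x features.
    """
    x = np.asarray(values, dtype=float)
    if n < 1:
        raise TrajectoryError("n must be >= 1")
    if n > min(x.shape):
        raise TrajectoryError(f"n={n} exceeds min(#samples, #features)={min(x.shape)}")
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n] * s[:n]
    for j in range(n):  # deterministic sign: largest-magnitude score positive
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def knn_graph(scores: np.ndarray, k: int = 10) -> np.ndarray:
    """Symmetric binary kNN adjacency (union symmetrization, no self-edges).

    Distance ties are broken by sample index.
    """
    x = np.asarray(scores, dtype=float)
    n = x.shape[0]
    if k >= n:
        raise TrajectoryError(f"k={k} must be < n_samples={n}")
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        order = np.lexsort((idx, d[i]))   # distance, then index
        adj[i, order[:k]] = True
    adj = adj | adj.T
    return adj


def spectral_embedding(adjacency: np.ndarray, dim: int = 2
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Laplacian eigenmap coordinates (samples x dim) plus a component mask.

    Uses eigenvectors 2..dim+1 (ascending eigenvalues) of the symmetric
    normalized Laplacian, degree-renormalized; per-axis sign fixed by making
    the largest-magnitude coordinate positive.  If the graph is disconnected
    only the largest component is embedded; other samples get NaN coordinates
    and ``mask`` is False there.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    if n == 0:
        raise TrajectoryError("empty graph")
    n_comp, labels = connected_components(a > 0, directed=False)
    keep = np.ones(n, dtype=bool)
    if n_comp > 1:
        sizes = np.bincount(labels)
        keep = labels == int(np.argmax(sizes))
    sub = a[np.ix_(keep, keep)]
    deg = sub.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)
    dmh = 1.0 / np.sqrt(deg)
    lap = np.eye(sub.shape[0]) - dmh[:, None] * sub * dmh[None, :]
    evals, evecs = np.linalg.eigh(lap)
    coords = evecs[:, 1: dim + 1] * dmh[:, None]
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    out = np.full((n, dim), np.nan)
    out[keep] = coords
    return out, keep


# ---------------------------------------------------------------------------
# principal path
# ---------------------------------------------------------------------------

def _project_to_polyline(points: np.ndarray, path: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length positions and distances of points projected onto a polyline."""
    seg_vec = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_start = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    best_d = np.full(points.shape[0], np.inf)
    best_t = np.zeros(points.shape[0])
    for s in range(len(seg_vec)):
        v = seg_vec[s]
        L2 = float(v @ v)
        if L2 == 0:
            tt = np.zeros(points.shape[0])
        else:
            tt = np.clip((points - path[s]) @ v / L2, 0.0, 1.0)
        proj = path[s][None, :] + tt[:, None] * v[None, :]
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_t[better] = seg_start[s] + tt[better] * seg_len[s]
    return best_t, best_d


def _densify(path: np.ndarray) -> np.ndarray:
    """Insert midpoints between consecutive vertices."""
    mids = 0.5 * (path[:-1] + path[1:])
    out = np.empty((path.shape[0] + mids.shape[0], path.shape[1]))
    out[0::2] = path
    out[1::2] = mids
    return out


def fit_trajectory(embedding: np.ndarray, n_clusters: int = 3,
                   max_iter: int = 100, seed: int = 0,
                   smooth: float = 0.1) -> TrajectoryResult:
    """Principal path through cluster centers, with arc-length pseudotime.

    Seeded k-means partitions the samples; the initial path orders the
    cluster centers to minimize total polyline length, with midpoints added.
    Refinement alternates projecting samples onto the path with moving each
    vertex toward the weighted local mean of nearby samples (tricube weights
    along arc length) under a smoothing pull toward its neighbors, until the
    largest vertex movement drops below 1e-6 or ``max_iter``.  Pseudotime is
    the arc-length position min-max normalized to [0, 1]; orientation is
    arbitrary.
    """
    x = np.asarray(embedding, dtype=float)
    x = x[~np.isnan(x).any(axis=1)] if np.isnan(x).any() else x
    n = x.shape[0]
    if n <= n_clusters:
        raise TrajectoryError("need more samples than clusters")
    if np.allclose(x, x[0]):
        raise TrajectoryError("degenerate embedding: all points identical")

    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    km.fit(x)
    centers = km.cluster_centers_

    best_order, best_len = None, np.inf
    for perm in itertools.permutations(range(n_clusters)):
        if perm[0] > perm[-1]:
            continue  # skip reversals
        length = sum(np.linalg.norm(centers[perm[i + 1]] - centers[perm[i]])
                     for i in range(n_clusters - 1))
        if length < best_len:
            best_len, best_order = length, perm
    path = _densify(centers[list(best_order)])

    scale = np.linalg.norm(x.max(axis=0) - x.min(axis=0))
    tol = 1e-6 * max(scale, 1.0)
    for _ in range(max_iter):
        t, _ = _project_to_polyline(x, path)
        total = t.max() - t.min()
        if total == 0:
            break
        vt, _ = _project_to_polyline(path, path)
        span = 0.35 * max(total, 1e-12)
        new_path = path.copy()
        for vi in range(path.shape[0]):
            w = np.abs(t - vt[vi]) / span
            w = np.where(w < 1, (1 - w ** 3) ** 3, 0.0)
            if w.sum() < 1e-12:
                continue
            local_mean = (w[:, None] * x).sum(axis=0) / w.sum()
            neigh = []
            if vi > 0:
                neigh.append(path[vi - 1])
            if vi < path.shape[0] - 1:
                neigh.append(path[vi + 1])
            pull = np.mean(neigh, axis=0)
            new_path[vi] = (local_mean + smooth * pull) / (1.0 + smooth)
        move = np.max(np.linalg.norm(new_path - path, axis=1))
        path = new_path
        if move < tol:
            break

    # extend the terminal segments so no sample is clamped to an endpoint
    # (clamping ties the extreme samples at pseudotime 0/1)
    for end, other, sign in ((0, 1, -1), (-1, -2, +1)):
        d = path[end] - path[other]
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        overshoot = np.max((x - path[end]) @ d)
        if overshoot > 0:
            path[end] = path[end] + d * overshoot * 1.0001

    t, _ = _project_to_polyline(x, path)
    rng = t.max() - t.min()
    pt = (t - t.min()) / (rng if rng > 0 else 1.0)
    return TrajectoryResult(
        embedding=x, path=path, pseudotime=pt,
        parameters={"n_clusters": n_clusters, "seed": seed, "max_iter": max_iter},
    )


def compute_pseudotime(values: np.ndarray, n_pcs: int = 40, k: int = 10,
                       n_clusters: int = 3, seed: int = 0,
                       anchor: np.ndarray | None = None) -> TrajectoryResult:
    """Full pipeline: samples x features values -> pseudotime.

    If ``anchor`` (a per-sample reference such as global pathology) is given,
    pseudotime is oriented so the anchor increases along it.
    """
    scores = top_pcs(values, n=min(n_pcs, min(values.shape)))
    adj = knn_graph(scores, k=k)
    emb, mask = spectral_embedding(adj, dim=2)
    if not mask.all():
        raise TrajectoryError(
            f"kNN graph disconnected ({int((~mask).sum())} samples outside the "
            "largest component); increase k")
    res = fit_trajectory(emb, n_clusters=n_clusters, seed=seed)
    if anchor is not None:
        r = stats.spearmanr(res.pseudotime, np.asarray(anchor, dtype=float)).statistic
        if np.isfinite(r) and r < 0:
            res.pseudotime = 1.0 - res.pseudotime
            res.path = res.path[::-1].copy()
    return res


# ---------------------------------------------------------------------------
# LOESS, milestones, staging
# ---------------------------------------------------------------------------

def loess_fit(pseudotime: np.ndarray, y: np.ndarray, degree: int = 2,
              span: float = 0.75, grid_size: int = 100
              ) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local polynomial fit on an even pseudotime grid.

    Returns (grid, fitted values).  Each grid point is fitted from the
    ``ceil(span * n)`` nearest observations, which must number at least
    ``degree + 2``.
    """
    x = np.asarray(pseudotime, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(yv)
    x, yv = x[ok], yv[ok]
    n = x.size
    window = int(math.ceil(span * n))
    if window < degree + 2:
        raise TrajectoryError(
            f"span {span} gives window {window} < degree+2={degree + 2}")
    grid = np.linspace(x.min(), x.max(), grid_size)
    fitted = np.empty(grid_size)
    powers = np.arange(degree + 1)
    for gi, g in enumerate(grid):
        d = np.abs(x - g)
        cut = np.partition(d, window - 1)[window - 1]
        sel = d <= cut
        dmax = d[sel].max()
        if dmax == 0:
            fitted[gi] = yv[sel].mean()
            continue
        w = (1.0 - (d[sel] / dmax) ** 3) ** 3
        X = (x[sel, None] - g) ** powers[None, :]
        sw = np.sqrt(np.maximum(w, 0.0))
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yv[sel] * sw, rcond=None)
        fitted[gi] = beta[0]
    return grid, fitted


def milestone_pseudotime(grid: np.ndarray, curve: np.ndarray,
                         threshold: float = 0.25) -> float | None:
    """First grid time where the curve has altered ``threshold`` of its range.

    Overall variation is max - min of the fitted curve; returns None for a
    flat curve.
    """
    curve = np.asarray(curve, dtype=float)
    variation = float(curve.max() - curve.min())
    if variation == 0:
        return None
    crossed = np.abs(curve - curve[0]) >= threshold * variation
    idx = np.flatnonzero(crossed)
    if idx.size == 0:
        return None
    return float(grid[idx[0]])


def _is_monotone(curve: np.ndarray, tol_fraction: float = 0.15) -> bool:
    """Movement-weighted monotonicity: counter-trend movement <= tol of total."""
    d = np.diff(curve)
    up = float(d[d > 0].sum())
    down = float(-d[d < 0].sum())
    total = up + down
    if total == 0:
        return True
    return min(up, down) / total <= tol_fraction


def classify_stage(
    module_curves: Mapping[str, tuple[np.ndarray, np.ndarray]],
    clinical_milestones: Mapping[str, float],
    threshold: float = 0.25,
    monotone_tol: float = 0.15,
    tie_steps: float = 5.0,
) -> list[StageAssignment]:
    """Assign early/mid/late/unspecified stages to module curves.

    ``module_curves`` maps module IDs to (grid, LOESS curve);
    ``clinical_milestones`` must provide increasing amyloid < tau < cognition
    milestone pseudotimes.  A module is *early* if its 25%-variation crossing
    is at or before the amyloid milestone, *mid* if at or before tau, *late*
    if at or before cognition, else unspecified; curves whose counter-trend
    movement exceeds ``monotone_tol`` of their total movement are
    non-monotone and hence unspecified (a sine sits at 0.5).

    A module crossing AT a milestone is a tie, resolved toward the earlier
    stage; because the crossing estimate carries a noise of a few grid steps,
    ties are absorbed with a guard band of ``tie_steps`` grid steps at each
    milestone boundary (narrow relative to the stage windows themselves).
    """
    try:
        m_amyloid = clinical_milestones["amyloid"]
        m_tau = clinical_milestones["tau"]
        m_cog = clinical_milestones["cognition"]
    except KeyError as e:
        raise TrajectoryError(f"missing clinical milestone {e}") from None
    if not (m_amyloid < m_tau < m_cog):
        raise TrajectoryError("clinical milestones must be increasing "
                              "(amyloid < tau < cognition)")
    out = []
    for mod, (grid, curve) in module_curves.items():
        step = float(grid[1] - grid[0]) if len(grid) > 1 else 0.0
        tol = tie_steps * step
        monotone = _is_monotone(curve, monotone_tol)
        crossing = milestone_pseudotime(grid, curve, threshold)
        if not monotone or crossing is None:
            out.append(StageAssignment(mod, crossing, "unspecified", monotone))
            continue
        if crossing <= m_amyloid + tol:
            stage = "early"
        elif crossing <= m_tau + tol:
            stage = "mid"
        elif crossing <= m_cog + tol:
            stage = "late"
        else:
            stage = "unspecified"
        out.append(StageAssignment(mod, crossing, stage, monotone))
    return out


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

def relative_importance(outcome: np.ndarray, predictors: np.ndarray,
                        names: Sequence[str] | None = None) -> pd.Series:
    """LMG variance decomposition: per-predictor R^2 share.

    Averages each predictor's sequential R^2 gain over all orderings of the
    predictors; shares sum to the full-model R^2.  Limited to 6 predictors.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    if p > 6:
        raise TrajectoryError("more than 6 predictors (factorial blow-up)")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    full = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(full) < p + 1:
        raise TrajectoryError("rank-deficient design")

    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise TrajectoryError("constant outcome")

    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}

    def r2(subset: frozenset) -> float:
        if subset not in r2_cache:
            Xs = np.column_stack([np.ones(n), X[:, sorted(subset)]])
            beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            resid = y - Xs @ beta
            r2_cache[subset] = 1.0 - float(resid @ resid) / tss
        return r2_cache[subset]

    shares = np.zeros(p)
    fact = math.factorial
    for j in range(p):
        others = [i for i in range(p) if i != j]
        for size in range(p):
            weight = fact(size) * fact(p - size - 1) / fact(p)
            for combo in itertools.combinations(others, size):
                s = frozenset(combo)
                shares[j] += weight * (r2(s | {j}) - r2(s))
    return pd.Series(shares, index=list(names))


def pseudotime_robustness(values: np.ndarray,
                          k_values: Sequence[int] = (5, 10, 25, 50),
                          pc_values: Sequence[int] = (40,),
                          n_clusters: int = 3, seed: int = 0) -> dict:
    """Mean pairwise |Spearman| of pseudotime across (k, n_pcs) settings."""
    settings = list(itertools.product(k_values, pc_values))
    if len(settings) < 2:
        raise TrajectoryError("need at least 2 settings")
    estimates = []
    for k, npc in settings:
        res = compute_pseudotime(values, n_pcs=npc, k=k,
                                 n_clusters=n_clusters, seed=seed)
        estimates.append(res.pseudotime)
    cors = []
    for i in range(len(estimates)):
        for j in range(i + 1, len(estimates)):
            r = stats.spearmanr(estimates[i], estimates[j]).statistic
            cors.append(abs(float(r)))
    return {"mean_abs_spearman": float(np.mean(cors)),
            "pairwise": cors, "settings": settings}
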