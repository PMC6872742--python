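"""Unsupervised feature reduction: k-medoids under Pearson correlation distance.

Features (columns of the feature table) are clustered with PAM-style
k-medoids using the distance d(x, y) = 1 - R(x, y), where R is the Pearson
correlation over patients. The number of clusters is chosen by the
Silhouette method over repeated random initializations, and the medoid
columns form the reduced, survival-blind feature pool.

Constant (zero-variance) columns have undefined correlation; pairs
involving one are assigned distance 1 (treated as uncorrelated) by
:func:`correlation_distance`, and the table-level entry point drops them
with a log message before clustering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: Above this many features the O(k (n-k)^2) PAM swap phase is skipped and
#: only the alternating (Voronoi) heuristic is used.
PAM_SWAP_MAX_FEATURES = 200


@dataclass
class ClusteringResult:
    """Assignment of features to k medoid-led clusters."""

    k: int
    assignment: np.ndarray  # feature -> cluster id (index into medoid_indices)
    medoid_indices: np.ndarray  # k feature column indices
    inner_distance_sum: float
    silhouette: float
    n_init: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "assignment": self.assignment.tolist(),
                "medoid_indices": self.medoid_indices.tolist(),
                "inner_distance_sum": self.inner_distance_sum,
                "silhouette": self.silhouette,
                "n_init": self.n_init,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ClusteringResult":
        d = json.loads(text)
        return cls(
            k=d["k"],
            assignment=np.asarray(d["assignment"], dtype=int),
            medoid_indices=np.asarray(d["medoid_indices"], dtype=int),
            inner_distance_sum=d["inner_distance_sum"],
            silhouette=d["silhouette"],
            n_init=d["n_init"],
            seed=d["seed"],
        )


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation distance 1 - R(x, y), in [0, 2].

    Zero iff perfectly positively correlated; 2 iff perfectly
    anticorrelated. A constant column makes R undefined; the pair is then
    treated as uncorrelated (distance 1) and logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations for a correlation")
    xc, yc = x - x.mean(), y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        log.debug("constant column in correlation_distance; returning 1 (uncorrelated)")
        return 1.0
    r = float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))
    return 1.0 - r


def correlation_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Full pairwise 1 - R matrix over columns of (patients x features)."""
    v = np.asarray(values, dtype=np.float64)
    vc = v - v.mean(axis=0)
    norms = np.linalg.norm(vc, axis=0)
    safe = norms.copy()
    n_const = int((norms == 0).sum())
    if n_const:
        log.warning("%d constant feature(s) in distance matrix; distances set to 1", n_const)
        safe[norms == 0] = 1.0
    u = (vc / safe).astype(np.float32)
    r = np.clip(u.T @ u, -1.0, 1.0)
    d = 1.0 - r
    if n_const:
        d[norms == 0, :] = 1.0
        d[:, norms == 0] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def drop_constant_features(values: np.ndarray) -> np.ndarray:
    """Indices of non-constant columns (constants are excluded with a log)."""
    keep = np.flatnonzero(values.std(axis=0) > 0)
    dropped = values.shape[1] - keep.size
    if dropped:
        log.info("dropping %d constant feature(s) before clustering", dropped)
    return keep


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    """Nearest-medoid assignment; ties break to the lowest medoid position.

    Every medoid is forced into its own cluster (relevant under duplicate
    columns, where another medoid may tie at distance zero).
    """
    assign = np.argmin(D[:, medoids], axis=1)
    assign[medoids] = np.arange(len(medoids))
    return assign


def _cost(D: np.ndarray, medoids: np.ndarray, assign: np.ndarray) -> float:
    return float(D[np.arange(D.shape[0]), medoids[assign]].sum())


def _cluster_distance_sums(D: np.ndarray, assign: np.ndarray, k: int) -> np.ndarray:
    """S[c, i] = sum of distances from feature i to all members of cluster c.

    One n x k GEMM; this is the hot path of both the medoid update and the
    silhouette computation at 10^4-feature scale.
    """
    onehot = np.zeros((D.shape[0], k), dtype=D.dtype)
    onehot[np.arange(D.shape[0]), assign] = 1.0
    return (D @ onehot).T


def _alternate(D: np.ndarray, medoids: np.ndarray, max_iter: int = 100):
    """Voronoi iteration: assign to nearest medoid, re-center each cluster."""
    medoids = medoids.copy()
    k = len(medoids)
    for _ in range(max_iter):
        assign = _assign(D, medoids)
        S = _cluster_distance_sums(D, assign, k)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            new[c] = members[int(np.argmin(S[c, members]))]  # ties -> lowest index
        if np.array_equal(new, medoids):
            break
        medoids = new
    assign = _assign(D, medoids)
    return medoids, assign


def _pam_swap(D: np.ndarray, medoids: np.ndarray, assign: np.ndarray):
    """Greedy best-improvement swap phase (exact PAM refinement)."""
    n = D.shape[0]
    medoids = medoids.copy()
    cost = _cost(D, medoids, assign)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        in_medoids = np.zeros(n, bool)
        in_medoids[medoids] = True
        for mi in range(len(medoids)):
            for h in np.flatnonzero(~in_medoids):
                cand = medoids.copy()
                cand[mi] = h
                a = _assign(D, cand)
                c = _cost(D, cand, a)
                if c < cost - 1e-12 and (best[1] is None or c < best[0]):
                    best = (c, cand, a)
        if best[1] is not None:
            cost, medoids, assign = best[0], best[1], best[2]
            improved = True
    return medoids, assign


def kmedoids(
    values_or_D: np.ndarray,
    k: int,
    n_init: int = 10,
    seed: int = 0,
    precomputed: bool = False,
) -> ClusteringResult:
    """PAM-style k-medoids under correlation distance, best of ``n_init``.

    ``values_or_D`` is a patients x features matrix, or a precomputed
    distance matrix when ``precomputed=True``. On problems with at most
    ``PAM_SWAP_MAX_FEATURES`` features the alternating pass is refined by a
    full PAM swap phase. Deterministic under ``seed``; the best run is the
    one with the smallest summed inner distance (ties to the earliest run).
    """
    D = np.asarray(values_or_D) if precomputed else correlation_distance_matrix(values_or_D)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} features")
    rng = np.random.default_rng(seed)
    use_swap = n <= PAM_SWAP_MAX_FEATURES
    best = None
    for _ in range(n_init):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        medoids, assign = _alternate(D, medoids)
        if use_swap:
            medoids, assign = _pam_swap(D, medoids, assign)
        cost = _cost(D, medoids, assign)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, medoids, assign)
    cost, medoids, assign = best
    order = np.argsort(medoids)  # canonical: medoids ascending
    medoids = medoids[order]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    assign = remap[assign]
    sil = _silhouette(D, assign)
    return ClusteringResult(
        k=k,
        assignment=assign,
        medoid_indices=medoids,
        inner_distance_sum=cost,
        silhouette=sil,
        n_init=n_init,
        seed=seed,
    )


def _silhouette(D: np.ndarray, assign: np.ndarray) -> float:
    """Mean silhouette under a precomputed distance matrix.

    Vectorized equivalent of sklearn's precomputed silhouette_score
    (cross-checked against it in the test suite): a(i) is the mean distance
    to own-cluster co-members, b(i) the smallest mean distance to another
    cluster; singleton clusters score 0.
    """
    labels = np.unique(assign)
    n = D.shape[0]
    if len(labels) < 2 or len(labels) > n - 1:
        return float("nan")  # silhouette undefined at k=1 and k=n
    k = int(assign.max()) + 1
    S = _cluster_distance_sums(D, assign, k)  # (k, n)
    sizes = np.bincount(assign, minlength=k).astype(np.float64)
    own = sizes[assign]
    a = np.where(own > 1, S[assign, np.arange(n)] / np.maximum(own - 1, 1), 0.0)
    mean_other = S.T / sizes  # (n, k) mean distance to each cluster
    mean_other[np.arange(n), assign] = np.inf
    mean_other[:, sizes == 0] = np.inf
    b = mean_other.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where((own > 1) & (denom > 0), (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(s.mean())


def silhouette_sweep(
    values: np.ndarray,
    k_range,
    n_init: int = 10,
    seed: int = 0,
    precomputed: bool = False,
) -> tuple[int, "object", dict[int, ClusteringResult]]:
    """Choose k by the Silhouette method over a range of cluster counts.

    For each k, ``n_init`` random initializations are run; the per-k curve
    records the mean summed inner-cluster distance and the mean Silhouette
    value across runs (consistency check), and the best run by inner
    distance is retained. The optimal k maximizes the mean Silhouette.

    Returns ``(k_opt, curve_dataframe, {k: best ClusteringResult})``.
    """
    import pandas as pd

    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("empty k range")
    D = np.asarray(values) if precomputed else correlation_distance_matrix(values)
    n = D.shape[0]
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError(f"k range {k_range} outside [2, {n - 1}]")
    rows, results = [], {}
    rng = np.random.default_rng(seed)
    for k in k_range:
        costs, sils = [], []
        best = None
        for _ in range(n_init):
            res = kmedoids(D, k, n_init=1, seed=int(rng.integers(2**31)), precomputed=True)
            costs.append(res.inner_distance_sum)
            sils.append(res.silhouette)
            if best is None or res.inner_distance_sum < best.inner_distance_sum - 1e-12:
                best = res
        results[k] = best
        rows.append(
            {
                "k": k,
                "mean_inner_distance": float(np.mean(costs)),
                "mean_silhouette": float(np.nanmean(sils)),
            }
        )
    curve = pd.DataFrame(rows)
    k_opt = int(curve.loc[curve["mean_silhouette"].idxmax(), "k"])
    return k_opt, curve, results


def select_medoids(table, result: ClusteringResult):
    """Reduced table containing exactly the k medoid columns (provenance kept)."""
    if result.assignment.shape[0] != table.n_features:
        raise ValueError(
            f"clustering over {result.assignment.shape[0]} features does not match "
            f"table with {table.n_features} columns"
        )
    return table.subset_columns(result.medoid_indices)


def save_clustering(result: ClusteringResult, path) -> None:
    Path(path).write_text(result.to_json())


def load_clustering(path) -> ClusteringResult:
    return ClusteringResult.from_json(Path(path).read_text())
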