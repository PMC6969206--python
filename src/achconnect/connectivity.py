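"""Connectivity matrices, stepping-stone probabilities, modularity clusters.

The single-generation connectivity matrix is P(i→j) = (number of particles
released at i that settled at j) / (number released at i).  Multi-generation
"stepping-stone" connectivity between sampled locations is the maximum
product of single-step probabilities over any path through the full set of
coastal points, computed with Floyd–Warshall on edge weights −ln P (the
minimum-sum path on −ln P is the maximum-product path on P).  Locations are
finally grouped by maximising weighted directed Newman modularity, by
exhaustive scan over all set partitions when the number of locations is
small enough and by a greedy agglomerative merge otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lagrangian import SETTLED, TrajectorySet


@dataclass
class ConnectivityMatrix:
    """Asymmetric settlement-probability matrix between coastal points.

    ``P[a, b]`` is the probability that a particle released at
    ``point_ids[a]`` settles at ``point_ids[b]``; row sums are ≤ 1, the
    remainder being the lost fraction.
    """

    point_ids: np.ndarray
    P: np.ndarray
    released: np.ndarray
    arrivals: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.point_ids = np.asarray(self.point_ids)
        self.P = np.asarray(self.P, dtype=float)

    def index_of(self, ids) -> np.ndarray:
        lookup = {p: k for k, p in enumerate(self.point_ids)}
        return np.array([lookup[i] for i in ids])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.P, index=self.point_ids, columns=self.point_ids).to_csv(path)

    def to_edge_list(self) -> pd.DataFrame:
        src, dst = np.nonzero(self.P)
        return pd.DataFrame(
            {
                "i": self.point_ids[src],
                "j": self.point_ids[dst],
                "P": self.P[src, dst],
            }
        )


def build_matrix(ts: TrajectorySet) -> ConnectivityMatrix:
    """Settlement probabilities P(i→j) = arrivals / releases from a run.

    Origins with zero releases are excluded (with a warning); lost particles
    contribute to no destination.
    """
    released = ts.released
    zero = released[released == 0].index.to_numpy()
    if len(zero):
        warnings.warn(f"origins with zero releases excluded: {list(zero)}")
    ids = released[released > 0].index.to_numpy()
    lookup = {p: k for k, p in enumerate(ids)}
    n = len(ids)
    arrivals = np.zeros((n, n))
    settled = ts.particles[ts.particles["fate"] == SETTLED]
    for o, s in zip(settled["origin_id"].to_numpy(), settled["settle_id"].to_numpy()):
        if o in lookup and s in lookup:
            arrivals[lookup[o], lookup[s]] += 1
    rel = released[released > 0].to_numpy().astype(float)
    P = arrivals / rel[:, None]
    return ConnectivityMatrix(
        point_ids=ids, P=P, released=rel, arrivals=arrivals, label=ts.year
    )


def average_matrices(yearly: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise arithmetic mean of annual matrices (label 'averaged')."""
    if len(yearly) == 0:
        raise ValueError("no matrices to average")
    ids = yearly[0].point_ids
    for m in yearly[1:]:
        if len(m.point_ids) != len(ids) or np.any(m.point_ids != ids):
            raise ValueError("matrices have mismatched point sets")
    P = np.mean([m.P for m in yearly], axis=0)
    return ConnectivityMatrix(
        point_ids=ids,
        P=P,
        released=np.sum([m.released for m in yearly], axis=0),
        arrivals=np.sum([m.arrivals for m in yearly], axis=0),
        label="averaged",
    )


@dataclass
class SteppingStoneResult:
    """Per-ordered-pair max-product path probabilities between sampled sites.

    ``pairs`` columns: source, target, direct_p, stepping_p, path (list of
    point ids along the best path, empty when unreachable).
    """

    pairs: pd.DataFrame

    def prob(self, source, target) -> float:
        row = self.pairs[
            (self.pairs["source"] == source) & (self.pairs["target"] == target)
        ]
        return float(row["stepping_p"].iloc[0])

    def path(self, source, target) -> list:
        row = self.pairs[
            (self.pairs["source"] == source) & (self.pairs["target"] == target)
        ]
        return list(row["path"].iloc[0])


def _floyd_warshall(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest paths on weight matrix W (np.inf = missing edge).

    Returns (dist, nxt) where nxt[i, j] is the next hop on the best i→j
    path (-1 when unreachable).  Updates only on strict improvement, with
    intermediates considered in ascending index order, so the result is
    deterministic.
    """
    n = W.shape[0]
    dist = W.copy()
    np.fill_diagonal(dist, 0.0)
    nxt = np.where(np.isfinite(W), np.arange(n)[None, :], -1)
    np.fill_diagonal(nxt, np.arange(n))
    for k in range(n):
        alt = dist[:, k, None] + dist[None, k, :]
        better = alt < dist
        if better.any():
            dist = np.where(better, alt, dist)
            nxt = np.where(better, nxt[:, k, None], nxt)
    return dist, nxt


def _reconstruct(nxt: np.ndarray, i: int, j: int, ids) -> list:
    if nxt[i, j] < 0:
        return []
    path = [i]
    while i != j:
        i = int(nxt[i, j])
        path.append(i)
    return [ids[k] for k in path]


def stepping_stone(matrix: ConnectivityMatrix, sampled_ids) -> SteppingStoneResult:
    """Max-product path probability between every ordered pair of sampled ids.

    All coastal points in the matrix are path vertices; the sampled locations
    are only the query endpoints.  Zero-probability edges are absent
    (infinite −ln P weight); an unreachable pair gets probability 0 and an
    empty path.  Self-loops never enter a path, so the i→i entry is the
    direct retention probability only.
    """
    P = matrix.P
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        W = np.where(P > 0, -np.log(P), np.inf)
    np.fill_diagonal(W, np.inf)  # retention is not a stepping stone
    dist, nxt = _floyd_warshall(W)

    sel = matrix.index_of(sampled_ids)
    rows = []
    for a, i in zip(sampled_ids, sel):
        for b, j in zip(sampled_ids, sel):
            if i == j:
                continue
            d = dist[i, j]
            p = float(np.exp(-d)) if np.isfinite(d) else 0.0
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "direct_p": float(P[i, j]),
                    "stepping_p": p,
                    "path": _reconstruct(nxt, int(i), int(j), matrix.point_ids)
                    if np.isfinite(d)
                    else [],
                }
            )
    return SteppingStoneResult(pairs=pd.DataFrame(rows))


def stepping_stone_matrix(matrix: ConnectivityMatrix, sampled_ids) -> np.ndarray:
    """Square matrix of stepping-stone probabilities among ``sampled_ids``.

    The diagonal carries the direct retention probability.
    """
    res = stepping_stone(matrix, sampled_ids)
    n = len(sampled_ids)
    out = np.zeros((n, n))
    sel = matrix.index_of(sampled_ids)
    for k, i in enumerate(sel):
        out[k, k] = matrix.P[i, i]
    lookup = {s: k for k, s in enumerate(sampled_ids)}
    for _, r in res.pairs.iterrows():
        out[lookup[r["source"]], lookup[r["target"]]] = r["stepping_p"]
    return out


# ---------------------------------------------------------------------------
# modularity clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterPartition:
    """A partition of locations with its modularity score Q."""

    ids: np.ndarray
    labels: np.ndarray
    Q: float
    method: str  # 'exhaustive' or 'greedy'

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def clusters(self) -> list[list]:
        out = []
        for c in np.unique(self.labels):
            out.append(np.asarray(self.ids)[self.labels == c].tolist())
        return out

    def as_dict(self) -> dict:
        return {i: int(c) for i, c in zip(self.ids, self.labels)}


def _modularity_matrix(W: np.ndarray) -> np.ndarray:
    """B with self-loop edge weights zeroed but the null-model diagonal kept."""
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    m = W.sum()
    if m <= 0:
        raise ValueError("graph has no edges")
    s_out = W.sum(axis=1)
    s_in = W.sum(axis=0)
    return (W - np.outer(s_out, s_in) / m) / m


def modularity(W: np.ndarray, labels) -> float:
    """Weighted directed Newman modularity; self-loop edges are excluded.

    Q = (1/m) Σ_{ij : c_i = c_j} [w_ij − s_out(i) s_in(j) / m] with
    m = Σ_ij w_ij after zeroing the diagonal of w.  The i = j null-model
    term is retained, so the one-cluster partition scores exactly 0.
    """
    B = _modularity_matrix(W)
    labels = np.asarray(labels)
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _iter_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    a = np.zeros(n, dtype=int)
    mx = np.zeros(n, dtype=int)
    while True:
        yield a
        i = n - 1
        while i > 0 and a[i] > mx[i - 1]:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        mx[i] = max(mx[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            mx[j] = mx[i]


def _exhaustive_python(B: np.ndarray) -> tuple[np.ndarray, float]:
    Bs = B + B.T  # Q(labels) = sum over unordered same-cluster pairs of Bs
    n = B.shape[0]
    best_q = -np.inf
    best = np.zeros(n, dtype=int)
    for labels in _iter_partitions(n):
        same = labels[:, None] == labels[None, :]
        q = 0.5 * Bs[same].sum()
        if q > best_q:
            best_q = q
            best = labels.copy()
    return best, float(best_q)


def _exhaustive_numba(B: np.ndarray) -> tuple[np.ndarray, float]:
    from numba import njit

    @njit(cache=False)
    def scan(Bs):
        n = Bs.shape[0]
        a = np.zeros(n, dtype=np.int64)
        mx = np.zeros(n, dtype=np.int64)
        best = np.zeros(n, dtype=np.int64)
        best_q = -1e300
        while True:
            q = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    if a[i] == a[j]:
                        q += Bs[i, j]
            if q > best_q:
                best_q = q
                for i in range(n):
                    best[i] = a[i]
            i = n - 1
            while i > 0 and a[i] > mx[i - 1]:
                i -= 1
            if i == 0:
                break
            a[i] += 1
            mx[i] = mx[i - 1] if mx[i - 1] > a[i] else a[i]
            for j in range(i + 1, n):
                a[j] = 0
                mx[j] = mx[i]
        return best, best_q

    best, q = scan(B + B.T)
    return np.asarray(best), float(q) + float(np.trace(B))


def _greedy(B: np.ndarray) -> tuple[np.ndarray, float]:
    """Agglomerative merging: repeatedly join the pair of clusters with the
    largest positive modularity gain."""
    n = B.shape[0]
    Bs = B + B.T
    labels = np.arange(n)
    clusters = {c: [c] for c in range(n)}
    while len(clusters) > 1:
        best_gain, best_pair = 0.0, None
        keys = sorted(clusters)
        for a, b in itertools.combinations(keys, 2):
            gain = sum(Bs[i, j] for i in clusters[a] for j in clusters[b])
            if gain > best_gain + 1e-15:
                best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            break
        a, b = best_pair
        clusters[a].extend(clusters.pop(b))
    new = np.empty(n, dtype=int)
    for c, (_, members) in enumerate(sorted(clusters.items())):
        new[members] = c
    q = 0.5 * Bs[new[:, None] == new[None, :]].sum()
    return new, float(q)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    seen: dict[int, int] = {}
    out = np.empty_like(labels)
    for k, c in enumerate(labels):
        out[k] = seen.setdefault(int(c), len(seen))
    return out


def cluster_modularity(
    W: np.ndarray,
    ids=None,
    exhaustive_limit: int = 14,
) -> ClusterPartition:
    """Partition locations by maximising directed weighted modularity.

    ``W`` is a square non-negative weight matrix (e.g. stepping-stone or
    direct probabilities among sampled locations); self-loops are ignored.
    Up to ``exhaustive_limit`` locations all set partitions are scanned
    (Bell-number many; a compiled enumerator is used when available past 10
    nodes) and the global optimum is returned; above the limit a greedy
    agglomerative search is used and flagged in ``method``.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    B = _modularity_matrix(W)

    if n <= exhaustive_limit:
        if n <= 10:
            labels, q = _exhaustive_python(B)
        else:
            try:
                labels, q = _exhaustive_numba(B)
            except ImportError:  # pragma: no cover - numba expected present
                warnings.warn(
                    "numba unavailable: falling back to greedy search above 10 nodes"
                )
                labels, q = _greedy(B)
                return ClusterPartition(ids, _relabel_by_first_occurrence(labels), q, "greedy")
        method = "exhaustive"
    else:
        labels, q = _greedy(B)
        method = "greedy"
    return ClusterPartition(ids, _relabel_by_first_occurrence(labels), q, method)
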