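"""Topological traits of branch skeletons via 0-dimensional persistent homology.

The branching pattern of a plant is summarized by sweeping a threshold *t*
downward through the geodesic distance-to-base function on the skeleton and
tracking connected components of the superlevel sets {d >= t}.  A component
is born at each branch tip (local maximum of d) and dies when it merges into
an older component (elder rule); the single surviving component dies at 0.
The resulting barcode — a multiset of (birth, death) intervals with
birth >= death — is compared between plants with the bottleneck distance,
and classical (Torgerson) multidimensional scaling of the pairwise distance
matrix yields the topological coordinates MDS1-MDS3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import PlantGraph

__all__ = [
    "Barcode",
    "MDSEmbedding",
    "geodesic_distances",
    "persistence_barcode",
    "bottleneck_distance",
    "pairwise_topo_distances",
    "classical_mds",
]


@dataclass(frozen=True)
class Barcode:
    """Multiset of (birth, death) intervals, birth >= death >= 0, in cm.

    Superlevel-set convention: bars are born at large geodesic distance
    (branch tips) and die at smaller distance (merge junctions).  Exactly
    one bar — the essential one — dies at 0.
    """

    intervals: tuple[tuple[float, float], ...]
    image_id: str = ""

    def __post_init__(self) -> None:
        for b, d in self.intervals:
            if not (b >= d >= 0):
                raise ValueError(f"invalid interval (birth={b}, death={d})")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def persistences(self) -> np.ndarray:
        return np.array([b - d for b, d in self.intervals])

    def total_persistence(self) -> float:
        return float(self.persistences.sum()) if self.intervals else 0.0


@dataclass
class MDSEmbedding:
    """Classical-MDS coordinates with per-dimension variance fractions."""

    coordinates: np.ndarray          # n x k
    variance_explained: np.ndarray   # fraction of positive-eigenvalue mass
    eigenvalues: np.ndarray          # all eigenvalues, descending


def geodesic_distances(plant: PlantGraph) -> dict[int, float]:
    """Path length in cm from the base vertex to every vertex.

    The skeleton is a tree, so the shortest path is the unique path and the
    distance is monotone non-decreasing along any root-to-leaf walk.
    """
    if not nx.is_connected(plant.graph):
        raise ValueError("plant skeleton is disconnected")
    return nx.single_source_dijkstra_path_length(
        plant.graph, plant.base_vertex, weight="length"
    )


def persistence_barcode(
    plant: PlantGraph, distances: dict[int, float] | None = None
) -> Barcode:
    """0-dimensional persistence of the superlevel filtration of geodesic distance.

    Vertices are inserted in order of decreasing distance (ties broken by
    vertex id).  Inserting a vertex with no previously inserted neighbor
    births a component at its distance value; when an insertion joins
    components, every component except the oldest (largest birth; ties by
    the smaller root vertex id) dies at the current distance (elder rule).
    The component containing the base survives to death 0.  One bar per
    branch tip.
    """
    if distances is None:
        distances = geodesic_distances(plant)
    g = plant.graph
    order = sorted(distances, key=lambda v: (-distances[v], v))

    parent: dict[int, int] = {}
    birth: dict[int, float] = {}  # root -> birth value

    def find(v: int) -> int:
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root

    bars: list[tuple[float, float]] = []
    inserted: set[int] = set()
    for v in order:
        parent[v] = v
        birth[v] = distances[v]
        inserted.add(v)
        roots = {find(u) for u in g.neighbors(v) if u in inserted}
        roots.add(find(v))
        if len(roots) > 1:
            # Oldest component survives; ties by smaller root id.
            elder = max(roots, key=lambda r: (birth[r], -r))
            for r in roots:
                # birth == death means the "component" was just the newly
                # inserted non-maximum vertex itself; no bar for those
                if r != elder and birth[r] > distances[v]:
                    bars.append((birth[r], distances[v]))
                parent[r] = elder

    root = find(plant.base_vertex)
    bars.append((birth[root], 0.0))
    bars.sort(key=lambda iv: (-iv[0], -iv[1]))
    return Barcode(tuple(bars), image_id=plant.image_id)


def _linf(p: tuple[float, float], q: tuple[float, float]) -> float:
    return max(abs(p[0] - q[0]), abs(p[1] - q[1]))


def _half_persistence(p: tuple[float, float]) -> float:
    return (p[0] - p[1]) / 2.0


def _feasible(a, b, cost_ab, diag_a, diag_b, t: float) -> bool:
    """Can every interval be matched (to a partner or the diagonal) at cost <= t?

    Bipartite side U = intervals of *a* plus |b| diagonal slots, side
    V = intervals of *b* plus |a| diagonal slots.  Diagonal-to-diagonal
    pairings are free, so a perfect matching of size |a|+|b| exists iff a
    maximum matching saturates U.  Hopcroft-Karp is overkill at these sizes;
    simple augmenting paths suffice.
    """
    n, m = len(a), len(b)
    size = n + m
    adj: list[list[int]] = [[] for _ in range(size)]
    for i in range(n):
        for j in range(m):
            if cost_ab[i][j] <= t:
                adj[i].append(j)
        if diag_a[i] <= t:
            adj[i].extend(range(m, size))
    for i in range(n, size):  # diagonal slots on the U side
        for j in range(m):
            if diag_b[j] <= t:
                adj[i].append(j)
        adj[i].extend(range(m, size))

    match_u = [-1] * size
    match_v = [-1] * size

    def augment(u: int, seen: list[bool]) -> bool:
        for v in adj[u]:
            if not seen[v]:
                seen[v] = True
                if match_v[v] == -1 or augment(match_v[v], seen):
                    match_u[u] = v
                    match_v[v] = u
                    return True
        return False

    matched = 0
    for u in range(size):
        if augment(u, [False] * size):
            matched += 1
    return matched == size


def bottleneck_distance(a: Barcode, b: Barcode) -> float:
    """Bottleneck distance between two barcodes.

    Minimum over partial matchings of the maximum L-inf cost between matched
    intervals, where an unmatched interval pays half its persistence (its
    L-inf distance to the diagonal birth = death).  The optimum is attained
    at one of finitely many candidate costs — the pairwise L-inf costs and
    the half-persistences — so a binary search over that sorted candidate
    set with a bipartite feasibility check is exact.
    """
    pa, pb = list(a.intervals), list(b.intervals)
    if not pa and not pb:
        return 0.0
    cost_ab = [[_linf(p, q) for q in pb] for p in pa]
    diag_a = [_half_persistence(p) for p in pa]
    diag_b = [_half_persistence(q) for q in pb]

    candidates = sorted(
        set(itertools.chain(diag_a, diag_b, (c for row in cost_ab for c in row)))
    )
    lo, hi = 0, len(candidates) - 1
    if _feasible(pa, pb, cost_ab, diag_a, diag_b, candidates[lo]):
        return candidates[lo]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _feasible(pa, pb, cost_ab, diag_a, diag_b, candidates[mid]):
            hi = mid
        else:
            lo = mid
    return candidates[hi]


def pairwise_topo_distances(barcodes: list[Barcode]) -> np.ndarray:
    """Symmetric matrix of pairwise bottleneck distances, zero diagonal."""
    n = len(barcodes)
    if n < 2:
        raise ValueError("need at least two barcodes")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bottleneck_distance(barcodes[i], barcodes[j])
    return d


def classical_mds(d: np.ndarray, k: int = 3) -> MDSEmbedding:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers -1/2 * J D^2 J, eigendecomposes, and returns coordinates
    scaled by the square roots of the top positive eigenvalues.  The
    variance explained by dimension i is lambda_i over the sum of positive
    eigenvalues.  Sign convention: the largest-magnitude loading in each
    dimension is made positive, so repeated runs agree (the embedding is
    otherwise only defined up to reflection).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(bmat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    pos = eigval > max(1e-12, 1e-9 * abs(eigval[0]))
    if not pos.any():
        raise ValueError("degenerate distance matrix: no positive eigenvalue")
    k_eff = min(k, int(pos.sum()))
    coords = eigvec[:, :k_eff] * np.sqrt(eigval[:k_eff])
    for dim in range(k_eff):
        col = coords[:, dim]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, dim] = -col
    varexp = eigval[:k_eff] / eigval[pos].sum()
    return MDSEmbedding(coords, varexp, eigval)
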