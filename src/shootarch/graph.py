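"""Branch-skeleton graph for a single plant image.

A plant skeleton is a tree of polylines: one *main* branch running from the
soil-line cut (base) to the top of the plant, and zero or more *primary*
branches attached at junction vertices on the main branch.  Secondary
branches (branches off primaries) are out of scope.  Coordinates are in cm
after calibration, with height increasing upward from the base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

MAIN = "main"
PRIMARY = "primary"


@dataclass
class Branch:
    """One labeled polyline: a role and an ordered vertex path."""

    role: str
    path: list[int]

    def __post_init__(self) -> None:
        if self.role not in (MAIN, PRIMARY):
            raise ValueError(f"unknown branch role {self.role!r}")
        if len(self.path) < 2:
            raise ValueError("a branch needs at least two vertices")


@dataclass
class PlantGraph:
    """Calibrated branch network of one plant image.

    ``graph`` is an undirected tree whose nodes carry a ``pos`` attribute
    (x, y) in cm and whose edges carry a ``length`` attribute (Euclidean,
    cm).  ``base_vertex`` is the soil-line cut; ``top_vertex`` the far end
    of the main branch.
    """

    graph: nx.Graph
    branches: list[Branch]
    base_vertex: int
    top_vertex: int
    image_id: str = ""
    accession_id: str = ""
    replicate_id: str = ""
    side: str = ""

    def validate(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise ValueError("empty plant graph")
        if not nx.is_connected(g):
            raise ValueError("plant skeleton is disconnected")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise ValueError("plant skeleton contains a cycle")
        mains = [b for b in self.branches if b.role == MAIN]
        if len(mains) != 1:
            raise ValueError(f"expected exactly one main branch, got {len(mains)}")
        main_set = set(mains[0].path)
        if self.base_vertex not in main_set or self.top_vertex not in main_set:
            raise ValueError("base/top anchors must lie on the main branch")
        for b in self.branches:
            if b.role == PRIMARY and b.path[0] not in main_set:
                raise ValueError(
                    f"primary branch does not start on the main branch (vertex {b.path[0]})"
                )
        for u, v, d in g.edges(data=True):
            if d["length"] <= 0:
                raise ValueError(f"non-positive edge length on ({u}, {v})")

    @property
    def main_branch(self) -> Branch:
        return next(b for b in self.branches if b.role == MAIN)

    @property
    def primary_branches(self) -> list[Branch]:
        return [b for b in self.branches if b.role == PRIMARY]

    def pos(self, v: int) -> tuple[float, float]:
        return tuple(self.graph.nodes[v]["pos"])

    def branch_length(self, branch: Branch) -> float:
        """Sum of edge lengths along the branch path."""
        return sum(
            self.graph.edges[u, v]["length"]
            for u, v in zip(branch.path[:-1], branch.path[1:])
        )

    def leaves(self) -> list[int]:
        """Degree-1 vertices excluding the base."""
        return [
            v for v in self.graph.nodes
            if self.graph.degree(v) == 1 and v != self.base_vertex
        ]


def build_graph(
    polylines: list[tuple[str, list[tuple[float, float]]]],
    base_point: tuple[float, float],
    snap_tol: float = 0.0,
    **meta: str,
) -> PlantGraph:
    """Assemble a :class:`PlantGraph` from role-labeled polylines.

    Vertices within ``snap_tol`` of an existing main-branch vertex are
    merged onto it (hand labeling is never vertex-exact, so a primary's
    first point rarely coincides with the main polyline bit-for-bit).
    The main polyline is oriented so that its end nearest ``base_point``
    becomes the base vertex.
    """
    mains = [(r, pts) for r, pts in polylines if r == MAIN]
    if len(mains) != 1:
        raise ValueError(f"expected exactly one main polyline, got {len(mains)}")

    g = nx.Graph()
    vid = 0
    index: list[tuple[float, float]] = []  # vid -> pos, for snapping

    def add_vertex(p: tuple[float, float], snap: bool) -> int:
        nonlocal vid
        if snap and snap_tol > 0 and index:
            best = min(range(len(index)), key=lambda i: math.dist(p, index[i]))
            if math.dist(p, index[best]) <= snap_tol:
                return best
        g.add_node(vid, pos=(float(p[0]), float(p[1])))
        index.append((float(p[0]), float(p[1])))
        vid += 1
        return vid - 1

    branches: list[Branch] = []
    # Main first so primaries can snap onto it.
    role, pts = mains[0]
    if math.dist(pts[-1], base_point) < math.dist(pts[0], base_point):
        pts = list(reversed(pts))
    path = [add_vertex(p, snap=False) for p in pts]
    _wire(g, path)
    branches.append(Branch(MAIN, path))
    base_vertex, top_vertex = path[0], path[-1]

    for role, pts in polylines:
        if role == MAIN:
            continue
        path = [add_vertex(p, snap=(i == 0)) for i, p in enumerate(pts)]
        _wire(g, path)
        branches.append(Branch(role, path))

    pg = PlantGraph(g, branches, base_vertex, top_vertex, **meta)
    pg.validate()
    return pg


def _wire(g: nx.Graph, path: list[int]) -> None:
    for u, v in zip(path[:-1], path[1:]):
        if u == v:
            raise ValueError("zero-length edge in polyline")
        length = math.dist(g.nodes[u]["pos"], g.nodes[v]["pos"])
        if g.has_edge(u, v):
            raise ValueError("duplicate edge between polylines (cycle)")
        g.add_edge(u, v, length=length)
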