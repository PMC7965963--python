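"""Independent brute-force oracles used by the test suite.

Each oracle takes a computational route disjoint from the implementation it
checks: recursive merge trees and superlevel component counting for
barcodes, exhaustive matching enumeration for the bottleneck distance, and
exact rational hypergeometric enumeration for the Fisher test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx

from shootarch.graph import PlantGraph
from shootarch.topology import Barcode


def barcode_by_merge_tree(plant: PlantGraph, distances: dict[int, float]) -> list:
    """Barcode via a recursive subtree computation (no union-find sweep).

    For the tree rooted at the base, each subtree contributes its maximum
    leaf distance.  Where k child subtrees meet at a vertex v, the elder
    rule keeps the child with the largest maximum (ties: smaller birth
    vertex id) and kills the others at d(v).  The surviving global maximum
    dies at 0.
    """
    g = plant.graph
    root = plant.base_vertex

    def walk(v: int, parent: int | None) -> tuple[float, int, list]:
        """Returns (max distance in subtree, argmax vertex id, bars)."""
        children = [u for u in g.neighbors(v) if u != parent]
        best = (distances[v], v)
        bars: list = []
        subtrees = []
        for u in children:
            m, arg, sub = walk(u, v)
            bars.extend(sub)
            subtrees.append((m, arg))
        # the subtree containing v itself competes as a degenerate branch
        contenders = subtrees + [best]
        winner = max(contenders, key=lambda t: (t[0], -t[1]))
        for m, arg in contenders:
            if (m, arg) != winner and m > distances[v]:
                bars.append((m, distances[v]))
        return winner[0], winner[1], bars

    m, _, bars = walk(root, None)
    bars.append((m, 0.0))
    return sorted(bars, key=lambda iv: (-iv[0], -iv[1]))


def betti_curve_counts(plant: PlantGraph, distances: dict[int, float]) -> list:
    """(threshold, component count) of superlevel subgraphs at critical midpoints."""
    values = sorted(set(distances.values()))
    thresholds = [
        (a + b) / 2.0 for a, b in zip(values[:-1], values[1:])
    ]
    out = []
    for t in thresholds:
        nodes = [v for v, d in distances.items() if d >= t]
        sub = plant.graph.subgraph(nodes)
        out.append((t, nx.number_connected_components(sub)))
    return out


def barcode_component_count(barcode: Barcode, t: float) -> int:
    """How many bars are alive at threshold t (death < t <= birth...)."""
    return sum(1 for b, d in barcode.intervals if d <= t <= b)


def bottleneck_by_enumeration(a: Barcode, b: Barcode) -> float:
    """Exhaustive minimum over all partial matchings (small barcodes only)."""
    pa, pb = list(a.intervals), list(b.intervals)

    def linf(p, q):
        return max(abs(p[0] - q[0]), abs(p[1] - q[1]))

    def diag(p):
        return (p[0] - p[1]) / 2.0

    best = [float("inf")]

    def recurse(i: int, used: set, current_max: float) -> None:
        if current_max >= best[0]:
            return
        if i == len(pa):
            rest = max(
                (diag(q) for j, q in enumerate(pb) if j not in used),
                default=0.0,
            )
            best[0] = min(best[0], max(current_max, rest))
            return
        recurse(i + 1, used, max(current_max, diag(pa[i])))  # unmatched
        for j, q in enumerate(pb):
            if j not in used:
                recurse(i + 1, used | {j}, max(current_max, linf(pa[i], q)))

    recurse(0, set(), 0.0)
    return best[0]


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p as an exact rational (probability-mass rule).

    All tables with the observed margins are enumerated; numerators
    comb(r1, x) * comb(r2, c1 - x) share the denominator comb(n, c1), so
    the probability comparison is exact integer arithmetic — no float ties.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = comb(r1, a) * comb(r2, c1 - a)
    total = sum(
        comb(r1, x) * comb(r2, c1 - x)
        for x in range(lo, hi + 1)
        if comb(r1, x) * comb(r2, c1 - x) <= num_obs
    )
    return Fraction(total, comb(n, c1))


def all_tables_up_to(n_max: int):
    """Every 2x2 count table with positive margins and total <= n_max."""
    for n in range(2, n_max + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    if min(a + b, c + d) > 0 and min(a + c, b + d) > 0:
                        yield a, b, c, d
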