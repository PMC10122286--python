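"""Independent brute-force oracles used to validate the package's fast paths.

Everything here is deliberately naive (enumeration, O(n^3) geometry,
union-find) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Delaunay via the empty-circumcircle definition
# ---------------------------------------------------------------------------

def brute_delaunay_edges(pts: np.ndarray, chunk: int = 50_000) -> set[tuple[int, int]]:
    """Edges of the Delaunay triangulation by direct circumcircle testing.

    A triangle belongs to the triangulation iff no other point lies strictly
    inside its circumcircle; its three sides are Delaunay edges.  O(n^4)
    naive cost, vectorized over chunks of triples.
    """
    pts = np.asarray(pts, dtype=np.float64)
    n = len(pts)
    triples = np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)
    edges: set[tuple[int, int]] = set()
    x, y = pts[:, 0], pts[:, 1]
    for start in range(0, len(triples), chunk):
        t = triples[start: start + chunk]
        ax, ay = x[t[:, 0]], y[t[:, 0]]
        bx, by = x[t[:, 1]], y[t[:, 1]]
        cx, cy = x[t[:, 2]], y[t[:, 2]]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        ok = np.abs(d) > 1e-12
        a2 = ax**2 + ay**2
        b2 = bx**2 + by**2
        c2 = cx**2 + cy**2
        with np.errstate(divide="ignore", invalid="ignore"):
            ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
            uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
        r2 = (ux - ax) ** 2 + (uy - ay) ** 2
        # strict interior test with a relative slack for near-cocircular points
        d2 = (x[None, :] - ux[:, None]) ** 2 + (y[None, :] - uy[:, None]) ** 2
        inside = d2 < r2[:, None] * (1.0 - 1e-9)
        inside[np.arange(len(t))[:, None], t] = False
        empty = ok & ~inside.any(axis=1)
        for i, j, k in t[empty]:
            edges.add((int(i), int(j)))
            edges.add((int(i), int(k)))
            edges.add((int(j), int(k)))
    return edges


def gift_wrapping_hull(pts: np.ndarray) -> np.ndarray:
    """Convex hull vertex coordinates by the gift-wrapping (Jarvis) march."""
    pts = np.asarray(pts, dtype=np.float64)
    n = len(pts)
    start = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
    hull = [start]
    current = start
    while True:
        cand = (current + 1) % n
        for j in range(n):
            if j == current:
                continue
            u = pts[cand] - pts[current]
            v = pts[j] - pts[current]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[current])
                             > np.linalg.norm(pts[cand] - pts[current])):
                cand = j
        current = cand
        if current == start:
            break
        hull.append(current)
    return pts[hull]


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a simple polygon."""
    v = np.asarray(vertices, dtype=np.float64)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# Connected components via union-find
# ---------------------------------------------------------------------------

class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def union_find_components(n: int, edges) -> list[frozenset[int]]:
    uf = UnionFind(n)
    for i, j in edges:
        uf.union(int(i), int(j))
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


# ---------------------------------------------------------------------------
# Join-count moments by exhaustive enumeration
# ---------------------------------------------------------------------------

def enumerate_join_moments(n: int, edges, n_slow: int) -> tuple[float, float]:
    """Mean and variance of the unlike-pair count over all labelings with
    exactly ``n_slow`` slow fibers (population variance)."""
    us = []
    for slow in itertools.combinations(range(n), n_slow):
        z = np.ones(n, dtype=int)
        z[list(slow)] = -1
        us.append(sum(1 for i, j in edges if z[i] != z[j]))
    us = np.asarray(us, dtype=float)
    return float(us.mean()), float(us.var())


def all_graphs(n: int):
    """Yield the edge list of every labeled graph on n nodes with >= 1 edge."""
    possible = list(itertools.combinations(range(n), 2))
    for r in range(1, len(possible) + 1):
        for subset in itertools.combinations(possible, r):
            yield list(subset)
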