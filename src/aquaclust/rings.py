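"""Shortest-path (SP) ring enumeration (2nd-level structure).

An SP ring is a cycle in the hydrogen-bond graph in which no pair of
member molecules has a shortcut: for every pair of nodes on the cycle the
shorter arc along the cycle equals their shortest-path distance in the
full graph.  This rejects cycles that merely circumscribe smaller rings
(a chorded hexagon contributes its two 4-rings, not the 6-cycle).

Ring sizes are capped (default 8).  The SP criterion is applied against
the full graph, testing all vertex pairs of the candidate cycle.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Iterable, Mapping

import networkx as nx


@dataclasses.dataclass(frozen=True, order=True)
class Ring:
    """A cyclically ordered ring, stored in canonical form.

    Canonical form: the lowest member first, then the direction whose
    second element is smaller.  Two rings are equal iff they traverse the
    same cycle.
    """

    members: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", canonical_cycle(self.members))
        if len(set(self.members)) != len(self.members):
            raise ValueError("ring members must be distinct")
        if len(self.members) < 3:
            raise ValueError("a ring has at least 3 members")

    @property
    def size(self) -> int:
        return len(self.members)

    def edges(self) -> frozenset[frozenset[int]]:
        """The undirected edges traversed by the ring."""
        m = self.members
        return frozenset(frozenset((m[i], m[(i + 1) % len(m)]))
                         for i in range(len(m)))


def canonical_cycle(members: Iterable[int]) -> tuple[int, ...]:
    """Rotate/reflect a cyclic sequence into its canonical representative."""
    m = tuple(int(x) for x in members)
    k = len(m)
    start = m.index(min(m))
    fwd = tuple(m[(start + i) % k] for i in range(k))
    rev = tuple(m[(start - i) % k] for i in range(k))
    return min(fwd, rev)


def _bfs_distances(graph: nx.Graph, source: int, cap: int) -> dict[int, int]:
    """Hop distances from ``source``, truncated at depth ``cap``."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if dist[u] == cap:
            continue
        for v in graph[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _is_sp_cycle(cycle: tuple[int, ...],
                 dists: Mapping[int, Mapping[int, int]]) -> bool:
    """Does the shorter arc equal the graph distance for every member pair?"""
    k = len(cycle)
    for a in range(k):
        da = dists[cycle[a]]
        for b in range(a + 1, k):
            arc = min(b - a, k - (b - a))
            # graph distance <= arc always; equality is the SP condition
            if da.get(cycle[b], arc + 1) < arc:
                return False
    return True


def enumerate_sp_rings(graph: nx.Graph, max_size: int = 8) -> set[Ring]:
    """Enumerate every SP ring of ``graph`` with at most ``max_size`` members.

    Candidate simple cycles are generated by a depth-first search rooted at
    each cycle's smallest node (each cycle produced exactly once), then
    filtered by the shortest-path criterion using per-node BFS distances
    truncated at ``max_size // 2``.
    """
    if max_size < 3:
        raise ValueError("max_size must be >= 3")
    cap = max_size // 2
    dist_cache: dict[int, dict[int, int]] = {}

    def dist_from(u: int) -> dict[int, int]:
        if u not in dist_cache:
            dist_cache[u] = _bfs_distances(graph, u, cap)
        return dist_cache[u]

    rings: set[Ring] = set()
    for s in sorted(graph.nodes):
        ds = dist_from(s)
        # DFS over paths s -> ... with all interior nodes > s
        stack: list[tuple[int, list[int], set[int]]] = [(s, [s], {s})]
        while stack:
            u, path, seen = stack.pop()
            for v in graph[u]:
                if v == s and len(path) >= 3:
                    if path[1] < path[-1]:  # one direction per cycle
                        cycle = tuple(path)
                        dmap = {n: dist_from(n) for n in cycle}
                        if _is_sp_cycle(cycle, dmap):
                            rings.add(Ring(cycle))
                    continue
                if v <= s or v in seen or len(path) == max_size:
                    continue
                # prune: closing the cycle needs dist(s, v) more edges
                if len(path) + ds.get(v, cap + 1) > max_size:
                    continue
                stack.append((v, path + [v], seen | {v}))
    return rings


def ring_size_histogram(rings: Iterable[Ring]) -> dict[int, int]:
    """Counts of rings by size ``k``; absent sizes are omitted."""
    hist: dict[int, int] = {}
    for r in rings:
        hist[r.size] = hist.get(r.size, 0) + 1
    return hist


def ring_table(rings: Iterable[Ring], frame_index: int = 0) -> list[tuple]:
    """Rows ``(frame, ring_id, size, "m0,m1,...")`` for TSV export."""
    return [(frame_index, i, r.size, ",".join(map(str, r.members)))
            for i, r in enumerate(sorted(rings))]
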