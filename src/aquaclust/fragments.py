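"""Cage fragments (3rd-level structure) and body/surface ring roles.

A fragment is a closed cage built from a small set of SP rings: a minimal
set of 3–5 rings whose covered hydrogen-bond edges each belong to exactly
two member rings (a closed 2-complex).  The theta cage — two 3-coordinated
molecules joined by three hydrogen-bonded paths — is the smallest family:
its three cycles pairwise share the path edges, giving signatures such as
(4,5,5) for 6 molecules or (6,7,7) for 9.

Fragments may share rings and molecules with each other; sharing is what
later links them into the fragment network.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .rings import Ring


@dataclasses.dataclass(frozen=True)
class Fragment:
    """A closed cage of rings; identity is the ring set."""

    rings: frozenset[Ring]

    @property
    def molecules(self) -> frozenset[int]:
        return frozenset(m for r in self.rings for m in r.members)

    @property
    def signature(self) -> tuple[int, ...]:
        return fragment_signature(self)

    @property
    def covered_edges(self) -> frozenset[frozenset[int]]:
        return frozenset(e for r in self.rings for e in r.edges())


def fragment_signature(fragment: Fragment) -> tuple[int, ...]:
    """Sorted tuple of member-ring sizes, e.g. ``(4, 5, 5)``."""
    return tuple(sorted(r.size for r in fragment.rings))


def _is_closed(rings: Sequence[Ring]) -> bool:
    """Every edge covered by the ring set lies in exactly two member rings."""
    counts: dict[frozenset[int], int] = {}
    for r in rings:
        for e in r.edges():
            counts[e] = counts.get(e, 0) + 1
            if counts[e] > 2:
                return False
    return all(c == 2 for c in counts.values())


def _connected_ring_subsets(adjacency: dict[int, set[int]], max_size: int):
    """Yield every connected subset of ring indices with 2..max_size members,
    each exactly once (ESU enumeration)."""

    def extend(sub: list[int], ext: list[int], neighborhood: set[int], root: int):
        if len(sub) >= 2:
            yield tuple(sub)
        if len(sub) == max_size:
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            new_neigh = neighborhood | adjacency[w]
            new_ext = ext + [u for u in adjacency[w]
                             if u > root and u not in neighborhood and u != w]
            yield from extend(sub + [w], new_ext, new_neigh, root)

    for v in sorted(adjacency):
        yield from extend([v], [u for u in adjacency[v] if u > v],
                          adjacency[v] | {v}, v)


def detect_fragments(rings: Iterable[Ring], graph: nx.Graph | None = None,
                     ring_counts: Iterable[int] = (3, 4, 5)) -> set[Fragment]:
    """Find all cage fragments among ``rings``.

    A fragment is a minimal set of rings, with cardinality in
    ``ring_counts``, in which every covered edge is shared by exactly two
    member rings.  Minimality: no proper subset of ≥3 rings is itself
    closed.  The search walks connected subsets of the ring-adjacency
    graph (rings sharing ≥1 edge), so only rings that touch can combine.

    ``graph`` is accepted for interface symmetry with the ring census; the
    closure condition is purely combinatorial on the rings.
    """
    ring_list = sorted(set(rings))
    allowed = set(ring_counts)
    if not ring_list or not allowed:
        return set()
    max_k = max(allowed)

    # ring adjacency: share at least one edge
    edge_to_rings: dict[frozenset[int], list[int]] = {}
    for i, r in enumerate(ring_list):
        for e in r.edges():
            edge_to_rings.setdefault(e, []).append(i)
    adjacency: dict[int, set[int]] = {i: set() for i in range(len(ring_list))}
    for members in edge_to_rings.values():
        for a, b in combinations(members, 2):
            adjacency[a].add(b)
            adjacency[b].add(a)

    fragments: set[Fragment] = set()
    for subset in _connected_ring_subsets(adjacency, max_k):
        if len(subset) not in allowed:
            continue
        rs = [ring_list[i] for i in subset]
        if not _is_closed(rs):
            continue
        # minimality: no proper closed subset of >= 3 rings
        minimal = True
        for k in range(3, len(rs)):
            if any(_is_closed(c) for c in combinations(rs, k)):
                minimal = False
                break
        if minimal:
            fragments.add(Fragment(frozenset(rs)))
    return fragments


@dataclasses.dataclass(frozen=True)
class RingRole:
    ring: Ring
    role: str  # "body" | "surface"


def classify_ring_roles(cluster_fragments: Iterable[Fragment]) -> set[RingRole]:
    """Label each distinct ring of a cluster's fragments.

    A ring is a *body* ring when it connects two fragments of the cluster
    (appears in at least two of them); every other ring is a *surface*
    ring.
    """
    counts: dict[Ring, int] = {}
    for f in cluster_fragments:
        for r in f.rings:
            counts[r] = counts.get(r, 0) + 1
    return {RingRole(r, "body" if c >= 2 else "surface")
            for r, c in counts.items()}


def fragment_table(fragments: Iterable[Fragment], ring_ids: dict[Ring, int],
                   frame_index: int = 0) -> list[tuple]:
    """Rows ``(frame, fragment_id, signature, ring_ids, molecule_ids)``."""
    rows = []
    for i, f in enumerate(sorted(fragments, key=lambda f: sorted(f.rings))):
        rows.append((frame_index, i,
                     ",".join(map(str, f.signature)),
                     ",".join(str(ring_ids[r]) for r in sorted(f.rings)),
                     ",".join(map(str, sorted(f.molecules)))))
    return rows
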