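"""Cluster transformations between consecutive frames and lifetimes.

Between frames t and t+1 every molecule belongs to a cluster (C), an
isolated ring (R, a ring in no cage fragment) or the debris (m, a lone
molecule in neither).  Entities of the two frames that share molecules
are linked; each connected component of that bipartite overlap graph is
one transformation event, classified into four patterns:

* changeless — one cluster maps to one identical-membership cluster;
* merge      — several reactants (≥1 cluster or ≥1 ring, plus debris)
               fuse into exactly one cluster;
* split      — the mirror image: one cluster breaks up;
* complex    — anything else (simultaneous fusion and fission).

A cluster's lifetime is the number of consecutive frames its exact
molecule membership persists, reported in units of the frame interval Δt.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Mapping, Sequence


@dataclasses.dataclass(frozen=True)
class FrameState:
    """The entity decomposition of one frame for dynamics tracking."""

    clusters: tuple[frozenset[int], ...]
    rings: tuple[frozenset[int], ...] = ()
    debris: frozenset[int] = frozenset()

    @staticmethod
    def build(clusters: Iterable[frozenset[int]],
              isolated_rings: Iterable[frozenset[int]] = (),
              debris: Iterable[int] = ()) -> "FrameState":
        return FrameState(tuple(frozenset(c) for c in clusters),
                          tuple(frozenset(r) for r in isolated_rings),
                          frozenset(debris))

    def entities(self) -> list[tuple[str, frozenset[int]]]:
        out = [("C", c) for c in self.clusters]
        out += [("R", r) for r in self.rings]
        out += [("m", frozenset([x])) for x in sorted(self.debris)]
        return out


@dataclasses.dataclass(frozen=True)
class TransformationEvent:
    """One connected component of the cross-frame overlap graph."""

    reactants: tuple[tuple[str, frozenset[int]], ...]
    products: tuple[tuple[str, frozenset[int]], ...]
    kind: str  # changeless | merge | split | complex

    def multiplicities(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        """((i_c, i_R, i_m), (i'_c, i'_R, i'_m))."""
        def count(side):
            kinds = [k for k, _ in side]
            return (kinds.count("C"), kinds.count("R"), kinds.count("m"))
        return count(self.reactants), count(self.products)

    def conserves_molecules(self) -> bool:
        r = frozenset(m for _, e in self.reactants for m in e)
        p = frozenset(m for _, e in self.products for m in e)
        return r == p


def match_clusters(clusters_t: Sequence[frozenset[int]],
                   clusters_t1: Sequence[frozenset[int]]
                   ) -> dict[tuple[int, int], int]:
    """Molecule-overlap counts between two frames' clusters.

    Returns ``{(i, j): |clusters_t[i] ∩ clusters_t1[j]|}`` for nonzero
    overlaps only.  Connected components of this bipartite map (extended
    with rings and debris) define transformation events.
    """
    by_mol: dict[int, list[int]] = defaultdict(list)
    for j, c in enumerate(clusters_t1):
        for m in c:
            by_mol[m].append(j)
    overlap: dict[tuple[int, int], int] = defaultdict(int)
    for i, c in enumerate(clusters_t):
        for m in c:
            for j in by_mol.get(m, ()):
                overlap[(i, j)] += 1
    return dict(overlap)


def _components(state_t: FrameState, state_t1: FrameState
                ) -> list[tuple[list[tuple[str, frozenset[int]]],
                                list[tuple[str, frozenset[int]]]]]:
    """Connected components of the entity overlap graph (union-find over
    shared molecules)."""
    left = state_t.entities()
    right = state_t1.entities()
    parent = list(range(len(left) + len(right)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    mol_to_left: dict[int, list[int]] = defaultdict(list)
    for i, (_, ent) in enumerate(left):
        for m in ent:
            mol_to_left[m].append(i)
    for j, (_, ent) in enumerate(right):
        for m in ent:
            for i in mol_to_left.get(m, ()):
                union(i, len(left) + j)

    comps: dict[int, tuple[list, list]] = defaultdict(lambda: ([], []))
    for i, e in enumerate(left):
        comps[find(i)][0].append(e)
    for j, e in enumerate(right):
        comps[find(len(left) + j)][1].append(e)
    return [v for v in comps.values() if v[0] or v[1]]


def classify_transformation(reactants: Sequence[tuple[str, frozenset[int]]],
                            products: Sequence[tuple[str, frozenset[int]]]
                            ) -> str:
    """Classify one event into changeless / merge / split / complex."""
    r_kinds = [k for k, _ in reactants]
    p_kinds = [k for k, _ in products]
    r_c, r_r = r_kinds.count("C"), r_kinds.count("R")
    p_c, p_r = p_kinds.count("C"), p_kinds.count("R")
    only_cluster_r = r_c == 1 and len(reactants) == 1
    only_cluster_p = p_c == 1 and len(products) == 1
    if only_cluster_r and only_cluster_p and reactants[0][1] == products[0][1]:
        return "changeless"
    if only_cluster_p and (r_c >= 1 or r_r >= 1):
        return "merge"
    if only_cluster_r and (p_c >= 1 or p_r >= 1):
        return "split"
    return "complex"


def detect_events(state_t: FrameState, state_t1: FrameState
                  ) -> list[TransformationEvent]:
    """All transformation events between two consecutive frames.

    Components that touch no cluster on either side (debris staying
    debris, isolated rings drifting) are still reported, classified as
    complex unless trivial; callers interested only in cluster dynamics
    can filter on the entity kinds.
    """
    events = []
    for reactants, products in _components(state_t, state_t1):
        kind = classify_transformation(reactants, products)
        events.append(TransformationEvent(tuple(reactants), tuple(products), kind))
    return events


@dataclasses.dataclass(frozen=True)
class LifetimeStats:
    """Mean cluster lifetimes per size class (Δt units) and event rates."""

    mean_lifetime: dict  # class name -> mean lifetime in Δt units
    n_tracks: dict       # class name -> number of lifetime tracks
    rates: dict          # event kind -> fraction of events
    n_events: int


DEFAULT_SIZE_CLASSES: dict[str, tuple[int, int]] = {
    "S<10": (1, 9),
    "S>50": (51, 10**9),
}


def lifetime_stats(states: Sequence[FrameState],
                   size_classes: Mapping[str, tuple[int, int]] | None = None,
                   cluster_events_only: bool = True) -> LifetimeStats:
    """Lifetimes and transformation rates over a frame sequence.

    A lifetime is the length of a maximal run of consecutive frames in
    which a cluster with exactly the same molecule membership exists
    (strict membership, no grace frames).  Event rates are tallied over
    all consecutive-frame events; by default only events involving at
    least one cluster are counted.
    """
    if len(states) < 2:
        return LifetimeStats({}, {}, {}, 0)
    classes = dict(size_classes) if size_classes is not None else DEFAULT_SIZE_CLASSES

    # lifetimes: runs of identical membership
    lifetimes: list[tuple[int, int]] = []  # (size, run length in frames)
    active: dict[frozenset[int], int] = {}
    for state in states:
        present = set(state.clusters)
        ended = [c for c in active if c not in present]
        for c in ended:
            lifetimes.append((len(c), active.pop(c)))
        for c in present:
            active[c] = active.get(c, 0) + 1
    lifetimes.extend((len(c), run) for c, run in active.items())

    mean_lt: dict[str, float] = {}
    n_tracks: dict[str, int] = {}
    for name, (lo, hi) in classes.items():
        runs = [run for size, run in lifetimes if lo <= size <= hi]
        n_tracks[name] = len(runs)
        mean_lt[name] = float(sum(runs) / len(runs)) if runs else float("nan")

    counts: dict[str, int] = defaultdict(int)
    total = 0
    for a, b in zip(states[:-1], states[1:]):
        for ev in detect_events(a, b):
            if cluster_events_only and not any(
                    k == "C" for k, _ in ev.reactants + ev.products):
                continue
            counts[ev.kind] += 1
            total += 1
    rates = {k: c / total for k, c in sorted(counts.items())} if total else {}
    return LifetimeStats(mean_lt, n_tracks, rates, total)


def event_table(events: Iterable[TransformationEvent], t: int) -> list[tuple]:
    """Rows ``(t, kind, i_c, i_R, i_m, i'_c, i'_R, i'_m, reactants, products)``."""
    rows = []
    for ev in events:
        (ic, ir, im), (jc, jr, jm) = ev.multiplicities()
        fmt = lambda side: ";".join(
            f"{k}:{','.join(map(str, sorted(e)))}" for k, e in side)
        rows.append((t, ev.kind, ic, ir, im, jc, jr, jm,
                     fmt(ev.reactants), fmt(ev.products)))
    return rows
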