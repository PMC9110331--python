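"""Water clusters as Louvain communities of the fragment network (4th level).

Fragments that share rings form a network (nodes: fragments; edge weight:
number of shared rings).  Water clusters are the modularity-maximizing
Louvain communities of that network, materialized as the union of the
member fragments' molecules.  A cluster's size ``S`` is its molecule
count; molecules in rings shared across community boundaries belong to
both clusters, and global coverage is measured on the union.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .fragments import Fragment
from .frames import WaterFrame
from .rings import Ring


def build_fragment_network(fragments: Iterable[Fragment]) -> nx.Graph:
    """Graph over fragments; edge iff two fragments share ≥1 ring, with
    ``weight`` = number of shared rings."""
    frags = sorted(set(fragments), key=lambda f: sorted(f.rings))
    g = nx.Graph()
    g.add_nodes_from(frags)
    ring_to_frags: dict[Ring, list[Fragment]] = {}
    for f in frags:
        for r in f.rings:
            ring_to_frags.setdefault(r, []).append(f)
    for members in ring_to_frags.values():
        for a, b in combinations(members, 2):
            if g.has_edge(a, b):
                g.edges[a, b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def louvain_partition(network: nx.Graph, seed: int = 0,
                      weighted: bool = True, resolution: float = 1.0
                      ) -> list[set]:
    """Louvain communities of the fragment network.

    Deterministic for a fixed ``seed`` (the seed fixes the node traversal
    order of the heuristic).  An empty network yields an empty partition.
    """
    if network.number_of_nodes() == 0:
        return []
    return [set(c) for c in nx.community.louvain_communities(
        network, weight="weight" if weighted else None,
        resolution=resolution, seed=seed)]


@dataclasses.dataclass(frozen=True)
class WaterCluster:
    """A community of fragments materialized as a molecule set."""

    cluster_id: int
    fragments: frozenset[Fragment]
    energy: float | None = None  # E_S, kJ/mol, filled by energetics stage

    @property
    def molecules(self) -> frozenset[int]:
        return frozenset(m for f in self.fragments for m in f.molecules)

    @property
    def rings(self) -> frozenset[Ring]:
        return frozenset(r for f in self.fragments for r in f.rings)

    @property
    def size(self) -> int:
        """Cluster size S: number of member molecules."""
        return len(self.molecules)

    def with_energy(self, energy: float) -> "WaterCluster":
        return dataclasses.replace(self, energy=energy)


def assemble_clusters(partition: Sequence[set], fragments: Iterable[Fragment]
                      ) -> list[WaterCluster]:
    """Materialize one :class:`WaterCluster` per community.

    Fragments absent from the partition (isolated, if the network was
    built from a subset) become single-fragment clusters.  Cluster ids are
    assigned in decreasing size order for stable reporting.
    """
    fragments = set(fragments)
    covered: set[Fragment] = set()
    groups: list[frozenset[Fragment]] = []
    for comm in partition:
        comm = frozenset(comm)
        if not comm <= fragments:
            raise ValueError("partition contains fragments not in the input set")
        groups.append(comm)
        covered |= comm
    groups.extend(frozenset([f]) for f in fragments - covered)
    groups.sort(key=lambda g: (-len(frozenset(m for f in g for m in f.molecules)),
                               sorted(sorted(r.members) for f in g for r in f.rings)))
    return [WaterCluster(i, g) for i, g in enumerate(groups)]


def coverage_fraction(clusters: Iterable[WaterCluster], frame: WaterFrame) -> float:
    """Fraction of the frame's molecules belonging to at least one cluster."""
    if frame.n_molecules == 0:
        return 0.0
    union: set[int] = set()
    for c in clusters:
        union |= c.molecules
    return len(union) / frame.n_molecules


def fragment_adjacency_stats(clusters: Iterable[WaterCluster]
                             ) -> dict[tuple[tuple[int, ...], tuple[int, ...]], float]:
    """Row-normalized frequency of signature pairs joined by fragment-network
    edges inside clusters.

    For each unordered pair of fragment signatures, counts the
    fragment-network edges (shared-ring adjacencies) within clusters that
    join fragments carrying those signatures, then normalizes each row
    (first signature of the sorted pair) to sum to 1.  Clusters with a
    single fragment contribute nothing; no multi-fragment cluster → empty
    mapping.
    """
    counts: dict[tuple, float] = {}
    for cluster in clusters:
        if len(cluster.fragments) < 2:
            continue
        net = build_fragment_network(cluster.fragments)
        for a, b in net.edges():
            key = tuple(sorted((a.signature, b.signature)))
            counts[key] = counts.get(key, 0.0) + 1.0
    row_totals: dict[tuple, float] = {}
    for (sig_a, _), c in counts.items():
        row_totals[sig_a] = row_totals.get(sig_a, 0.0) + c
    return {k: v / row_totals[k[0]] for k, v in counts.items()}


def debris_molecules(frame: WaterFrame, rings: Iterable[Ring],
                     clusters: Iterable[WaterCluster]) -> frozenset[int]:
    """Molecules in no cluster and no ring — the debris (m_t) the dynamics
    stage tracks.  Molecules of isolated rings are excluded; they enter the
    dynamics through the ring terms instead."""
    covered = {m for r in rings for m in r.members}
    for c in clusters:
        covered |= c.molecules
    return frozenset(range(frame.n_molecules)) - covered


def isolated_rings(rings: Iterable[Ring], fragments: Iterable[Fragment]
                   ) -> frozenset[Ring]:
    """Rings that belong to no fragment (enter dynamics as R_t terms)."""
    in_fragment = {r for f in fragments for r in f.rings}
    return frozenset(rings) - in_fragment


def modularity(network: nx.Graph, partition: Sequence[set],
               weighted: bool = True) -> float:
    """Newman modularity of a partition (delegates to networkx)."""
    return nx.community.modularity(network, partition,
                                   weight="weight" if weighted else None)
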