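"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's algorithms: brute-force
27-image distances, exhaustive simple-cycle enumeration with an SP check,
exhaustive modularity maximization over all set partitions.  Tests compare
the package's spatial-index / DFS / heuristic paths against them.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from aquaclust.rings import canonical_cycle


def brute_force_min_image(p: np.ndarray, q: np.ndarray,
                          box: np.ndarray) -> np.ndarray:
    """Minimum displacement q−p over all 27 periodic images of q."""
    best = None
    best_norm = np.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        d = (q + np.asarray(shift) * box) - p
        n = np.linalg.norm(d)
        if n < best_norm:
            best_norm, best = n, d
    return best


def brute_force_pairs(points: np.ndarray, box: np.ndarray,
                      radius: float) -> set[tuple[int, int]]:
    """All-pairs O(N²) neighbor search using the 27-image distance."""
    out = set()
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            d = np.linalg.norm(brute_force_min_image(points[i], points[j], box))
            if d < radius:
                out.add((i, j))
    return out


def oracle_sp_rings(graph: nx.Graph, max_size: int = 8) -> set[tuple[int, ...]]:
    """SP rings by exhaustive simple-cycle enumeration + all-pairs check."""
    sp = dict(nx.all_pairs_shortest_path_length(graph, cutoff=max_size // 2))
    found = set()
    for cyc in nx.simple_cycles(graph, length_bound=max_size):
        k = len(cyc)
        if k < 3:
            continue
        ok = True
        for a in range(k):
            for b in range(a + 1, k):
                arc = min(b - a, k - (b - a))
                if sp[cyc[a]].get(cyc[b], max_size + 1) < arc:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            found.add(canonical_cycle(cyc))
    return found


def set_partitions(items: list):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(graph: nx.Graph, weighted: bool = True) -> float:
    """Maximum modularity over every partition of the nodes.

    Enumerates all set partitions as restricted growth strings and
    evaluates Newman modularity from the (weighted) adjacency matrix.
    """
    n = graph.number_of_nodes()
    adj = nx.to_numpy_array(graph, weight="weight" if weighted else None)
    deg = adj.sum(1)
    two_m = deg.sum()
    labels = np.zeros(n, dtype=int)
    best = -np.inf

    def rec(i: int, maxl: int):
        nonlocal best
        if i == n:
            k = labels.max() + 1
            member = np.zeros((n, k))
            member[np.arange(n), labels] = 1
            intra = np.einsum("ic,ij,jc->c", member, adj, member)
            dsum = deg @ member
            q = float((intra / two_m - (dsum / two_m) ** 2).sum())
            best = max(best, q)
            return
        for lab in range(maxl + 1):
            labels[i] = lab
            rec(i + 1, max(maxl, lab + 1))

    rec(1, 1)
    return best


@pytest.fixture(scope="session")
def theta_455():
    """The (2,2,3) theta cage: one (4,5,5) fragment of 6 molecules."""
    from aquaclust.synth import CageSpec, build_theta_cage

    return build_theta_cage(CageSpec((2, 2, 3)))


@pytest.fixture(scope="session")
def random_box_200():
    from aquaclust.synth import build_random_box

    return build_random_box(200, density=0.0334, min_separation=2.4, seed=42)
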