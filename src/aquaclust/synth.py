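"""Synthetic water structures with known hydrogen-bond topology.

These generators make every pipeline stage testable without molecular
dynamics output:

* theta cages — two 3-coordinated molecules joined by three hydrogen-
  bonded paths, realizing cage fragments with prescribed ring signatures
  such as (4,5,5) (6 molecules) or (6,7,7) (9 molecules);
* an ice-like lattice (ice-Ih oxygen positions, proton-ordered by an
  Eulerian orientation so every molecule donates exactly two bonds),
  whose ring census contains 6-rings only;
* random packings as a bulk-like negative control;
* power-law size samples and ideal-solid surface samples for estimator
  recovery tests.

All generators are deterministic given their seed.  The geometric
builders verify hard distance margins (bonded O–O well inside the
hydrogen-bond cutoff + 1 Å, non-bonded pairs well outside) so that
hydrogen-bond detection reconstructs the intended graph exactly; they
never consult the detection code itself.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .frames import WaterFrame, minimum_image_displacement, wrap_positions

OH_BOND = 1.0       # covalent O–H placed along the donated bond, Å
HOH_ANGLE = 109.47  # degrees, used for free (non-donating) hydrogens


class GeometryError(RuntimeError):
    """The requested structure could not be embedded within the margins."""


@dataclasses.dataclass(frozen=True)
class CageSpec:
    """A theta cage: three internally disjoint paths joining two poles.

    ``paths`` are the edge counts (p1, p2, p3); the implied ring sizes
    are p1+p2, p1+p3 and p2+p3.  At most one path may be a single edge
    (two direct pole–pole edges would be parallel).
    """

    paths: tuple[int, int, int]
    bond_length: float = 2.8   # Å, target O–O distance along cage edges
    max_ring_size: int = 8

    def __post_init__(self) -> None:
        p = tuple(int(x) for x in self.paths)
        object.__setattr__(self, "paths", p)
        if len(p) != 3 or any(x < 1 for x in p):
            raise ValueError("paths must be three positive edge counts")
        if sum(x == 1 for x in p) > 1:
            raise ValueError("at most one path may be a single edge")
        for a, b in combinations(p, 2):
            if a + b > self.max_ring_size:
                raise ValueError(
                    f"implied ring size {a + b} exceeds max ring size "
                    f"{self.max_ring_size}")

    @property
    def ring_sizes(self) -> tuple[int, int, int]:
        p1, p2, p3 = sorted(self.paths)
        return tuple(sorted((p1 + p2, p1 + p3, p2 + p3)))

    @property
    def n_molecules(self) -> int:
        """Closed form: the 2 poles plus the interior path nodes."""
        return 2 + sum(p - 1 for p in self.paths)

    def is_sp_realizable(self) -> bool:
        """Are all three cycles of the theta graph shortest-path rings?

        The largest cycle (through the two longer paths) survives the SP
        criterion only when no pair of its members has a shortcut through
        the shortest path; for a theta graph this holds exactly when the
        two shortest paths are equally long.  Only such cages appear as
        fragments in an SP-ring census (signatures like (4,5,5), (6,7,7),
        (4,8,8) — the two larger rings always tie).
        """
        g, _ = _theta_graph(self)
        sp = dict(nx.all_pairs_shortest_path_length(g))
        cycles = nx.cycle_basis(g)
        # the three cycles of a theta graph = the 3 pairs of paths; the
        # basis gives 2, their symmetric difference the third
        e1 = set(map(frozenset, zip(cycles[0], cycles[0][1:] + cycles[0][:1])))
        e2 = set(map(frozenset, zip(cycles[1], cycles[1][1:] + cycles[1][:1])))
        third = e1 ^ e2
        all_cycles = [cycles[0], cycles[1], _edges_to_cycle(third)]
        for cyc in all_cycles:
            k = len(cyc)
            for a in range(k):
                for b in range(a + 1, k):
                    arc = min(b - a, k - (b - a))
                    if sp[cyc[a]][cyc[b]] < arc:
                        return False
        return True


def _edges_to_cycle(edges: set[frozenset[int]]) -> list[int]:
    """Order an edge set forming one simple cycle into a vertex sequence."""
    adj: dict[int, list[int]] = {}
    for e in edges:
        u, v = sorted(e)
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    start = min(adj)
    cyc = [start]
    prev = None
    while True:
        nxt = [w for w in adj[cyc[-1]] if w != prev]
        prev = cyc[-1]
        if nxt[0] == start:
            return cyc
        cyc.append(nxt[0])


def _theta_graph(spec: CageSpec) -> tuple[nx.Graph, list[list[int]]]:
    """Node 0 and 1 are the poles; paths hold the node chains pole→pole."""
    g = nx.Graph()
    g.add_nodes_from(range(spec.n_molecules))
    nxt = 2
    chains = []
    for p in spec.paths:
        chain = [0] + list(range(nxt, nxt + p - 1)) + [1]
        nxt += p - 1
        chains.append(chain)
        g.add_edges_from(zip(chain[:-1], chain[1:]))
    return g, chains


def _initial_embedding(spec: CageSpec, chains: Sequence[Sequence[int]]
                       ) -> np.ndarray:
    """Meridional-arc starting layout: poles on the z axis, each path
    bulging outward at azimuth 0°, 120°, 240°."""
    d0 = spec.bond_length
    pmin = min(spec.paths)
    lz = d0 if pmin == 1 else 0.85 * d0 * pmin
    pos = np.zeros((spec.n_molecules, 3))
    pos[1] = (0.0, 0.0, lz)
    for arc, (chain, p) in enumerate(zip(chains, spec.paths)):
        phi = 2.0 * np.pi * arc / 3.0
        # bulge so the arc length roughly matches p bonds
        w = 0.45 * d0 * max(p - lz / d0, 0.5)
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        for k, node in enumerate(chain[1:-1], start=1):
            t = k / p
            pos[node] = u * (w * np.sin(np.pi * t)) + (0.0, 0.0, lz * t)
    return pos


def _refine_embedding(pos: np.ndarray, edges: list[tuple[int, int]],
                      d0: float, nonedge_min: float) -> np.ndarray:
    """Penalty minimization: edges at d0, non-edges pushed beyond margin."""
    n = len(pos)
    non_edges = [(i, j) for i, j in combinations(range(n), 2)
                 if (i, j) not in set(edges) and (j, i) not in set(edges)]
    e = np.array(edges)
    ne = np.array(non_edges) if non_edges else np.empty((0, 2), int)
    target = nonedge_min + 0.4

    def objective(x: np.ndarray) -> float:
        p = x.reshape(n, 3)
        de = np.linalg.norm(p[e[:, 0]] - p[e[:, 1]], axis=1)
        cost = np.sum((de - d0) ** 2)
        if len(ne):
            dn = np.linalg.norm(p[ne[:, 0]] - p[ne[:, 1]], axis=1)
            cost += 4.0 * np.sum(np.maximum(0.0, target - dn) ** 2)
        return float(cost)

    res = minimize(objective, pos.ravel(), method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14})
    return res.x.reshape(n, 3)


def _orient_theta(spec: CageSpec, chains: Sequence[Sequence[int]]
                  ) -> list[tuple[int, int]]:
    """Directed (donor, acceptor) pairs: path 1 runs pole0→pole1, paths
    2 and 3 run pole1→pole0, so no molecule donates more than twice."""
    directed = []
    for arc, chain in enumerate(chains):
        seq = chain if arc == 0 else list(reversed(chain))
        directed.extend(zip(seq[:-1], seq[1:]))
    return directed


def _place_hydrogens(oxy: np.ndarray, directed: list[tuple[int, int]],
                     box: np.ndarray, clash_min: float = 2.6) -> tuple[np.ndarray, np.ndarray]:
    """Donating H 1 Å along each directed bond; remaining hydrogens aimed
    at the direction maximizing clearance from every foreign oxygen."""
    n = len(oxy)
    h_pos: list[list[np.ndarray]] = [[] for _ in range(n)]
    for donor, acc in directed:
        u = minimum_image_displacement(oxy[donor], oxy[acc], box)
        h_pos[donor].append(oxy[donor] + OH_BOND * u / np.linalg.norm(u))
    dirs = _candidate_directions()
    for i in range(n):
        while len(h_pos[i]) < 2:
            others = np.delete(oxy, i, axis=0)
            cands = oxy[i] + OH_BOND * dirs
            d = np.linalg.norm(
                minimum_image_displacement(cands[:, None, :], others[None, :, :],
                                           box), axis=-1).min(axis=1)
            if h_pos[i]:  # keep the two hydrogens apart
                sep = np.linalg.norm(cands - h_pos[i][0], axis=1)
                d = np.where(sep > 1.2, d, -np.inf)
            best = int(np.argmax(d))
            if d[best] < clash_min:
                raise GeometryError(
                    f"cannot place a free hydrogen on molecule {i} with "
                    f"{clash_min} Å clearance (best {d[best]:.2f} Å)")
            h_pos[i].append(cands[best])
    positions = np.vstack([np.vstack(h) for h in h_pos])
    owners = np.repeat(np.arange(n), 2)
    return positions, owners


def _candidate_directions(n: int = 192) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def build_theta_cage(spec: CageSpec, box_lengths: Sequence[float] = (30.0, 30.0, 30.0)
                     ) -> tuple[WaterFrame, set[frozenset[int]]]:
    """Embed a theta cage and return the frame plus its intended bonds.

    The embedding places the poles on the z axis and the three paths on
    meridional arcs, then refines positions by penalty minimization so
    that every intended bond sits near the target length while every
    non-bonded pair clears 3.6 Å.  Hard margins are verified after
    refinement; violation raises :class:`GeometryError`.

    Returns the frame (centred in the box) and the intended hydrogen-bond
    edge set as ``frozenset({i, j})`` pairs.
    """
    box = np.asarray(box_lengths, float)
    graph, chains = _theta_graph(spec)
    edges = list(graph.edges())
    pos = _initial_embedding(spec, chains)
    pos = _refine_embedding(pos, edges, spec.bond_length, nonedge_min=3.6)
    extent = pos.max(axis=0) - pos.min(axis=0)
    if np.any(extent + 7.0 > box):
        raise GeometryError(f"box {box} too small for cage extent {extent}")
    pos = pos - pos.mean(axis=0) + box / 2.0

    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    for i, j in edges:
        if not (spec.bond_length - 0.61 < d[i, j] < 3.4):
            raise GeometryError(f"edge ({i},{j}) length {d[i, j]:.2f} Å out of "
                                "bond margin")
    adj = {frozenset(e) for e in edges}
    for i, j in combinations(range(len(pos)), 2):
        if frozenset((i, j)) not in adj and d[i, j] < 3.6:
            raise GeometryError(f"spurious contact ({i},{j}) at {d[i, j]:.2f} Å")

    directed = _orient_theta(spec, chains)
    h_pos, owners = _place_hydrogens(pos, directed, box)
    frame = WaterFrame(pos, h_pos, owners, box)
    return frame, adj


# ---------------------------------------------------------------------------
# ice lattice

ICE_OO = 2.75  # Å nearest-neighbour O–O distance


def build_hexagonal_lattice(repeats: tuple[int, int, int] = (2, 2, 2),
                            oo_distance: float = ICE_OO
                            ) -> WaterFrame:
    """Proton-ordered ice-Ih-like lattice in an orthorhombic cell.

    Oxygens sit on the hexagonal-diamond (lonsdaleite) lattice, 8 per
    orthorhombic cell; every molecule is 4-coordinated and the ring
    census of the hydrogen-bond graph contains 6-rings only.  Hydrogens
    are assigned by orienting the 4-regular bond graph along an Eulerian
    circuit, which gives every molecule exactly two donated bonds (the
    ice rules).

    ``repeats`` must keep every box length above 6 Å so periodic bond
    detection is unambiguous.
    """
    nx_, ny_, nz_ = (int(r) for r in repeats)
    if min(nx_, ny_, nz_) < 1:
        raise ValueError("repeats must be >= 1")
    r = float(oo_distance)
    a = r * np.sqrt(8.0 / 3.0)
    c = 8.0 * r / 3.0
    cell = np.array([a, a * np.sqrt(3.0), c])
    box = cell * np.array([nx_, ny_, nz_], float)
    if box.min() <= 6.0:
        raise ValueError(f"box {box} too small for periodic bond detection; "
                         "increase repeats")
    # wurtzite fractional positions in the hexagonal basis
    hex_frac = [(1 / 3, 2 / 3, 0.0), (2 / 3, 1 / 3, 0.5),
                (1 / 3, 2 / 3, 3 / 8), (2 / 3, 1 / 3, 7 / 8)]
    a1 = np.array([a, 0.0, 0.0])
    a2 = np.array([-a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0])
    base = []
    for fx, fy, fz in hex_frac:
        cart = fx * a1 + fy * a2 + np.array([0.0, 0.0, fz * c])
        for shift in (0, 1):  # the orthorhombic cell spans two hexagonal cells
            base.append(cart + shift * a2)
    base = np.mod(np.asarray(base), cell)
    offsets = np.array([(i, j, k) for i in range(nx_) for j in range(ny_)
                        for k in range(nz_)], float) * cell
    oxy = (base[None, :, :] + offsets[:, None, :]).reshape(-1, 3)

    tree = cKDTree(wrap_positions(oxy, box), boxsize=box)
    pairs = tree.query_pairs(1.1 * r, output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(len(oxy)))
    g.add_edges_from(map(tuple, pairs))
    degrees = dict(g.degree())
    if set(degrees.values()) != {4}:
        raise GeometryError("ice lattice is not 4-regular; repeats too small")
    directed: list[tuple[int, int]] = []
    donations = np.zeros(len(oxy), int)
    for u, v in nx.eulerian_circuit(g):
        directed.append((u, v))
        donations[u] += 1
    if donations.max() > 2:
        raise GeometryError("Eulerian orientation failed to satisfy ice rules")
    h_pos, owners = _place_hydrogens(oxy, directed, box)
    return WaterFrame(oxy, h_pos, owners, box)


def build_cubic_ice(repeats: tuple[int, int, int] = (3, 3, 3),
                    oo_distance: float = ICE_OO) -> WaterFrame:
    """Proton-ordered cubic-ice (ice Ic, diamond-topology) lattice.

    The SP-ring census of the diamond network contains 6-rings only,
    making this the reference fixture for an all-hexagon census; the
    hexagonal (ice-Ih) lattice additionally carries shortcut-free 8-rings
    across its eclipsed bonds.  ``repeats`` below 3 in any direction
    admit cycles winding around the periodic box and are rejected.
    """
    nx_, ny_, nz_ = (int(r) for r in repeats)
    if min(nx_, ny_, nz_) < 3:
        raise ValueError("cubic ice needs repeats >= 3 per direction (smaller "
                         "boxes admit rings winding around the boundary)")
    a = 4.0 * float(oo_distance) / np.sqrt(3.0)
    cell = np.full(3, a)
    box = cell * np.array([nx_, ny_, nz_], float)
    basis = np.array([[0, 0, 0], [0, .5, .5], [.5, 0, .5], [.5, .5, 0],
                      [.25, .25, .25], [.25, .75, .75],
                      [.75, .25, .75], [.75, .75, .25]]) * a
    offsets = np.array([(i, j, k) for i in range(nx_) for j in range(ny_)
                        for k in range(nz_)], float) * cell
    oxy = (basis[None, :, :] + offsets[:, None, :]).reshape(-1, 3)

    tree = cKDTree(wrap_positions(oxy, box), boxsize=box)
    pairs = tree.query_pairs(1.1 * float(oo_distance), output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(len(oxy)))
    g.add_edges_from(map(tuple, pairs))
    if set(dict(g.degree()).values()) != {4}:
        raise GeometryError("cubic ice lattice is not 4-regular")
    directed: list[tuple[int, int]] = []
    donations = np.zeros(len(oxy), int)
    for u, v in nx.eulerian_circuit(g):
        directed.append((u, v))
        donations[u] += 1
    if donations.max() > 2:
        raise GeometryError("Eulerian orientation failed to satisfy ice rules")
    h_pos, owners = _place_hydrogens(oxy, directed, box)
    return WaterFrame(oxy, h_pos, owners, box)


# ---------------------------------------------------------------------------
# random packing

def build_random_box(n_molecules: int, density: float = 0.0334,
                     min_separation: float = 2.5, seed: int = 0,
                     max_attempts: int = 200) -> WaterFrame:
    """Seeded random packing at a target number density (molecules/Å³).

    Oxygen positions are drawn uniformly and rejected below
    ``min_separation`` (minimum image); hydrogens get random rigid-water
    orientations (O–H 1 Å, H–O–H 109.47°).  Raises after ``max_attempts``
    passes without placing all molecules.
    """
    if n_molecules < 1 or density <= 0:
        raise ValueError("need n_molecules >= 1 and density > 0")
    edge = (n_molecules / density) ** (1.0 / 3.0)
    box = np.full(3, edge)
    if min_separation > edge / 2:
        raise ValueError("min_separation exceeds half the box edge")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_molecules:
        attempts += 1
        if attempts > max_attempts * n_molecules:
            raise GeometryError(
                f"packing failed: placed {len(placed)}/{n_molecules} after "
                f"{attempts} attempts")
        cand = rng.random(3) * box
        if placed:
            d = np.linalg.norm(minimum_image_displacement(
                cand, np.asarray(placed), box), axis=-1)
            if d.min() < min_separation:
                continue
        placed.append(cand)
    oxy = np.asarray(placed)

    half = np.deg2rad(HOH_ANGLE) / 2.0
    h_local = OH_BOND * np.array([[np.sin(half), 0.0, np.cos(half)],
                                  [-np.sin(half), 0.0, np.cos(half)]])
    h_pos = np.empty((2 * n_molecules, 3))
    for i in range(n_molecules):
        rot = _random_rotation(rng)
        h_pos[2 * i] = oxy[i] + h_local[0] @ rot.T
        h_pos[2 * i + 1] = oxy[i] + h_local[1] @ rot.T
    owners = np.repeat(np.arange(n_molecules), 2)
    return WaterFrame(oxy, h_pos, owners, box)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


# ---------------------------------------------------------------------------
# statistical generators

def sample_cluster_sizes(exponent: float, s_min: int, n: int, seed: int = 0,
                         s_max_factor: int = 10**5) -> np.ndarray:
    """``n`` i.i.d. sizes from the discrete power law P(S) ∝ S^(−τ), S ≥ s_min.

    The support is truncated at ``s_min * s_max_factor``; for τ ≥ 2 the
    discarded tail mass is below 1e-5 of the distribution.
    """
    if exponent <= 1:
        raise ValueError("power-law exponent must exceed 1 (normalizable)")
    if s_min < 1:
        raise ValueError("s_min must be >= 1")
    if n == 0:
        return np.empty(0, dtype=int)
    support = np.arange(s_min, s_min * s_max_factor + 1, dtype=float)
    weights = (support / s_min) ** (-exponent)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    return support[np.searchsorted(cdf, rng.random(n))].astype(int)


_TET_VERTS = np.array([(1.0, 1.0, 1.0), (1.0, -1.0, -1.0),
                       (-1.0, 1.0, -1.0), (-1.0, -1.0, 1.0)])


def sample_solid_surface(solid: str, size: float, n_points: int, seed: int = 0
                         ) -> np.ndarray:
    """Uniform (area-weighted) samples of an ideal solid's surface.

    ``size`` is the radius for a sphere and the edge length for a cube or
    regular tetrahedron, all centred at the origin.
    """
    if n_points < 4:
        raise ValueError("need at least 4 surface points")
    rng = np.random.default_rng(seed)
    if solid == "sphere":
        v = rng.normal(size=(n_points, 3))
        return size * v / np.linalg.norm(v, axis=1, keepdims=True)
    if solid == "cube":
        face = rng.integers(0, 6, n_points)
        uv = (rng.random((n_points, 2)) - 0.5) * size
        pts = np.empty((n_points, 3))
        axis = face // 2
        sign = np.where(face % 2 == 0, 0.5, -0.5) * size
        for k in range(3):
            m = axis == k
            pts[m, k] = sign[m]
            pts[m, (k + 1) % 3] = uv[m, 0]
            pts[m, (k + 2) % 3] = uv[m, 1]
        return pts
    if solid == "tetrahedron":
        verts = _TET_VERTS * (size / (2.0 * np.sqrt(2.0)))
        faces = list(combinations(range(4), 3))
        which = rng.integers(0, 4, n_points)
        u, v = rng.random(n_points), rng.random(n_points)
        flip = u + v > 1
        u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
        tri = np.array([verts[list(f)] for f in faces])[which]
        return (tri[:, 0] + u[:, None] * (tri[:, 1] - tri[:, 0])
                + v[:, None] * (tri[:, 2] - tri[:, 0]))
    raise ValueError(f"unknown solid {solid!r}; expected sphere, cube or "
                     "tetrahedron")
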