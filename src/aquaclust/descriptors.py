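"""Local-structure descriptors: LSI, probe-sphere density profiles, RDFs.

The local structure index (LSI) measures how cleanly the gap opens
between a molecule's first coordination shell and the rest: with the
neighbour distances ordered r_1 < r_2 < … < r_n < cutoff < r_{n+1}
(cutoff 3.7 Å) and gaps Δ(i) = r_{i+1} − r_i,

    LSI = (1/n) Σ_{i=1..n} (Δ(i) − Δ̄)²   [Å²].

High LSI marks tetrahedral, low-density-like environments; low LSI a
disordered, high-density-like first shell.

The density probe counts oxygens inside a 4.6 Å sphere; profiles bin the
probes by distance from the cluster's geometric center.  RDFs are the
standard pair-distance histograms normalized by ideal-gas shell counts.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .frames import WaterFrame, wrap_positions
from .morphology import unwrap_cluster

M_O = 15.999
M_H = 1.008


@dataclasses.dataclass(frozen=True)
class LSIResult:
    value: float                      # Å²
    shell_distances: tuple[float, ...]  # r_1..r_{n+1}, Å
    gaps: tuple[float, ...]           # Δ(1)..Δ(n), Å
    mean_gap: float                   # Δ̄, Å
    shell_count: int                  # n


def lsi(frame: WaterFrame, molecule: int, shell_cutoff: float = 3.7
        ) -> LSIResult | None:
    """Local structure index of one molecule.

    Returns ``None`` (undefined; excluded from averages) when no
    neighbour lies inside the shell cutoff or none lies beyond it.
    """
    box = frame.box_lengths
    pos = wrap_positions(frame.oxygen_positions, box)
    d = pos - pos[molecule]
    d -= box * np.round(d / box)
    r = np.sort(np.linalg.norm(np.delete(d, molecule, axis=0), axis=1))
    n = int(np.searchsorted(r, shell_cutoff))  # neighbours with r < cutoff
    if n == 0 or n >= len(r):
        return None
    shell = r[:n + 1]
    gaps = np.diff(shell)
    mean_gap = float(gaps.mean())
    value = float(np.mean((gaps - mean_gap) ** 2))
    return LSIResult(value, tuple(map(float, shell)), tuple(map(float, gaps)),
                     mean_gap, n)


def cluster_center(frame: WaterFrame, molecules: Iterable[int],
                   graph: nx.Graph, mode: str = "geometric") -> np.ndarray:
    """Center of an unwrapped cluster.

    ``geometric``: unweighted mean of oxygen positions.  ``mass``: center
    of mass over all nine atoms per three molecules (O and both H).
    """
    mols = sorted(set(int(m) for m in molecules))
    oxy = unwrap_cluster(frame, mols, graph)
    if mode == "geometric":
        return oxy.mean(axis=0)
    if mode != "mass":
        raise ValueError(f"unknown center mode {mode!r}")
    box = frame.box_lengths
    total = np.zeros(3)
    mass = 0.0
    for k, m in enumerate(mols):
        total += M_O * oxy[k]
        for h in frame.hydrogens_of(m):
            d = frame.hydrogen_positions[h] - frame.oxygen_positions[m]
            d -= box * np.round(d / box)
            total += M_H * (oxy[k] + d)
        mass += M_O + 2 * M_H
    return total / mass


@dataclasses.dataclass(frozen=True)
class DensityProfile:
    bin_centers: np.ndarray   # distance from cluster center, Å
    density: np.ndarray       # molecules/Å³ per bin (NaN where no probe)
    probe_radius: float       # Å


def local_density_profile(frame: WaterFrame, molecules: Iterable[int],
                          graph: nx.Graph, probe_radius: float = 4.6,
                          bin_width: float = 0.5, r_max: float | None = None,
                          probe_mode: str = "atoms") -> DensityProfile:
    """Radial profile of probe-sphere local density around a cluster.

    Probes are the cluster's own oxygen atoms (``probe_mode="atoms"``,
    matching where structure actually is) or points laid on deterministic
    spherical shells around the center (``"radial"``).  Each probe counts
    the *other* oxygens of the whole frame within ``probe_radius`` under
    minimum image; ρ_local = count / probe volume, averaged per distance
    bin from the cluster's geometric center.
    """
    box = frame.box_lengths
    if probe_radius > box.min() / 2:
        raise ValueError("probe radius exceeds min(box)/2")
    mols = sorted(set(int(m) for m in molecules))
    center = cluster_center(frame, mols, graph, "geometric")
    oxy_unwrapped = unwrap_cluster(frame, mols, graph)
    tree = cKDTree(wrap_positions(frame.oxygen_positions, box), boxsize=box)
    sphere_volume = 4.0 / 3.0 * np.pi * probe_radius**3

    if probe_mode == "atoms":
        probes = oxy_unwrapped
        self_count = 1  # the probe-center molecule itself is not counted
    elif probe_mode == "radial":
        if r_max is None:
            r_max = float(np.linalg.norm(oxy_unwrapped - center, axis=1).max())
        shells = np.arange(bin_width / 2, r_max + bin_width / 2, bin_width)
        dirs = _fibonacci_sphere(64)
        probes = (center[None, None, :]
                  + shells[:, None, None] * dirs[None, :, :]).reshape(-1, 3)
        self_count = 0
    else:
        raise ValueError(f"unknown probe mode {probe_mode!r}")

    counts = np.array([len(c) for c in tree.query_ball_point(
        wrap_positions(probes, box), probe_radius)]) - self_count
    dist = np.linalg.norm(probes - center, axis=1)
    if r_max is None:
        r_max = float(dist.max()) + bin_width
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = np.full(len(centers), np.nan)
    idx = np.digitize(dist, edges) - 1
    for b in range(len(centers)):
        mask = idx == b
        if np.any(mask):
            density[b] = counts[mask].mean() / sphere_volume
    return DensityProfile(centers, density, probe_radius)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform directions on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


@dataclasses.dataclass(frozen=True)
class RDFCurve:
    r: np.ndarray    # bin centers, Å
    g: np.ndarray    # dimensionless
    label: str = ""


def rdf(points_a: np.ndarray, points_b: np.ndarray | None,
        box_lengths: np.ndarray, r_max: float, bin_width: float = 0.1,
        label: str = "") -> RDFCurve:
    """Radial distribution function between two point selections.

    ``points_b=None`` gives the self-RDF of ``points_a``.  Distances use
    the minimum image; normalization is by ideal-gas shell counts at the
    partner selection's number density, so g → 1 at large r for
    homogeneous selections.  ``r_max`` may not exceed half the shortest
    box length.
    """
    box = np.asarray(box_lengths, float)
    if r_max > box.min() / 2:
        raise ValueError("r_max exceeds min(box)/2")
    a = wrap_positions(np.atleast_2d(points_a), box)
    same = points_b is None
    b = a if same else wrap_positions(np.atleast_2d(points_b), box)
    if len(a) == 0 or len(b) == 0 or (same and len(a) < 2):
        raise ValueError("RDF needs a non-empty selection (≥ 2 points for self-RDF)")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    tree_a = cKDTree(a, boxsize=box)
    tree_b = tree_a if same else cKDTree(b, boxsize=box)
    cum = tree_a.count_neighbors(tree_b, edges)  # ordered pairs with d <= edge
    counts = np.diff(cum).astype(float)
    if same:
        # remove self pairs (distance 0) counted in the first bin
        counts[0] -= len(a)
    volume = float(np.prod(box))
    rho_b = (len(b) - (1 if same else 0)) / volume
    shell = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    g = counts / (len(a) * rho_b * shell)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(centers, g, label)
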