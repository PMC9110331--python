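"""Cluster morphology: alpha-shape volume/area, diameters, and scaling fits.

Cluster geometry is computed in real space: a cluster is first unwrapped
across the periodic boundary (breadth-first from an arbitrary member,
placing every neighbour at its minimum-image position relative to its
parent), then its oxygen positions feed the alpha shape.

The alpha shape is the classical alpha complex: the subset of Delaunay
tetrahedra whose circumradius does not exceed the alpha radius.  Volume
is the summed tetrahedron volume and surface area the summed area of
boundary facets (facets belonging to exactly one retained tetrahedron).
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.spatial.distance import pdist

from .frames import WaterFrame, minimum_image_displacement


class UndefinedShapeError(ValueError):
    """Fewer than 4 points, or a degenerate (coplanar) configuration."""


@dataclasses.dataclass(frozen=True)
class ClusterShape:
    """Alpha-shape volume/area and maximum diameter of one cluster."""

    volume: float        # Å³ (NaN when undefined)
    area: float          # Å² (NaN when undefined)
    max_diameter: float  # Å
    alpha_radius: float  # Å

    @property
    def radius(self) -> float:
        """Cluster radius r = L/2."""
        return self.max_diameter / 2.0


@dataclasses.dataclass(frozen=True)
class ScalingFitResult:
    """A least-squares line on log-transformed data."""

    slope: float
    intercept: float
    n_points: int
    x_range: tuple[float, float]
    residual_rms: float


def unwrap_cluster(frame: WaterFrame, molecules: Iterable[int],
                   graph: nx.Graph) -> np.ndarray:
    """Real-space oxygen coordinates of a cluster, continuous across the
    periodic boundary.

    BFS over the hydrogen-bond graph restricted to the cluster; each
    newly reached molecule is placed at its minimum-image position
    relative to its BFS parent.  Disconnected components (possible only
    for ad-hoc molecule sets) are each unwrapped internally and placed by
    minimum image of their root relative to the first root.
    """
    mols = sorted(set(int(m) for m in molecules))
    box = frame.box_lengths
    placed: dict[int, np.ndarray] = {}
    remaining = set(mols)
    anchor: np.ndarray | None = None
    while remaining:
        root = min(remaining)
        root_pos = frame.oxygen_positions[root]
        if anchor is None:
            placed[root] = root_pos.astype(float)
            anchor = placed[root]
        else:
            placed[root] = anchor + minimum_image_displacement(anchor, root_pos, box)
        remaining.discard(root)
        queue = deque([root])
        while queue:
            u = queue.popleft()
            for v in graph[u] if u in graph else ():
                if v in remaining:
                    placed[v] = placed[u] + minimum_image_displacement(
                        placed[u], frame.oxygen_positions[v], box)
                    remaining.discard(v)
                    queue.append(v)
    return np.array([placed[m] for m in mols])


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra (vectorized).

    Solves ``2 (v_i - v_0) · c = |v_i|² - |v_0|²`` for the circumcenter c.
    Degenerate (flat) tetrahedra get radius +inf so they are never kept.
    """
    v = points[simplices]            # (m, 4, 3)
    a = 2.0 * (v[:, 1:] - v[:, :1])  # (m, 3, 3)
    sq = np.einsum("mij,mij->mi", v, v)
    b = sq[:, 1:] - sq[:, :1]
    det = np.linalg.det(a)
    radii = np.full(len(simplices), np.inf)
    ok = np.abs(det) > 1e-12
    if np.any(ok):
        centers = np.linalg.solve(a[ok], b[ok][..., None])[..., 0]
        radii[ok] = np.linalg.norm(centers - v[ok, 0], axis=1)
    return radii


def _tet_volumes(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    v = points[simplices]
    return np.abs(np.linalg.det(v[:, 1:] - v[:, :1])) / 6.0


def _triangle_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def alpha_shape_metrics(points: np.ndarray, alpha_radius: float = 3.5
                        ) -> tuple[float, float]:
    """Volume and surface area of the alpha shape of a 3D point set.

    Tetrahedra of the Delaunay triangulation with circumradius ≤
    ``alpha_radius`` (within a small relative tolerance, so exactly
    co-spherical inputs behave like the limiting case) form the complex;
    its boundary facets give the area.

    Raises
    ------
    UndefinedShapeError
        For fewer than 4 points or degenerate configurations.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise UndefinedShapeError(f"alpha shape needs ≥ 4 points, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise UndefinedShapeError(f"degenerate point set: {exc}") from exc
    radii = _circumradii(pts, tri.simplices)
    keep = radii <= alpha_radius * (1.0 + 1e-9)
    if not np.any(keep):
        return 0.0, 0.0
    kept = tri.simplices[keep]
    volume = float(_tet_volumes(pts, kept).sum())
    # boundary facets: faces used by exactly one retained tetrahedron
    faces = np.sort(np.concatenate([kept[:, [0, 1, 2]], kept[:, [0, 1, 3]],
                                    kept[:, [0, 2, 3]], kept[:, [1, 2, 3]]]), axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    area = float(_triangle_areas(pts, boundary).sum())
    return volume, area


def max_diameter(points: np.ndarray) -> float:
    """Longest pairwise distance of a point set (0 for a single point)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 400:
        try:  # the diameter is realized by hull vertices
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    return float(pdist(pts).max())


def cluster_shape(frame: WaterFrame, molecules: Iterable[int],
                  graph: nx.Graph, alpha_radius: float = 3.5) -> ClusterShape:
    """Unwrap a cluster and measure its alpha-shape V, A and diameter L.

    Clusters too small or too flat for a 3D alpha shape are reported with
    ``V = A = NaN`` but a valid diameter.
    """
    pts = unwrap_cluster(frame, molecules, graph)
    diam = max_diameter(pts)
    try:
        v, a = alpha_shape_metrics(pts, alpha_radius)
    except UndefinedShapeError:
        v = a = float("nan")
    return ClusterShape(v, a, diam, alpha_radius)


_SHAPE_FACTORS = {
    # intercept b of lnA = (2/3) lnV + b for the ideal solid
    "sphere": float(np.log(4 * np.pi) - (2 / 3) * np.log(4 * np.pi / 3)),
    "cube": float(np.log(6.0)),
    "tetrahedron": float(np.log(np.sqrt(3.0)) + (2 / 3) * np.log(6 * np.sqrt(2.0))),
}


def shape_factor_reference(solid: str) -> float:
    """Analytic shape factor b of ``lnA = (2/3) lnV + b``.

    sphere ≈ 1.58, cube ≈ 1.79, regular tetrahedron ≈ 1.97 — rounder
    shapes have smaller b.
    """
    try:
        return _SHAPE_FACTORS[solid]
    except KeyError:
        raise ValueError(f"unknown solid {solid!r}; expected one of "
                         f"{sorted(_SHAPE_FACTORS)}") from None


def _linefit(x: np.ndarray, y: np.ndarray) -> ScalingFitResult:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return ScalingFitResult(float(slope), float(intercept), len(x),
                            (float(x.min()), float(x.max())),
                            float(np.sqrt(np.mean(resid**2))))


def surface_volume_fit(shapes: Sequence[ClusterShape], split_volume: float = 100.0
                       ) -> dict[str, ScalingFitResult | None]:
    """Fit ``lnA = a lnV + b`` separately for small (V < split) and large
    (V ≥ split) clusters.  A regime with < 3 clusters is skipped (None)."""
    v = np.array([s.volume for s in shapes])
    a = np.array([s.area for s in shapes])
    good = np.isfinite(v) & np.isfinite(a) & (v > 0) & (a > 0)
    v, a = v[good], a[good]
    out: dict[str, ScalingFitResult | None] = {}
    for name, mask in (("small", v < split_volume), ("large", v >= split_volume)):
        if mask.sum() < 3 or len(np.unique(v[mask])) < 2:
            out[name] = None
        else:
            out[name] = _linefit(np.log(v[mask]), np.log(a[mask]))
    return out


def fixed_slope_intercept(volumes: Sequence[float], areas: Sequence[float],
                          slope: float = 2.0 / 3.0) -> float:
    """Least-squares intercept of ``lnA = slope·lnV + b`` with the slope
    held fixed — the shape-factor estimate for a family of solids."""
    v = np.asarray(volumes, float)
    a = np.asarray(areas, float)
    return float(np.mean(np.log(a) - slope * np.log(v)))


def radius_scaling_fit(shapes: Sequence[ClusterShape]
                       ) -> tuple[ScalingFitResult, ScalingFitResult]:
    """Log–log slopes d_V (volume vs radius) and d_S (area vs radius)."""
    v = np.array([s.volume for s in shapes])
    a = np.array([s.area for s in shapes])
    r = np.array([s.radius for s in shapes])
    good = np.isfinite(v) & np.isfinite(a) & (v > 0) & (a > 0) & (r > 0)
    if good.sum() < 3 or len(np.unique(r[good])) < 2:
        raise ValueError("radius scaling fit needs ≥ 3 shapes with distinct r > 0")
    return (_linefit(np.log(r[good]), np.log(v[good])),
            _linefit(np.log(r[good]), np.log(a[good])))


def powerlaw_exponent(n_s: Mapping[int, int] | Sequence[int],
                      fit_min_size: int = 1, n_bins: int = 20,
                      method: str = "least-squares") -> float:
    """Exponent τ of a power-law size distribution ``n_S ~ S^(−τ)``.

    Parameters
    ----------
    n_s
        Histogram mapping size → count (or an array indexed by size).
    fit_min_size
        Smallest size included in the fit.
    method
        ``least-squares`` (default): slope of log density vs log size on
        logarithmically binned counts.  ``mle``: continuous-Pareto
        maximum-likelihood estimate.
    """
    if isinstance(n_s, Mapping):
        sizes = np.array(sorted(s for s in n_s if s >= fit_min_size and n_s[s] > 0))
        counts = np.array([n_s[s] for s in sizes], dtype=float)
    else:
        arr = np.asarray(n_s, dtype=float)
        sizes = np.flatnonzero(arr > 0)
        keep = sizes >= fit_min_size
        sizes, counts = sizes[keep], arr[sizes[keep]]
    if len(sizes) < 3:
        raise ValueError("power-law fit needs ≥ 3 occupied sizes above fit_min_size")
    if method == "mle":
        n = counts.sum()
        return float(1.0 + n / np.sum(counts * np.log(sizes / (fit_min_size - 0.5))))
    if method != "least-squares":
        raise ValueError(f"unknown method {method!r}")
    lo, hi = sizes.min(), sizes.max() + 1
    edges = np.unique(np.round(np.geomspace(lo, hi, n_bins + 1)).astype(int))
    if len(edges) < 4:
        raise ValueError("insufficient size support for log binning")
    idx = np.digitize(sizes, edges) - 1
    xs, ys = [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not np.any(mask):
            continue
        width = edges[b + 1] - edges[b]
        density = counts[mask].sum() / width
        center = np.sqrt(edges[b] * (edges[b + 1] - 1))
        xs.append(np.log(center))
        ys.append(np.log(density))
    if len(xs) < 3:
        raise ValueError("insufficient occupied bins for power-law fit")
    slope, _ = np.polyfit(xs, ys, 1)
    return float(-slope)


@dataclasses.dataclass(frozen=True)
class Crossing:
    """One sign change between two distributions on a common grid."""

    bracket: tuple[float, float]  # grid points left/right of the crossing
    location: float               # linear interpolation inside the bracket


def distribution_crossing(grid: Sequence[float], dist_low: Sequence[float],
                          dist_high: Sequence[float], smooth_window: int = 5
                          ) -> list[Crossing]:
    """Locate isosbestic points: where two distributions cross.

    Both distributions are smoothed with a centered moving average
    (``smooth_window`` bins) before sign-change detection on their
    difference; zero stretches are ignored.  Identical distributions, or
    ones differing by a constant factor, yield no crossings.
    """
    grid = np.asarray(grid, float)
    d = np.asarray(dist_low, float) - np.asarray(dist_high, float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        d = np.convolve(d, kernel, mode="same")
    sign = np.sign(d)
    nz = np.flatnonzero(sign != 0)
    crossings: list[Crossing] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] != sign[b]:
            t = d[a] / (d[a] - d[b])
            crossings.append(Crossing((float(grid[a]), float(grid[b])),
                                      float(grid[a] + t * (grid[b] - grid[a]))))
    return crossings
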