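"""Coordinate frames, periodic-box geometry, and trajectory I/O.

A :class:`WaterFrame` holds one configuration of a rigid-water system:
oxygen and hydrogen positions in an orthorhombic periodic box, with every
hydrogen assigned to its covalent oxygen.  All other analysis stages
(hydrogen-bond detection, ring census, cage fragments, cluster morphology)
consume this container.

Units are Å for lengths and fs for times throughout the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree


class FrameError(ValueError):
    """Malformed coordinate input (parse, composition or assignment)."""


@dataclasses.dataclass(frozen=True)
class TrajectorySettings:
    """All tunable thresholds of the analysis pipeline.

    Parameters
    ----------
    frame_interval
        Spacing between stored configurations, fs.
    hb_cutoff
        Intermolecular O···H distance below which two molecules are
        hydrogen bonded (strict ``<``), Å.
    max_ring_size
        Largest shortest-path ring enumerated.
    fragment_ring_counts
        Admissible number of rings in a closed cage fragment.
    alpha_radius
        Alpha-shape circumradius threshold for cluster volume/area, Å.
    probe_radius
        Probe-sphere radius for local-density profiles, Å.
    lsi_shell_cutoff
        First-shell boundary of the local structure index, Å.
    energy_cutoff
        O–O truncation of the pair interaction energy, Å.
    rng_seed
        Seed forwarded to every stochastic step (Louvain node order,
        synthetic generators).
    """

    frame_interval: float = 10.0
    hb_cutoff: float = 2.5
    max_ring_size: int = 8
    fragment_ring_counts: frozenset[int] = frozenset({3, 4, 5})
    alpha_radius: float = 3.5
    probe_radius: float = 4.6
    lsi_shell_cutoff: float = 3.7
    energy_cutoff: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_interval", "hb_cutoff", "alpha_radius",
                     "probe_radius", "lsi_shell_cutoff", "energy_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_ring_size < 3:
            raise ValueError("max_ring_size must be >= 3")
        object.__setattr__(self, "fragment_ring_counts",
                           frozenset(self.fragment_ring_counts))


@dataclasses.dataclass
class WaterFrame:
    """One configuration of water molecules in an orthorhombic periodic box.

    ``hydrogen_owner[h]`` is the molecule (oxygen) index owning hydrogen
    ``h``; exactly two hydrogens map to each oxygen.  Coordinates are kept
    as given (possibly outside the box); wrapping is applied only inside
    geometry operations.
    """

    oxygen_positions: np.ndarray          # (N, 3) Å
    hydrogen_positions: np.ndarray        # (2N, 3) Å
    hydrogen_owner: np.ndarray            # (2N,) int
    box_lengths: np.ndarray               # (3,) Å
    frame_index: int = 0
    frame_time: float = 0.0               # fs

    def __post_init__(self) -> None:
        self.oxygen_positions = np.asarray(self.oxygen_positions, dtype=float)
        self.hydrogen_positions = np.asarray(self.hydrogen_positions, dtype=float)
        self.hydrogen_owner = np.asarray(self.hydrogen_owner, dtype=int)
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.box_lengths.shape != (3,) or not np.all(self.box_lengths > 0):
            raise FrameError("box must be three positive lengths")
        if not (np.isfinite(self.oxygen_positions).all()
                and np.isfinite(self.hydrogen_positions).all()):
            raise FrameError("coordinates must be finite")
        n = len(self.oxygen_positions)
        if len(self.hydrogen_positions) != 2 * n:
            raise FrameError(
                f"composition error: {len(self.hydrogen_positions)} hydrogens "
                f"for {n} oxygens (expected {2 * n})")
        counts = np.bincount(self.hydrogen_owner, minlength=n)
        if n and not np.all(counts == 2):
            bad = int(np.flatnonzero(counts != 2)[0])
            raise FrameError(f"molecule {bad} owns {counts[bad]} hydrogens, expected 2")

    @property
    def n_molecules(self) -> int:
        return len(self.oxygen_positions)

    def hydrogens_of(self, mol: int) -> np.ndarray:
        """Indices of the two hydrogens covalently bound to molecule ``mol``."""
        return np.flatnonzero(self.hydrogen_owner == mol)


def minimum_image_displacement(p: np.ndarray, q: np.ndarray,
                               box_lengths: np.ndarray) -> np.ndarray:
    """Displacement ``q - p`` wrapped componentwise into ``[-box/2, box/2)``.

    Broadcasts over leading axes, so ``p`` and ``q`` may be arrays of points.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    box = np.asarray(box_lengths, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("non-finite coordinates")
    d = q - p
    return d - box * np.floor(d / box + 0.5)


def minimum_image_distance(p: np.ndarray, q: np.ndarray,
                           box_lengths: np.ndarray) -> np.ndarray:
    """Euclidean norm of the minimum-image displacement."""
    return np.linalg.norm(minimum_image_displacement(p, q, box_lengths), axis=-1)


def wrap_positions(points: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Map points into the primary cell ``[0, box)`` componentwise."""
    box = np.asarray(box_lengths, dtype=float)
    return np.mod(np.asarray(points, dtype=float), box)


def assign_hydrogens(oxygens: np.ndarray, hydrogens: np.ndarray,
                     box_lengths: np.ndarray, tie_tol: float = 1e-6
                     ) -> np.ndarray:
    """Assign each hydrogen to its nearest oxygen under minimum image.

    Raises
    ------
    FrameError
        If two oxygens are equidistant from a hydrogen within ``tie_tol``
        (ambiguous covalent assignment).
    """
    oxygens = np.asarray(oxygens, float)
    hydrogens = np.asarray(hydrogens, float)
    box = np.asarray(box_lengths, float)
    tree = cKDTree(wrap_positions(oxygens, box), boxsize=box)
    dists, owners = tree.query(wrap_positions(hydrogens, box), k=min(2, len(oxygens)))
    if len(oxygens) > 1:
        ambiguous = dists[:, 1] - dists[:, 0] < tie_tol
        if np.any(ambiguous):
            h = int(np.flatnonzero(ambiguous)[0])
            raise FrameError(
                f"assignment error: hydrogen {h} equidistant from oxygens "
                f"{owners[h, 0]} and {owners[h, 1]}")
        owners = owners[:, 0]
    return np.atleast_1d(np.asarray(owners, dtype=int).reshape(-1))


# ---------------------------------------------------------------------------
# readers / writers

_FORMATS = ("xyz", "gro", "lammps-dump")


def read_frames(path: str | Path, format_id: str = "xyz",
                box_lengths: Sequence[float] | None = None,
                type_map: dict[int, str] | None = None) -> list[WaterFrame]:
    """Read all frames from a trajectory file.

    Parameters
    ----------
    path
        Input file.
    format_id
        One of ``xyz``, ``gro``, ``lammps-dump``.
    box_lengths
        Required for XYZ files whose comment line carries no box; ignored
        for formats that store the box.
    type_map
        LAMMPS atom-type → element mapping, e.g. ``{1: "O", 2: "H"}``.
        Defaults to that mapping.

    Hydrogens are assigned to their nearest oxygen under minimum image, so
    the input need not group atoms by molecule.
    """
    path = Path(path)
    if format_id not in _FORMATS:
        raise ValueError(f"unknown format {format_id!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FrameError(f"no such file: {path}")
    if format_id == "xyz":
        raw = list(_read_xyz(path, box_lengths))
    elif format_id == "gro":
        raw = list(_read_mdanalysis(path, "GRO"))
    else:
        raw = list(_read_mdanalysis(path, "LAMMPSDUMP",
                                    type_map=type_map or {1: "O", 2: "H"}))
    frames = []
    for i, (elements, coords, box, time) in enumerate(raw):
        frames.append(_build_frame(elements, coords, box, i, time))
    return frames


def _build_frame(elements: Sequence[str], coords: np.ndarray,
                 box: np.ndarray, index: int, time: float) -> WaterFrame:
    elements = [e.capitalize() for e in elements]
    unknown = sorted(set(elements) - {"O", "H"})
    if unknown:
        raise FrameError(f"unrecognized element records: {unknown}")
    is_o = np.array([e == "O" for e in elements])
    oxy = coords[is_o]
    hyd = coords[~is_o]
    if len(hyd) != 2 * len(oxy):
        raise FrameError(
            f"composition error: frame {index} has {len(oxy)} O and "
            f"{len(hyd)} H records (expected H = 2×O)")
    owners = assign_hydrogens(oxy, hyd, box)
    return WaterFrame(oxy, hyd, owners, box, frame_index=index, frame_time=time)


def _parse_xyz_comment_box(comment: str) -> np.ndarray | None:
    """Extract box lengths from an XYZ comment line.

    Accepts the extended-XYZ ``Lattice="ax ... cz"`` form (orthorhombic
    only) or three bare floats.
    """
    comment = comment.strip()
    if "Lattice=" in comment:
        try:
            inner = comment.split("Lattice=", 1)[1]
            quote = inner[0]
            vals = [float(x) for x in inner[1:].split(quote, 1)[0].split()]
        except (IndexError, ValueError) as exc:
            raise FrameError(f"malformed Lattice comment: {comment!r}") from exc
        if len(vals) != 9:
            raise FrameError("Lattice must have 9 components")
        m = np.array(vals).reshape(3, 3)
        if not np.allclose(m, np.diag(np.diag(m))):
            raise FrameError("triclinic boxes are not supported (orthorhombic only)")
        return np.diag(m).copy()
    parts = comment.split()
    if len(parts) >= 3:
        try:
            return np.array([float(x) for x in parts[:3]])
        except ValueError:
            return None
    return None


def _read_xyz(path: Path, box_lengths: Sequence[float] | None
              ) -> Iterator[tuple[list[str], np.ndarray, np.ndarray, float]]:
    lines = path.read_text().splitlines()
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].split()[0])
        except ValueError as exc:
            raise FrameError(f"{path}:{pos + 1}: expected atom count, got "
                             f"{lines[pos]!r}") from exc
        if pos + 2 + natoms > len(lines):
            raise FrameError(f"{path}:{pos + 1}: truncated frame")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        box = _parse_xyz_comment_box(comment)
        if box is None:
            if box_lengths is None:
                raise FrameError(
                    f"{path}:{pos + 2}: XYZ comment carries no box and no "
                    "box_lengths were supplied")
            box = np.asarray(box_lengths, float)
        elements, coords = [], []
        for j in range(natoms):
            ln = pos + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise FrameError(f"{path}:{ln + 1}: malformed atom record "
                                 f"{lines[ln]!r}")
            elements.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError as exc:
                raise FrameError(f"{path}:{ln + 1}: non-numeric coordinate in "
                                 f"{lines[ln]!r}") from exc
        yield elements, np.array(coords, float), box, frame * 0.0
        frame += 1
        pos += 2 + natoms


def _read_mdanalysis(path: Path, fmt: str, type_map: dict[int, str] | None = None
                     ) -> Iterator[tuple[list[str], np.ndarray, np.ndarray, float]]:
    import warnings
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                raise FrameError(f"{path}: frame without box dimensions")
            if not np.allclose(dims[3:], 90.0):
                raise FrameError("triclinic boxes are not supported (orthorhombic only)")
            if type_map is not None:
                types = u.atoms.types
                try:
                    elements = [type_map[int(t)] for t in types]
                except (KeyError, ValueError) as exc:
                    raise FrameError(f"atom type not in type_map: {exc}") from exc
            else:
                names = u.atoms.names
                elements = [str(n)[0] for n in names]
            yield (elements, u.atoms.positions.astype(float).copy(),
                   dims[:3].astype(float).copy(), float(ts.time or 0.0))


def write_frames(path: str | Path, frames: Iterable[WaterFrame]) -> None:
    """Write frames as extended XYZ (O records first, then H) with the box
    on the comment line, so that ``read_frames`` round-trips."""
    path = Path(path)
    with path.open("w") as fh:
        for fr in frames:
            bx, by, bz = fr.box_lengths
            fh.write(f"{fr.n_molecules * 3}\n")
            fh.write(f'Lattice="{bx:.8f} 0.0 0.0 0.0 {by:.8f} 0.0 0.0 0.0 '
                     f'{bz:.8f}" frame={fr.frame_index} time={fr.frame_time}\n')
            for p in fr.oxygen_positions:
                fh.write(f"O {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
            for p in fr.hydrogen_positions:
                fh.write(f"H {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
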