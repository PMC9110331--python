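"""Hydrogen-bond graph construction (1st-level structure).

Two molecules are hydrogen bonded when any hydrogen of one lies strictly
closer than the cutoff (default 2.5 Å) to the oxygen of the other, under
the minimum-image convention.  No angular term is applied; the criterion
is purely geometric.  Multiple H···O contacts between the same pair
collapse to a single undirected edge, but every donating contact is kept
as an annotation so donation counts can be audited.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .frames import WaterFrame, wrap_positions


def neighbor_search(frame: WaterFrame, radius: float) -> np.ndarray:
    """All oxygen pairs with minimum-image distance < ``radius``.

    Uses a periodic k-d tree.  Returns an (n_pairs, 2) integer array of
    molecule index pairs ``i < j``, without duplicates.

    Raises
    ------
    ValueError
        If ``radius`` exceeds half the shortest box length (the minimum
        image would be ambiguous).
    """
    box = frame.box_lengths
    if radius > box.min() / 2:
        raise ValueError(f"radius {radius} exceeds min(box)/2 = {box.min() / 2}")
    tree = cKDTree(wrap_positions(frame.oxygen_positions, box), boxsize=box)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    # cKDTree uses <=; the package convention is strict < everywhere
    if len(pairs):
        pos = wrap_positions(frame.oxygen_positions, box)
        d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        d -= box * np.round(d / box)
        keep = np.einsum("ij,ij->i", d, d) < radius**2
        pairs = pairs[keep]
    return np.sort(pairs, axis=1) if len(pairs) else pairs.reshape(0, 2)


def detect_hbonds(frame: WaterFrame, cutoff: float = 2.5) -> nx.Graph:
    """Build the hydrogen-bond graph of a frame.

    Returns a :class:`networkx.Graph` whose nodes are molecule indices
    (all molecules, bonded or not) and whose edges carry a ``donors``
    attribute: a list of ``(donor_molecule, hydrogen_index)`` tuples, one
    per H···O contact below the cutoff.

    Bifurcated bonds are allowed: one hydrogen within the cutoff of two
    acceptors produces two edges.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    box = frame.box_lengths
    g = nx.Graph()
    g.add_nodes_from(range(frame.n_molecules))
    if frame.n_molecules == 0:
        return g
    o_tree = cKDTree(wrap_positions(frame.oxygen_positions, box), boxsize=box)
    h_wrapped = wrap_positions(frame.hydrogen_positions, box)
    # for each hydrogen, all oxygens within the cutoff (<=, re-checked strictly)
    neigh = o_tree.query_ball_point(h_wrapped, cutoff)
    o_wrapped = wrap_positions(frame.oxygen_positions, box)
    for h_idx, acceptors in enumerate(neigh):
        donor = int(frame.hydrogen_owner[h_idx])
        for acc in acceptors:
            if acc == donor:
                continue
            d = h_wrapped[h_idx] - o_wrapped[acc]
            d -= box * np.round(d / box)
            if float(d @ d) >= cutoff**2:
                continue
            if g.has_edge(donor, acc):
                g.edges[donor, acc]["donors"].append((donor, h_idx))
            else:
                g.add_edge(donor, acc, donors=[(donor, h_idx)])
    return g


def hbond_edge_table(graph: nx.Graph, frame: WaterFrame) -> list[tuple]:
    """Rows ``(frame_index, donor_mol, acceptor_mol, O..H distance Å)`` for
    every donating contact, for TSV export."""
    from .frames import minimum_image_distance

    rows = []
    for i, j, data in graph.edges(data=True):
        for donor, h_idx in data["donors"]:
            acceptor = j if donor == i else i
            d = float(minimum_image_distance(
                frame.hydrogen_positions[h_idx],
                frame.oxygen_positions[acceptor], frame.box_lengths))
            rows.append((frame.frame_index, donor, acceptor, d))
    return rows
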