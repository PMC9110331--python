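"""SPC/E interaction energies of molecule pairs and clusters.

The SPC/E rigid water model: point charges q_O = −0.8476 e, q_H =
+0.4238 e and a single O–O Lennard-Jones site (σ = 3.166 Å, ε = 0.650
kJ/mol).  A pair's energy is the sum over all nine charge–charge terms
plus the O–O LJ term, under the minimum-image convention, truncated
(set to zero) when the O–O distance reaches the cutoff (default 10 Å,
the nonbonded cutoff of the simulations this analysis targets).  No
long-range correction is applied: cluster energies are plain pair sums.

Energies are in kJ/mol; :func:`kjmol_to_ev` converts for reporting.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .frames import WaterFrame, minimum_image_displacement, minimum_image_distance

Q_O = -0.8476           # e
Q_H = +0.4238           # e
SIGMA_OO = 3.166        # Å
EPS_OO = 0.650          # kJ/mol
COULOMB_K = 1389.35457644382  # kJ Å / (mol e²)
EV_PER_KJMOL = 1.0 / 96.48533212331  # 1 kJ/mol in eV


def kjmol_to_ev(energy: float) -> float:
    """Convert an energy from kJ/mol to eV (per entity)."""
    return energy * EV_PER_KJMOL


def _sites(frame: WaterFrame, mol: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions (3, 3) and charges (3,) of a molecule's O, H, H sites."""
    h = frame.hydrogens_of(mol)
    pos = np.vstack([frame.oxygen_positions[mol], frame.hydrogen_positions[h]])
    return pos, np.array([Q_O, Q_H, Q_H])


def pair_interaction_energy(mol_i: int, mol_j: int, frame: WaterFrame,
                            cutoff: float = 10.0) -> float:
    """SPC/E interaction energy of two molecules, kJ/mol.

    Zero when the O–O minimum-image distance is ≥ ``cutoff``.  Raises on
    overlapping sites (any intermolecular site pair closer than 0.1 Å),
    which would make the Coulomb sum numerically meaningless.
    """
    if mol_i == mol_j:
        raise ValueError("pair energy needs two distinct molecules")
    box = frame.box_lengths
    d_oo = float(minimum_image_distance(frame.oxygen_positions[mol_i],
                                        frame.oxygen_positions[mol_j], box))
    if d_oo >= cutoff:
        return 0.0
    pos_i, q_i = _sites(frame, mol_i)
    pos_j, q_j = _sites(frame, mol_j)
    disp = minimum_image_displacement(pos_i[:, None, :], pos_j[None, :, :], box)
    dist = np.linalg.norm(disp, axis=-1)
    if dist.min() < 0.1:
        raise ValueError(f"overlapping sites between molecules {mol_i} and "
                         f"{mol_j} (distance {dist.min():.2e} Å)")
    coulomb = COULOMB_K * float(np.sum(np.outer(q_i, q_j) / dist))
    sr6 = (SIGMA_OO / d_oo) ** 6
    lj = 4.0 * EPS_OO * (sr6 * sr6 - sr6)
    return coulomb + lj


def cluster_energy(molecules: Iterable[int], frame: WaterFrame,
                   cutoff: float = 10.0) -> float:
    """E_S: sum of pair interaction energies over all unordered pairs of
    cluster molecules, kJ/mol.  Zero for singletons."""
    mols = sorted(set(int(m) for m in molecules))
    return sum(pair_interaction_energy(i, j, frame, cutoff)
               for i, j in combinations(mols, 2))


@dataclasses.dataclass(frozen=True)
class EnergySizeFit:
    """Least-squares line E_S = a·S + b over the cluster population."""

    slope: float       # a, energy per molecule
    intercept: float   # b
    n_clusters: int

    def per_molecule(self, size: float) -> float:
        """E_S/S = a + b/S at a given size."""
        return self.slope + self.intercept / size


def energy_size_fit(sizes: Sequence[int], energies: Sequence[float]
                    ) -> EnergySizeFit:
    """Fit the linear size–energy relation E_S = a·S + b.

    Requires at least 3 distinct sizes; with all clusters the same size
    the slope is unidentifiable.
    """
    s = np.asarray(sizes, float)
    e = np.asarray(energies, float)
    if len(s) != len(e):
        raise ValueError("sizes and energies must have equal length")
    if len(np.unique(s)) < 3:
        raise ValueError("energy-size fit needs ≥ 3 distinct cluster sizes")
    slope, intercept = np.polyfit(s, e, 1)
    return EnergySizeFit(float(slope), float(intercept), len(s))
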