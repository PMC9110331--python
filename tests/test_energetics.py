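"""SPC/E pair energies, cluster energies, LSI, density probes and RDFs."""

import itertools

import numpy as np
import pytest

from aquaclust.descriptors import (cluster_center, local_density_profile, lsi,
                                   rdf)
from aquaclust.energetics import (COULOMB_K, EPS_OO, Q_H, Q_O, SIGMA_OO,
                                  cluster_energy, energy_size_fit,
                                  kjmol_to_ev, pair_interaction_energy)
from aquaclust.frames import WaterFrame


def _dimer(oo: float, box: float = 40.0):
    oxy = np.array([[10.0, 20, 20], [10.0 + oo, 20, 20]])
    hyd = np.array([[11.0, 20, 20], [9.76, 20.93, 20],
                    [10.0 + oo + 0.96, 20, 20], [10.0 + oo - 0.24, 20.93, 20]])
    return WaterFrame(oxy, hyd, np.array([0, 0, 1, 1]), np.full(3, box))


def _oracle_pair_energy(frame, i, j):
    """Term-by-term site sum, written independently of the implementation."""
    box = frame.box_lengths

    def mi(d):
        return d - box * np.round(d / box)

    sites_i = [(frame.oxygen_positions[i], Q_O)] + [
        (frame.hydrogen_positions[h], Q_H) for h in frame.hydrogens_of(i)]
    sites_j = [(frame.oxygen_positions[j], Q_O)] + [
        (frame.hydrogen_positions[h], Q_H) for h in frame.hydrogens_of(j)]
    e = 0.0
    for (pa, qa), (pb, qb) in itertools.product(sites_i, sites_j):
        e += COULOMB_K * qa * qb / np.linalg.norm(mi(pb - pa))
    r = np.linalg.norm(mi(frame.oxygen_positions[j] - frame.oxygen_positions[i]))
    e += 4 * EPS_OO * ((SIGMA_OO / r) ** 12 - (SIGMA_OO / r) ** 6)
    return e


class TestPairEnergy:
    def test_beyond_cutoff_zero(self):
        assert pair_interaction_energy(0, 1, _dimer(12.0), cutoff=10.0) == 0.0

    def test_symmetry(self):
        f = _dimer(3.2)
        assert pair_interaction_energy(0, 1, f) == pytest.approx(
            pair_interaction_energy(1, 0, f))

    def test_ideal_hb_dimer_matches_site_sum_oracle(self):
        f = _dimer(2.8)
        e = pair_interaction_energy(0, 1, f)
        assert e < 0  # hydrogen-bonded geometry is attractive
        assert e == pytest.approx(_oracle_pair_energy(f, 0, 1), rel=1e-12)

    def test_random_pairs_match_oracle(self, random_box_200):
        f = random_box_200
        rng = np.random.default_rng(12)
        for _ in range(20):
            i, j = rng.choice(f.n_molecules, 2, replace=False)
            got = pair_interaction_energy(int(i), int(j), f)
            d = np.linalg.norm(
                (lambda d: d - f.box_lengths * np.round(d / f.box_lengths))(
                    f.oxygen_positions[j] - f.oxygen_positions[i]))
            expect = 0.0 if d >= 10.0 else _oracle_pair_energy(f, int(i), int(j))
            assert got == pytest.approx(expect, rel=1e-10)

    def test_overlapping_sites_rejected(self):
        f = _dimer(2.8)
        f2 = WaterFrame(np.array([[10.0, 20, 20], [10.05, 20, 20]]),
                        f.hydrogen_positions, f.hydrogen_owner, f.box_lengths)
        with pytest.raises(ValueError, match="overlap"):
            pair_interaction_energy(0, 1, f2)

    def test_same_molecule_rejected(self):
        with pytest.raises(ValueError):
            pair_interaction_energy(1, 1, _dimer(2.8))


class TestClusterEnergy:
    def test_singleton_zero(self):
        assert cluster_energy([0], _dimer(2.8)) == 0.0

    def test_pair_cluster_is_pair_energy(self):
        f = _dimer(2.9)
        assert cluster_energy([0, 1], f) == pytest.approx(
            pair_interaction_energy(0, 1, f))

    def test_cage_matches_double_loop(self, theta_455):
        frame, _ = theta_455
        mols = range(frame.n_molecules)
        brute = sum(_oracle_pair_energy(frame, i, j)
                    for i in mols for j in mols if i < j)
        assert cluster_energy(mols, frame) == pytest.approx(brute, rel=1e-10)

    def test_invariant_under_translation(self, theta_455):
        frame, _ = theta_455
        mols = list(range(frame.n_molecules))
        e1 = cluster_energy(mols, frame)
        f2 = WaterFrame(frame.oxygen_positions + 11.3,
                        frame.hydrogen_positions + 11.3,
                        frame.hydrogen_owner, frame.box_lengths)
        assert cluster_energy(mols, f2) == pytest.approx(e1, rel=1e-9)


class TestEnergySizeFit:
    def test_recovers_noisy_line(self):
        rng = np.random.default_rng(13)
        sizes = rng.integers(5, 200, 300)
        energies = -12.37 * sizes + 60.60 + rng.normal(0, 0.1, 300)
        fit = energy_size_fit(sizes, energies)
        # 3-sigma bands from the least-squares standard errors at n=300
        assert fit.slope == pytest.approx(-12.37, abs=0.01)
        assert fit.intercept == pytest.approx(60.60, abs=0.5)
        assert fit.per_molecule(100) == pytest.approx(
            fit.slope + fit.intercept / 100)

    def test_exact_line_exact_recovery(self):
        sizes = np.array([5, 10, 20, 40])
        fit = energy_size_fit(sizes, -3.0 * sizes + 7.0)
        assert fit.slope == pytest.approx(-3.0, abs=1e-12)
        assert fit.intercept == pytest.approx(7.0, abs=1e-10)

    def test_two_sizes_rejected(self):
        with pytest.raises(ValueError):
            energy_size_fit([5, 5, 9], [1.0, 1.1, 2.0])

    def test_ev_conversion(self):
        assert kjmol_to_ev(96.48533212331) == pytest.approx(1.0)


class TestLSI:
    def _frame_with_shell(self, distances, box=40.0):
        """Central molecule at the box center with neighbors at given
        distances along well-separated directions."""
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1], [.577, .577, .577]])
        center = np.full(3, box / 2)
        oxy = [center] + [center + d * r for r, d in zip(distances, dirs)]
        oxy = np.array(oxy)
        hyd = np.vstack([[o + [0.96, 0, 0.1], o + [-0.24, 0.93, 0.1]]
                         for o in oxy])
        return WaterFrame(oxy, hyd, np.repeat(np.arange(len(oxy)), 2),
                          np.full(3, box))

    def test_worked_value(self):
        """Four neighbors at 2.8 Å and the next at 4.5 Å: the gap sequence
        (0,0,0,1.7) has variance 0.541875 Å² about its mean 0.425."""
        f = self._frame_with_shell([2.8, 2.8, 2.8, 2.8, 4.5])
        res = lsi(f, 0)
        assert res.shell_count == 4
        assert res.mean_gap == pytest.approx(0.425)
        assert res.value == pytest.approx(0.5419, abs=1e-4)

    def test_equidistant_shell_zero(self):
        f = self._frame_with_shell([3.0, 3.0, 3.0, 3.0, 5.0])
        # gaps (0,0,2.0) -> nonzero; truly equal gaps instead:
        f2 = self._frame_with_shell([2.6, 2.9, 3.2, 3.5, 3.8])
        res = lsi(f2, 0)
        assert res.shell_count == 4
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_single_neighbor_inside_zero(self):
        res = lsi(self._frame_with_shell([3.0, 4.5, 4.8, 5.0, 5.5]), 0)
        assert res.shell_count == 1
        assert res.value == 0.0

    def test_no_neighbor_inside_is_undefined(self):
        assert lsi(self._frame_with_shell([4.5, 5.0, 5.5, 6.0, 6.5]), 0) is None

    def test_tie_stability(self):
        """Two equidistant neighbors contribute one zero gap regardless of
        their index order."""
        f = self._frame_with_shell([2.8, 2.8, 3.1, 4.5, 5.0])
        res = lsi(f, 0)
        assert res.gaps[0] == pytest.approx(0.0, abs=1e-12)


class TestDensityProfile:
    def test_uniform_gas_recovers_bulk_density(self):
        """Probes in a homogeneous system at 0.0334 molecules/Å³ count
        ≈ 0.0334 × 407.5 ≈ 13.6 oxygens each, giving ρ_local ≈ bulk."""
        import networkx as nx

        rng = np.random.default_rng(21)
        n, rho = 1000, 0.0334
        box = np.full(3, (n / rho) ** (1 / 3))
        pts = rng.random((n, 3)) * box
        hyd = np.vstack([[p + [0.96, 0, 0], p + [-0.24, 0.93, 0]]
                         for p in pts])
        f = WaterFrame(pts, hyd, np.repeat(np.arange(n), 2), box)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        prof = local_density_profile(f, range(n), g, probe_radius=4.6,
                                     bin_width=5.0)
        counts_per_probe = np.nanmean(prof.density) * 4 / 3 * np.pi * 4.6**3
        assert np.nanmean(prof.density) == pytest.approx(rho, rel=0.05)
        assert counts_per_probe == pytest.approx(13.6, rel=0.06)

    def test_probe_radius_limited_by_box(self, theta_455):
        import networkx as nx

        frame, _ = theta_455
        g = nx.Graph()
        g.add_nodes_from(range(frame.n_molecules))
        with pytest.raises(ValueError, match="probe radius"):
            local_density_profile(frame, range(frame.n_molecules), g,
                                  probe_radius=frame.box_lengths.min())

    def test_center_modes(self, theta_455):
        from aquaclust.hbonds import detect_hbonds

        frame, _ = theta_455
        g = detect_hbonds(frame)
        mols = range(frame.n_molecules)
        geo = cluster_center(frame, mols, g, "geometric")
        com = cluster_center(frame, mols, g, "mass")
        assert np.linalg.norm(geo - com) < 1.0  # close but not identical
        assert not np.allclose(geo, com)


class TestRDF:
    def test_poisson_gas_is_flat(self):
        rng = np.random.default_rng(14)
        box = np.full(3, 30.0)
        pts = rng.random((3000, 3)) * box
        curve = rdf(pts, None, box, r_max=10.0, bin_width=0.5)
        # skip the first bins (few pairs, noisy)
        assert np.all(np.abs(curve.g[4:] - 1.0) < 0.1)

    def test_normalization_integrates_to_neighbor_count(self):
        rng = np.random.default_rng(15)
        box = np.full(3, 20.0)
        pts = rng.random((800, 3)) * box
        r_max, dr = 8.0, 0.2
        curve = rdf(pts, None, box, r_max=r_max, bin_width=dr)
        rho = (len(pts) - 1) / box.prod()
        edges = np.arange(0.0, r_max + dr, dr)
        shell = 4 / 3 * np.pi * np.diff(edges**3)
        integral = np.sum(curve.g * rho * shell)
        expected = 4 / 3 * np.pi * r_max**3 * rho
        assert integral == pytest.approx(expected, rel=0.05)

    def test_cubic_lattice_first_peak(self):
        spacing, n = 3.0, 6
        pts = np.array([[i, j, k] for i in range(n) for j in range(n)
                        for k in range(n)], float) * spacing
        curve = rdf(pts, None, np.full(3, n * spacing), r_max=8.0,
                    bin_width=0.2)
        first_peak = curve.r[np.argmax(curve.g)]
        assert first_peak == pytest.approx(3.0, abs=0.2)

    def test_single_particle_self_rdf_rejected(self):
        with pytest.raises(ValueError):
            rdf(np.array([[1.0, 1, 1]]), None, np.full(3, 10.0), r_max=4.0)
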