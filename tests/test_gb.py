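"""Closed-form and brute-force oracles for the GB/MM-GBSA energy stack."""

import numpy as np
import pytest

from mdpost.gb import (COULOMB_CONSTANT, EnergyError, EnergyModelConfig,
                       coulomb_lj_interaction, decompose,
                       effective_born_radii, gb_polar_energy,
                       hct_descreening_integrals, mmgbsa_binding, sasa)
from mdpost.io import Trajectory
from mdpost.synthetic import (born_ion, charge_pair, charged_dimer, lj_pair,
                              toy_charged_complex)

from conftest import apply_rigid, random_rigid_motion

SALT_FREE = EnergyModelConfig(salt=0.0)


class TestCoulombLJ:
    def test_unit_charges_at_one_angstrom(self):
        top, xyz = charge_pair(separation=1.0)
        e_elec, _ = coulomb_lj_interaction([0], [1], xyz, top)
        assert e_elec == pytest.approx(332.0636)

    def test_lj_minimum_is_minus_epsilon(self):
        top, xyz = lj_pair(rmin_half=1.7, epsilon=0.25)
        _, e_vdw = coulomb_lj_interaction([0], [1], xyz, top)
        assert e_vdw == pytest.approx(-0.25, abs=1e-12)

    def test_silent_partner_gives_zero(self):
        top, xyz = toy_charged_complex([
            {"charge": 1.0, "position": (0, 0, 0), "residue": 0},
            {"charge": 0.0, "epsilon": 0.0, "position": (2, 0, 0),
             "residue": 1}])
        assert coulomb_lj_interaction([0], [1], xyz, top) == (0.0, 0.0)

    def test_overlapping_groups_rejected(self):
        top, xyz = charge_pair()
        with pytest.raises(EnergyError, match="overlap"):
            coulomb_lj_interaction([0, 1], [1], xyz, top)

    def test_coincident_atoms_rejected(self):
        top, xyz = toy_charged_complex([
            {"charge": 1.0, "position": (0, 0, 0), "residue": 0},
            {"charge": 1.0, "position": (0, 0, 0), "residue": 1}])
        with pytest.raises(EnergyError, match="r = 0"):
            coulomb_lj_interaction([0], [1], xyz, top)


class TestBornRadii:
    def test_isolated_atom_offset_limit(self):
        top, xyz = born_ion(radius=2.0)
        radii = effective_born_radii(xyz, top, SALT_FREE)
        assert radii[0] == pytest.approx(2.0 - 0.09, abs=1e-12)

    def test_distant_pair_approaches_isolated(self):
        top, xyz = toy_charged_complex([
            {"radius": 1.5, "position": (0, 0, 0), "residue": 0},
            {"radius": 1.7, "position": (100.0, 0, 0), "residue": 1}])
        radii = effective_born_radii(xyz, top, SALT_FREE)
        assert radii[0] == pytest.approx(1.5 - 0.09, abs=1e-6)
        assert radii[1] == pytest.approx(1.7 - 0.09, abs=1e-6)

    def test_neighbor_descreening_shrinks_inverse_radius(self):
        top, xyz = toy_charged_complex([
            {"radius": 1.5, "position": (0, 0, 0), "residue": 0},
            {"radius": 1.7, "position": (4.0, 0, 0), "residue": 1}])
        radii = effective_born_radii(xyz, top, SALT_FREE)
        assert radii[0] > 1.5 - 0.09   # burial increases the Born radius

    def test_descreening_integral_matches_monte_carlo(self, rng):
        """HCT analytic integral vs volume MC of 1/(4π r⁴), 10⁷ samples."""
        rho = np.array([1.5, 1.7])
        screen = np.ones(2)
        sep = 4.0
        coords = np.array([[0.0, 0, 0], [sep, 0, 0]])
        analytic = hct_descreening_integrals(coords, rho, screen)[0]

        rho_t = rho - 0.09
        n = 10_000_000
        # uniform points in the scaled sphere around atom 1
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        radii = rho_t[1] * rng.random(n) ** (1 / 3)
        pts = coords[1] + u * radii[:, None]
        r = np.linalg.norm(pts, axis=1)
        keep = r > rho_t[0]
        vals = np.where(keep, 1.0 / r ** 4, 0.0)
        volume = 4.0 / 3.0 * np.pi * rho_t[1] ** 3
        estimate = volume / (4 * np.pi) * vals.mean()
        stderr = volume / (4 * np.pi) * vals.std() / np.sqrt(n)
        assert abs(estimate - analytic) < 5 * stderr

    def test_nonpositive_radius_rejected(self):
        top, xyz = born_ion()
        object.__setattr__(top.atoms[0], "intrinsic_radius", None)
        with pytest.raises(Exception, match="radius"):
            effective_born_radii(xyz, top, SALT_FREE)


class TestGBPolar:
    def test_zero_charges_zero_energy(self):
        top, xyz = lj_pair()
        radii = effective_born_radii(xyz, top, SALT_FREE)
        assert gb_polar_energy(xyz, top.charges, radii, SALT_FREE) == 0.0

    def test_born_ion_closed_form(self):
        """q = 1e, R = 2 Å, ε_out = 78.5, no salt → −81.96 kcal/mol."""
        top, xyz = born_ion(charge=1.0, radius=2.0)
        e = gb_polar_energy(xyz, top.charges, np.array([2.0]), SALT_FREE)
        exact = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5) / 2.0
        assert e == pytest.approx(exact, rel=1e-9)
        assert e == pytest.approx(-81.96, abs=5e-3)

    def test_salt_adds_debye_stabilization(self):
        """Salt screening lowers the ion's solvation energy further,
        bounded below by the conductor (κ → ∞) limit."""
        top, xyz = born_ion()
        e0 = gb_polar_energy(xyz, top.charges, np.array([2.0]), SALT_FREE)
        e1 = gb_polar_energy(xyz, top.charges, np.array([2.0]),
                             EnergyModelConfig(salt=0.1))
        e2 = gb_polar_energy(xyz, top.charges, np.array([2.0]),
                             EnergyModelConfig(salt=0.5))
        conductor = -0.5 * COULOMB_CONSTANT / 2.0
        assert conductor < e2 < e1 < e0 < 0

    def test_opposite_pair_continuous_monotone_in_separation(self):
        """Neutral ± pair: ΔG_GB decreases smoothly as charges separate."""

        def energy_curve(grid):
            out = []
            for sep in grid:
                top, xyz = toy_charged_complex([
                    {"charge": 1.0, "radius": 1.5, "position": (0, 0, 0),
                     "residue": 0},
                    {"charge": -1.0, "radius": 1.5, "position": (sep, 0, 0),
                     "residue": 1}])
                radii = effective_born_radii(xyz, top, SALT_FREE)
                out.append(gb_polar_energy(xyz, top.charges, radii,
                                           SALT_FREE))
            return np.array(out)

        coarse = energy_curve(np.linspace(2.0, 50.0, 49))
        fine = energy_curve(np.linspace(2.0, 50.0, 97))
        assert np.all(np.diff(coarse) < 0)         # monotone
        assert np.all(np.diff(fine) < 0)
        # continuity: halving the step roughly halves the largest jump
        assert np.abs(np.diff(fine)).max() \
            < 0.75 * np.abs(np.diff(coarse)).max()


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.5]), SALT_FREE)
        assert areas[0] == pytest.approx(4 * np.pi * 2.9 ** 2, rel=2e-3)

    def test_fully_overlapping_spheres_count_once_total(self):
        # near-coincident identical spheres: each contributes its outward
        # hemisphere, so the summed area is one sphere to grid accuracy
        coords = np.array([[0.0, 0, 0], [1e-3, 0, 0]])
        areas = sasa(coords, np.array([1.5, 1.5]), SALT_FREE)
        assert areas.sum() == pytest.approx(4 * np.pi * 2.9 ** 2, rel=2e-2)

    def test_distant_spheres_additive(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        areas = sasa(coords, np.array([1.5, 2.0]), SALT_FREE)
        assert areas[0] == pytest.approx(4 * np.pi * 2.9 ** 2, rel=2e-3)
        assert areas[1] == pytest.approx(4 * np.pi * 3.4 ** 2, rel=2e-3)

    def test_grid_convergence(self, rng):
        """Doubling sphere points changes a 10-atom total by < 0.5%."""
        coords = rng.normal(scale=2.0, size=(10, 3))
        radii = np.full(10, 1.6)
        a1 = sasa(coords, radii, EnergyModelConfig(sasa_points=960)).sum()
        a2 = sasa(coords, radii, EnergyModelConfig(sasa_points=1920)).sum()
        assert abs(a2 - a1) / a2 < 0.005


class TestMMGBSA:
    def _dimer(self):
        top, xyz = charged_dimer(separation=8.0)
        return top, Trajectory(xyz[None])

    def test_noninteracting_limit(self):
        top, xyz = toy_charged_complex([
            {"charge": 0.0, "epsilon": 0.0, "position": (0, 0, 0),
             "residue": 0, "chain": "A"},
            {"charge": 0.0, "epsilon": 0.0, "position": (500.0, 0, 0),
             "residue": 1, "chain": "B"}])
        bd = mmgbsa_binding(Trajectory(xyz[None]), top,
                            {"receptor": [0], "ligand": [1]},
                            EnergyModelConfig(frame_count=1, salt=0.0))
        assert abs(bd.total) < 1e-6

    def test_dimer_matches_independent_whole_system_oracle(self):
        """ΔG_b equals a from-scratch G(AB) − G(A) − G(B) evaluation."""
        top, traj = self._dimer()
        cfg = EnergyModelConfig(frame_count=1)
        bd = mmgbsa_binding(traj, top, {"receptor": [0], "ligand": [1]}, cfg)
        xyz = traj.coordinates[0]
        q = top.charges
        rad = top.intrinsic_radii()

        def species_energy(idx):
            idx = np.asarray(idx)
            born = effective_born_radii(xyz, top, cfg, subset=idx)
            g = gb_polar_energy(xyz[idx], q[idx], born, cfg)
            e_el = e_vdw = 0.0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = idx[a], idx[b]
                    r = np.linalg.norm(xyz[i] - xyz[j])
                    e_el += COULOMB_CONSTANT * q[i] * q[j] / r
                    rmin = top.lj_rmin_half[i] + top.lj_rmin_half[j]
                    eps = np.sqrt(top.lj_epsilon[i] * top.lj_epsilon[j])
                    e_vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            area = sasa(xyz[idx], rad[idx], cfg).sum()
            return e_el + e_vdw + g + cfg.surface_tension * area

        oracle = (species_energy([0, 1]) - species_energy([0])
                  - species_energy([1]))
        assert bd.total == pytest.approx(oracle, abs=1e-9)

    def test_component_additivity(self):
        top, traj = self._dimer()
        bd = mmgbsa_binding(traj, top, {"receptor": [0], "ligand": [1]},
                            EnergyModelConfig(frame_count=1))
        assert bd.total == pytest.approx(sum(bd.components.values()),
                                         abs=1e-6)

    def test_decomposition_sums_to_total(self):
        top, traj = self._dimer()
        bd = mmgbsa_binding(traj, top, {"receptor": [0], "ligand": [1]},
                            EnergyModelConfig(frame_count=1))
        assert bd.per_residue.sum() == pytest.approx(bd.total, abs=1e-4)
        pair_sum = np.diag(bd.pairwise).sum() + np.triu(bd.pairwise, 1).sum()
        assert pair_sum == pytest.approx(bd.total, abs=1e-4)

    def test_symmetric_homodimer_equal_per_residue(self):
        top, xyz = toy_charged_complex([
            {"charge": 0.5, "radius": 1.5, "position": (0, 0, 0),
             "residue": 0, "chain": "A"},
            {"charge": 0.5, "radius": 1.5, "position": (8.0, 0, 0),
             "residue": 1, "chain": "B"}])
        bd = mmgbsa_binding(Trajectory(xyz[None]), top,
                            {"receptor": [0], "ligand": [1]},
                            EnergyModelConfig(frame_count=1))
        assert bd.per_residue[0] == pytest.approx(bd.per_residue[1],
                                                  abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        top, traj = self._dimer()
        cfg = EnergyModelConfig(frame_count=1)
        part = {"receptor": [0], "ligand": [1]}
        base = mmgbsa_binding(traj, top, part, cfg).total
        rot, trans = random_rigid_motion(rng)
        moved = Trajectory(apply_rigid(traj.coordinates, rot, trans))
        assert mmgbsa_binding(moved, top, part, cfg).total \
            == pytest.approx(base, abs=1e-6)

    def test_single_frame_degenerate_average(self):
        top, traj = self._dimer()
        bd = mmgbsa_binding(traj, top, {"receptor": [0], "ligand": [1]},
                            EnergyModelConfig(frame_count=1))
        assert bd.per_frame["total"].iloc[0] == bd.total

    def test_partition_gap_rejected(self):
        top, traj = self._dimer()
        with pytest.raises(EnergyError, match="cover"):
            mmgbsa_binding(traj, top, {"receptor": [0], "ligand": []},
                           EnergyModelConfig(frame_count=1))

    def test_partition_overlap_rejected(self):
        top, traj = self._dimer()
        with pytest.raises(EnergyError, match="overlap"):
            mmgbsa_binding(traj, top, {"receptor": [0, 1], "ligand": [1]},
                           EnergyModelConfig(frame_count=1))


class TestDecompose:
    def _five_residue_interface(self):
        """One dominant close pair (residues 1↔3), weaker others."""
        specs = []
        charges = [0.2, 1.0, 0.1, -1.0, 0.15]
        xs = [0.0, 4.0, 1.0, 7.4, 16.0]
        ys = [0.0, 1.0, 0.0, 1.0, 0.0]
        chains = ["A", "A", "A", "B", "B"]
        for i, (q, x, y, ch) in enumerate(zip(charges, xs, ys, chains)):
            specs.append({"charge": q, "position": (x, y, 0.0),
                          "residue": i, "chain": ch, "radius": 1.5})
        top, xyz = toy_charged_complex(specs)
        return top, Trajectory(xyz[None])

    def test_top_interface_pair_matches_enumeration(self):
        top, traj = self._five_residue_interface()
        bd = mmgbsa_binding(traj, top,
                            {"receptor": [0, 1, 2], "ligand": [3, 4]},
                            EnergyModelConfig(frame_count=1))
        table = decompose(bd, "pairwise", interface_only=True,
                          partition_residues=({0, 1, 2}, {3, 4}))
        # exhaustive enumeration over the retained matrix
        best = max(((i, j) for i in (0, 1, 2) for j in (3, 4)),
                   key=lambda p: abs(bd.pairwise[p]))
        top_row = table.iloc[0]
        assert {top_row["residue_i"], top_row["residue_j"]} == {
            bd.residue_labels[best[0]], bd.residue_labels[best[1]]}
        # and the planted dominant pair is the charge-1/charge-−1 contact
        assert best == (1, 3)

    def test_per_residue_table_sums_to_total(self):
        top, traj = self._five_residue_interface()
        bd = mmgbsa_binding(traj, top,
                            {"receptor": [0, 1, 2], "ligand": [3, 4]},
                            EnergyModelConfig(frame_count=1))
        table = decompose(bd, "per_residue")
        assert table["energy_kcal_mol"].sum() == pytest.approx(bd.total,
                                                               abs=1e-4)

    def test_missing_bookkeeping_rejected(self):
        top, xyz = charged_dimer()
        bd = mmgbsa_binding(Trajectory(xyz[None]), top,
                            {"receptor": [0], "ligand": [1]},
                            EnergyModelConfig(frame_count=1),
                            keep_decomposition=False)
        with pytest.raises(EnergyError, match="bookkeeping"):
            decompose(bd)
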