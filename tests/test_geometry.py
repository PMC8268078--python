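"""Superposition, average structure, RMSD and RMSF behaviour."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdpost.geometry import (BFACTOR_FACTOR, GeometryError, average_structure,
                             fit_trajectory, kabsch_fit, rmsd_series, rmsf,
                             select_backbone, select_heavy)
from mdpost.io import Topology, Trajectory

from conftest import apply_rigid, make_atom, random_rigid_motion


class TestKabschFit:
    def test_identity(self, tetra_coords):
        res = kabsch_fit(tetra_coords, tetra_coords)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_rigid_motion_removed(self, tetra_coords):
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = tetra_coords @ rot.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_fit(moved, tetra_coords)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.transform(moved), tetra_coords,
                                   atol=1e-9)

    def test_proper_rotation_only(self, tetra_coords):
        mirrored = tetra_coords * np.array([1.0, 1.0, -1.0])
        res = kabsch_fit(mirrored, tetra_coords)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1  # a reflection would give 0; must not be used

    def test_swapped_axis_triangle_superposes_exactly(self):
        """(0,1,0) → (0,0,1) is a proper 90° rotation about x: RMSD = 0."""
        ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        mob = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        assert kabsch_fit(mob, ref).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_matches_rotation_grid_search_oracle(self):
        """Optimal RMSD agrees with brute-force search over many rotations."""
        ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                        [0.3, 0.2, 0.9]])
        mob = np.array([[0.1, 0.0, 0.0], [1.0, 0.2, 0.0], [0.0, 0.0, 1.1],
                        [0.8, 0.1, 0.4]])
        fitted = kabsch_fit(mob, ref).rmsd
        rots = Rotation.random(200_000,
                               random_state=np.random.RandomState(7))
        ref_c = ref - ref.mean(axis=0)
        mob_c = mob - mob.mean(axis=0)
        cand = np.einsum("rij,nj->rni", rots.as_matrix(), mob_c)
        rmsds = np.sqrt(((cand - ref_c) ** 2).sum(axis=(1, 2)) / len(ref))
        assert fitted <= rmsds.min() + 1e-12      # never beaten by the grid
        assert rmsds.min() - fitted < 5e-3         # grid resolution bound

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert kabsch_fit(a, b).rmsd == pytest.approx(
            kabsch_fit(b, a).rmsd, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        np.zeros((2, 3)),                                   # too few points
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),      # collinear
    ])
    def test_degenerate_inputs_rejected(self, bad):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        with pytest.raises(GeometryError):
            kabsch_fit(bad, ref[: len(bad)])

    def test_zero_weights_rejected(self, tetra_coords):
        with pytest.raises(GeometryError, match="weight"):
            kabsch_fit(tetra_coords, tetra_coords, np.zeros(4))


class TestAverageStructure:
    def test_identical_frames_fixed_point(self, tetra_coords):
        traj = Trajectory(np.repeat(tetra_coords[None], 5, axis=0))
        mean = average_structure(traj)
        np.testing.assert_allclose(mean, tetra_coords, atol=1e-12)

    def test_translated_frames_congruent(self, tetra_coords):
        frames = np.stack([tetra_coords, tetra_coords + [3.0, -1.0, 2.0]])
        mean = average_structure(Trajectory(frames))
        assert kabsch_fit(mean, tetra_coords).rmsd == pytest.approx(
            0.0, abs=1e-9)

    def test_noise_averages_out(self, tetra_coords, rng):
        sigma = 0.05
        n = 100
        frames = tetra_coords[None] + rng.normal(
            scale=sigma, size=(n, 4, 3))
        mean = average_structure(Trajectory(frames), tol=1e-8, max_iter=50)
        aligned = kabsch_fit(mean, tetra_coords)
        # law of large numbers: each coordinate within a few sigma/sqrt(n)
        assert np.abs(aligned.transform(mean)
                      - tetra_coords).max() < 5 * sigma / np.sqrt(n)

    def test_nonconvergence_reports_displacement(self, tetra_coords, rng):
        frames = tetra_coords[None] + rng.normal(scale=1.0, size=(20, 4, 3))
        with pytest.raises(GeometryError, match="displacement"):
            average_structure(Trajectory(frames), tol=1e-15, max_iter=1)


class TestRmsdSeries:
    def test_reference_frame_is_zero(self, tetra_coords, rng):
        frames = tetra_coords[None] + rng.normal(scale=0.3, size=(4, 4, 3))
        series = rmsd_series(Trajectory(frames), frames[2], fit=False)
        assert series[2] == pytest.approx(0.0, abs=1e-12)

    def test_translated_copies_fit_to_zero(self, tetra_coords):
        shifts = np.array([[0, 0, 0], [1, 2, 3], [-4, 0, 1.5]], dtype=float)
        frames = tetra_coords[None] + shifts[:, None, :]
        series = rmsd_series(Trajectory(frames), tetra_coords, fit=True)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_hand_value_two_atoms_one_displaced(self):
        """Equal masses, one atom off by 1 Å: RMSD = sqrt(1/2)."""
        top = Topology([make_atom(i + 1, name=f"C{i + 1}") for i in range(4)])
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        moved = ref.copy()
        moved[0, 0] += 1.0
        series = rmsd_series(Trajectory(moved[None]), ref,
                             selection=np.array([0, 1]),
                             weights=top.masses[:2], fit=False)
        assert series[0] == pytest.approx(np.sqrt(0.5))

    def test_fitted_never_exceeds_unfitted(self, tetra_coords, rng):
        frames = tetra_coords[None] + rng.normal(scale=0.5, size=(6, 4, 3))
        traj = Trajectory(frames)
        fitted = rmsd_series(traj, tetra_coords, fit=True)
        unfitted = rmsd_series(traj, tetra_coords, fit=False)
        assert np.all(fitted <= unfitted + 1e-12)

    def test_empty_selection_rejected(self, tetra_coords):
        with pytest.raises(GeometryError, match="selection"):
            rmsd_series(Trajectory(tetra_coords[None]), tetra_coords,
                        selection=np.array([], dtype=int))


class TestRmsf:
    def _topology(self):
        return Topology([make_atom(i + 1, name=f"C{i + 1}") for i in range(4)])

    def test_static_trajectory_is_zero(self, tetra_coords):
        top = self._topology()
        traj = Trajectory(np.repeat(tetra_coords[None], 6, axis=0))
        prof = rmsf(traj, top)
        np.testing.assert_allclose(prof.per_residue_rmsf, 0.0)
        np.testing.assert_allclose(prof.per_residue_bfactor, 0.0)

    def test_alternating_unit_displacement(self, tetra_coords):
        """x = ±1 Å alternation: RMSF = 1 Å, B = 8π²/3 ≈ 26.32 Å²."""
        top = self._topology()
        frames = np.repeat(tetra_coords[None], 10, axis=0)
        frames[::2, 0, 0] += 1.0
        frames[1::2, 0, 0] -= 1.0
        prof = rmsf(Trajectory(frames), top)
        assert prof.atom_rmsf[0] == pytest.approx(1.0)
        atom_b = BFACTOR_FACTOR * prof.atom_rmsf[0] ** 2
        assert atom_b == pytest.approx(8 * np.pi ** 2 / 3)

    def test_gaussian_sigma_recovery(self, tetra_coords, rng):
        """Isotropic σ = 0.5 Å per axis ⇒ RMSF = √3·0.5 within 1% at n=1e5."""
        top = self._topology()
        n = 100_000
        frames = tetra_coords[None] + rng.normal(scale=0.5, size=(n, 4, 3))
        prof = rmsf(Trajectory(frames), top)
        expected = np.sqrt(3) * 0.5
        np.testing.assert_allclose(prof.atom_rmsf, expected, rtol=0.01)

    def test_bfactor_invariant_exact(self, tetra_coords, rng):
        top = self._topology()
        frames = tetra_coords[None] + rng.normal(scale=0.2, size=(50, 4, 3))
        prof = rmsf(Trajectory(frames), top)
        np.testing.assert_array_equal(
            prof.per_residue_bfactor,
            BFACTOR_FACTOR * prof.per_residue_rmsf ** 2)

    def test_invariant_under_global_rigid_motion(self, tetra_coords, rng):
        top = self._topology()
        frames = tetra_coords[None] + rng.normal(scale=0.2, size=(40, 4, 3))
        rot, trans = random_rigid_motion(rng)
        moved = apply_rigid(frames, rot, trans)

        def profile(f):
            traj = Trajectory(f)
            mean = average_structure(traj, weights=top.masses)
            fitted = fit_trajectory(traj, mean, weights=top.masses)
            return rmsf(fitted, top).per_residue_rmsf

        np.testing.assert_allclose(profile(moved), profile(frames),
                                   atol=1e-9)

    def test_single_frame_window_rejected(self, tetra_coords):
        top = self._topology()
        with pytest.raises(GeometryError, match="2 frames"):
            rmsf(Trajectory(tetra_coords[None]), top)


def test_selections_name_conventions():
    atoms = [make_atom(1, name="N", element="N"),
             make_atom(2, name="CA"),
             make_atom(3, name="C"),
             make_atom(4, name="O", element="O"),
             make_atom(5, name="CB"),
             make_atom(6, name="HB", element="H")]
    top = Topology(atoms)
    assert select_backbone(top).tolist() == [0, 1, 2, 3]
    assert select_heavy(top).tolist() == [0, 1, 2, 3, 4]
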