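"""Binding-energy cut-off filter, pairwise RMSD matrix, average-structure
selection — checked against brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from pmhcdock.consensus import (DockedPose, PoseEnsemble, compute_cutoff,
                                filter_poses, load_ensemble,
                                pairwise_rmsd_matrix, run_consensus,
                                select_from_matrix)
from pmhcdock.epitope_builder import thread_peptide
from pmhcdock.errors import ConsensusError
from pmhcdock.fixtures import EnsembleSpec, make_ensemble
from pmhcdock.structure_io import select_atom_records, write_pdb


def _ensemble_from(template, be_values, perturb=None):
    base = thread_peptide(template.pattern_sequence, template)
    poses = []
    for k, be in enumerate(be_values):
        pose = base.copy()
        if perturb:
            perturb(pose, k)
        poses.append(DockedPose(coords=pose, binding_energy=be,
                                run_index=k + 1))
    return PoseEnsemble(poses)


class TestCutoffAndFilter:
    def test_constant_energies(self, toy9):
        ens = _ensemble_from(toy9[1], [-10.0] * 4)
        assert compute_cutoff(ens) == -10.0
        assert filter_poses(ens, -10.0) == [0, 1, 2, 3]

    def test_mean_of_mixed_energies(self, toy9):
        ens = _ensemble_from(toy9[1], [-10, -9, -8, -7])
        co = compute_cutoff(ens)
        assert co == -8.5
        assert filter_poses(ens, co) == [0, 1]

    def test_single_pose(self, toy9):
        ens = _ensemble_from(toy9[1], [-6.2])
        assert compute_cutoff(ens) == -6.2
        assert filter_poses(ens, -6.2) == [0]

    def test_one_strong_binder_dominates(self, toy9):
        ens = _ensemble_from(toy9[1], [-10, -1, -1, -1])
        co = compute_cutoff(ens)
        assert co == -3.25
        assert filter_poses(ens, co) == [0]

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ConsensusError):
            PoseEnsemble([])

    @given(st.lists(st.floats(-15, 0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_filter_always_retains_at_least_one(self, bes):
        bes = np.asarray(bes)
        cutoff = float(np.mean(bes))
        assert np.count_nonzero(bes <= cutoff) >= 1


class TestRmsdMatrix:
    def test_identical_poses_zero_matrix(self, toy9):
        ens = _ensemble_from(toy9[1], [-9.0, -9.0])
        m = pairwise_rmsd_matrix(ens, [0, 1])
        np.testing.assert_allclose(m, 0.0, atol=1e-9)

    def test_rigidly_rotated_pose_gives_zero_offdiagonal(self, toy9):
        def perturb(pose, k):
            if k == 1:
                R = Rotation.from_euler("xyz", [30, -60, 45],
                                        degrees=True).as_matrix()
                pose.set_coords(pose.coords_array() @ R.T + [4.0, 1.0, -2.0])
        ens = _ensemble_from(toy9[1], [-9.0, -9.0], perturb)
        m = pairwise_rmsd_matrix(ens, [0, 1])
        assert m[0, 1] < 1e-9

    def test_single_displaced_atom_arithmetic(self, toy9):
        # displace one side-chain atom of pose 3 by d perpendicular to the
        # fit: m[0,2] == m[1,2] approx d/sqrt(N) for small d
        d = 0.01  # small so the Kabsch fit stays essentially the identity
        def perturb(pose, k):
            if k == 2:
                records = select_atom_records(pose, "side-chain")
                records[0].coords = records[0].coords + np.array([0, 0, d])
        ens = _ensemble_from(toy9[1], [-9.0] * 3, perturb)
        m = pairwise_rmsd_matrix(ens, [0, 1, 2])
        n_atoms = len(select_atom_records(ens.poses[0].coords, "heavy"))
        # d/sqrt(N) is the no-fit value; the superposition absorbs a small
        # part of a single-atom displacement, so the entry sits just below it
        bound = d / np.sqrt(n_atoms)
        assert 0.9 * bound < m[0, 2] <= bound + 1e-12
        assert m[1, 2] == pytest.approx(m[0, 2], abs=1e-12)
        assert m[0, 1] < 1e-12


class TestSelection:
    def test_hand_computed_row_means(self):
        matrix = np.array([[0, 1, 1], [1, 0, 4], [1, 4, 0]], dtype=float)
        pos, row_means = select_from_matrix(
            matrix, np.array([-9.0, -9.0, -9.0]), np.array([1, 2, 3]))
        np.testing.assert_allclose(row_means, [1.0, 2.5, 2.5])
        assert pos == 0

    def test_tie_broken_by_lower_binding_energy(self):
        matrix = np.ones((3, 3)) - np.eye(3)
        pos, _ = select_from_matrix(matrix, np.array([-9.0, -10.0, -8.0]),
                                    np.array([1, 2, 3]))
        assert pos == 1

    def test_remaining_tie_broken_by_run_index(self):
        matrix = np.ones((3, 3)) - np.eye(3)
        pos, _ = select_from_matrix(matrix, np.array([-9.0, -9.0, -9.0]),
                                    np.array([7, 3, 5]))
        assert pos == 1  # run 3

    def test_singleton_selected_directly(self, toy9):
        ens = _ensemble_from(toy9[1], [-10, -1, -1, -1])
        result = run_consensus(ens)
        assert result.retained_indices == [0]
        assert result.selected_index == 0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_selection_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 20)
        sym = rng.uniform(0.1, 5.0, size=(m, m))
        matrix = (sym + sym.T) / 2
        np.fill_diagonal(matrix, 0.0)
        bes = rng.uniform(-12, -2, size=m)
        runs = np.arange(1, m + 1)
        pos, row_means = select_from_matrix(matrix, bes, runs)
        # independent brute force over all rows
        best, best_key = None, None
        for j in range(m):
            mean_j = sum(matrix[j, k] for k in range(m) if k != j) / (m - 1)
            key = (round(mean_j, 9), bes[j], runs[j])
            if best_key is None or key < best_key:
                best, best_key = j, key
        assert row_means[pos] <= min(row_means) + 1e-9
        assert pos == best

    def test_consensus_invariant_under_reordering(self, toy9):
        spec = EnsembleSpec(n_poses=6, chi_sigma_deg=25.0,
                            be_values=(-9, -8, -11, -7, -10, -8.5), seed=5)
        ens = make_ensemble(toy9[1], spec)
        result = run_consensus(ens)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = PoseEnsemble([ens.poses[i] for i in perm])
        result2 = run_consensus(shuffled)
        assert perm[result2.selected_index] == result.selected_index

    def test_bitwise_determinism(self, toy9):
        spec = EnsembleSpec(n_poses=8, chi_sigma_deg=20.0, seed=9)
        ens = make_ensemble(toy9[1], spec)
        r1 = run_consensus(ens)
        r2 = run_consensus(ens)
        assert r1.selected_index == r2.selected_index
        np.testing.assert_array_equal(r1.rmsd_matrix, r2.rmsd_matrix)
        np.testing.assert_array_equal(r1.row_means, r2.row_means)


class TestEnsembleIO:
    def test_load_from_directory_and_csv(self, tmp_path, toy9):
        ens = _ensemble_from(toy9[1], [-10.0, -8.0, -6.0])
        rows = ["run_index,binding_energy"]
        for pose in ens.poses:
            write_pdb(pose.coords, tmp_path / f"pose_{pose.run_index}.pdb")
            rows.append(f"{pose.run_index},{pose.binding_energy}")
        csv_path = tmp_path / "energies.csv"
        csv_path.write_text("\n".join(rows) + "\n")
        loaded = load_ensemble(tmp_path, csv_path)
        assert len(loaded) == 3
        assert loaded.binding_energies().tolist() == [-10.0, -8.0, -6.0]
        result = run_consensus(loaded)
        assert result.cutoff == -8.0
        assert result.selected_index in result.retained_indices
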