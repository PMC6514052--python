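"""PCA, quasi-harmonic entropy and gromos clustering."""

import numpy as np
import pytest

from conftest import trajectory_from_coords
from lbdkit.ensembles import (
    atom_mode_amplitudes, cartesian_pca, distance_feature_matrix, gromos_cluster,
    harmonic_mode_entropy, pairwise_rmsd_matrix, pca, quasiharmonic_entropy,
)
from lbdkit.errors import ConfigurationError, InsufficientDataError
from lbdkit.structio import SelectionMask
from lbdkit.synthetic import SyntheticSpec, make_gaussian_ensemble, make_transition_trajectory
from oracles import (
    greedy_cluster_reference, harmonic_entropy_closed_form,
    nested_loop_distance_features, quaternion_rmsd_matrix, random_rotation,
)


def full_mask(n):
    return SelectionMask(tuple(range(n)))


class TestDistanceFeatures:
    def test_column_count_and_brute_force_agreement(self, rng):
        coords = rng.normal(size=(5, 7, 3))
        traj = trajectory_from_coords(coords)
        feats = distance_feature_matrix(traj, full_mask(7))
        assert feats.shape == (5, 21)
        assert np.allclose(feats, nested_loop_distance_features(coords), atol=1e-12)

    def test_rigid_copies_give_identical_rows(self, rng):
        base = rng.normal(size=(6, 3))
        rot = random_rotation(rng)
        coords = np.stack([base, base @ rot.T + 2.0])
        traj = trajectory_from_coords(coords)
        feats = distance_feature_matrix(traj, full_mask(6))
        assert np.allclose(feats[0], feats[1], atol=1e-12)

    def test_stride_and_validation(self, rng):
        traj = trajectory_from_coords(rng.normal(size=(10, 4, 3)))
        assert distance_feature_matrix(traj, full_mask(4), stride=3).shape[0] == 4
        with pytest.raises(ConfigurationError):
            distance_feature_matrix(traj, full_mask(4), stride=0)


class TestPCA:
    def test_single_axis_data_explains_all_variance(self, rng):
        x = np.zeros((50, 4))
        x[:, 2] = rng.normal(size=50)
        result = pca(x, n_components=2)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        x = rng.normal(size=(40, 6)) * rng.uniform(0.1, 2.0, size=6)
        result = pca(x, n_components=3)
        total = np.var(x, axis=0, ddof=1).sum()
        assert result.eigenvalues.sum() == pytest.approx(total, rel=1e-10)

    def test_isotropic_gaussian_eigenvalue_ratio_near_one(self, rng):
        x = rng.normal(size=(20000, 2))
        result = pca(x, n_components=2)
        ratio = result.eigenvalues[0] / result.eigenvalues[1]
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_matches_sklearn_up_to_convention(self, rng):
        sk = pytest.importorskip("sklearn.decomposition")
        x = rng.normal(size=(30, 8)) * rng.uniform(0.5, 3.0, size=8)
        ours = pca(x, n_components=3)
        ref = sk.PCA(n_components=3).fit(x)
        assert ours.eigenvalues[:3] == pytest.approx(
            ref.explained_variance_, rel=1e-9)
        for k in range(3):
            dot = abs(np.dot(ours.eigenvectors[k], ref.components_[k]))
            assert dot == pytest.approx(1.0, abs=1e-9)

    def test_two_state_trajectory_pc1_separates_planted_labels(self):
        spec = SyntheticSpec(n_frames=100, noise_sigma=0.02,
                             stage_schedule=[(0, 0, 0.0), (50, 50, 1.0)])
        traj, refs, truth = make_transition_trajectory(spec)
        feats = distance_feature_matrix(traj, refs.mask_traj)
        result = pca(feats, n_components=1)
        labels = truth.state_fraction > 0.5
        signs = result.projections[:, 0] > 0
        accuracy = max(np.mean(signs == labels), np.mean(signs != labels))
        assert accuracy == 1.0

    def test_insufficient_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            pca(np.zeros((1, 5)))


class TestCartesianPCA:
    def test_static_trajectory_all_zero_eigenvalues(self, rng):
        base = rng.normal(size=(5, 3))
        traj = trajectory_from_coords(np.stack([base] * 6))
        result = cartesian_pca(traj, full_mask(5))
        assert np.all(result.eigenvalues < 1e-20)

    def test_oscillating_atom_mode_localised(self):
        base = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2, 0], [2.0, 2, 0],
                         [1.0, 1, 2]])
        frames = []
        for k in range(10):
            c = base.copy()
            c[4, 2] += 0.05 * (1 if k % 2 == 0 else -1)
            frames.append(c)
        traj = trajectory_from_coords(np.stack(frames))
        result = cartesian_pca(traj, full_mask(5), n_components=1)
        amp = atom_mode_amplitudes(result, 0)
        assert np.argmax(amp) == 4
        # superposition removes net translation, so the 4 static atoms pick
        # up 1/5 of the motion each; the driven atom keeps 4x their amplitude
        assert amp[4] > 3.5 * amp[:4].max()

    def test_transition_modes_largest_on_mobile_helix(self):
        spec = SyntheticSpec(n_frames=60, noise_sigma=0.005,
                             stage_schedule=[(0, 59, 1.0)])
        traj, refs, _ = make_transition_trajectory(spec)
        result = cartesian_pca(traj, refs.mask_traj, n_components=1)
        amp = atom_mode_amplitudes(result, 0)
        displacement = np.linalg.norm(
            refs.closed_coords - refs.open_coords, axis=1)
        # top-10 amplitude atoms should be among the genuinely moving atoms
        top = np.argsort(amp)[-10:]
        assert np.all(displacement[top] > 0.1)


class TestEntropy:
    def test_zero_variance_ensemble_gives_zero(self, rng):
        base = rng.normal(size=(4, 3))
        traj = trajectory_from_coords(np.stack([base] * 10))
        result = quasiharmonic_entropy(traj, full_mask(4), superpose=False)
        assert result.total == 0.0
        assert result.n_modes_discarded == 12

    def test_recovers_prescribed_spectrum_closed_form(self):
        lam = np.linspace(0.002, 0.05, 24)
        masses = np.linspace(10.0, 16.0, 8)
        traj, closed_form = make_gaussian_ensemble(lam, masses,
                                                   n_frames=8000, seed=11)
        mask = full_mask(8)
        est = quasiharmonic_entropy(traj, mask, superpose=False)
        oracle = harmonic_entropy_closed_form(lam, 300.0, "quasiharmonic")
        assert closed_form["quasiharmonic"] == pytest.approx(oracle, rel=1e-10)
        assert est.total == pytest.approx(oracle, rel=0.02)

    def test_schlitter_upper_bounds_quasiharmonic(self):
        lam = np.geomspace(0.001, 0.1, 12)
        masses = np.full(4, 12.011)
        traj, _ = make_gaussian_ensemble(lam, masses, n_frames=3000, seed=5)
        mask = full_mask(4)
        qh = quasiharmonic_entropy(traj, mask, superpose=False)
        sch = quasiharmonic_entropy(traj, mask, method="schlitter",
                                    superpose=False)
        assert sch.total >= qh.total

    def test_monotone_under_covariance_inflation(self):
        lam = np.linspace(0.005, 0.02, 9)
        a = harmonic_mode_entropy(lam, 300.0).total
        b = harmonic_mode_entropy(4.0 * lam, 300.0).total
        assert b > a

    def test_rigid_transform_invariance(self, rng):
        coords = rng.normal(size=(200, 5, 3)) * 0.05 + rng.normal(size=(5, 3))
        traj = trajectory_from_coords(coords)
        rot = random_rotation(rng)
        moved = trajectory_from_coords(coords @ rot.T + 3.0)
        mask = full_mask(5)
        s1 = quasiharmonic_entropy(traj, mask)
        s2 = quasiharmonic_entropy(moved, mask)
        assert s1.total == pytest.approx(s2.total, rel=1e-6)

    def test_invalid_temperature_rejected(self, rng):
        traj = trajectory_from_coords(rng.normal(size=(5, 3, 3)))
        with pytest.raises(ConfigurationError):
            quasiharmonic_entropy(traj, full_mask(3), temperature=-1.0)


class TestGromosClustering:
    def test_identical_frames_form_one_cluster(self, rng):
        base = rng.normal(size=(5, 3))
        traj = trajectory_from_coords(np.stack([base] * 7))
        result = gromos_cluster(traj, full_mask(5), cutoff=0.2)
        assert result.n_clusters == 1
        assert result.sizes.tolist() == [7]

    def test_two_separated_bundles_recovered(self, rng):
        a = rng.normal(size=(6, 3))
        b = a + np.array([5.0, 1.0, -2.0]) + rng.normal(size=(6, 3)) * 0.5
        coords = np.stack(
            [a + rng.normal(size=(6, 3)) * 0.01 for _ in range(8)]
            + [b + rng.normal(size=(6, 3)) * 0.01 for _ in range(5)]
        )
        traj = trajectory_from_coords(coords)
        result = gromos_cluster(traj, full_mask(6), cutoff=0.2)
        assert result.n_clusters == 2
        assert result.sizes.tolist() == [8, 5]
        assert len(set(result.assignment[:8])) == 1
        assert len(set(result.assignment[8:])) == 1

    def test_cutoff_above_diameter_gives_one_cluster(self, rng):
        traj = trajectory_from_coords(rng.normal(size=(10, 4, 3)) * 0.01)
        result = gromos_cluster(traj, full_mask(4), cutoff=100.0)
        assert result.n_clusters == 1

    def test_matches_reference_implementation_with_ties(self, rng):
        # duplicated frames create exact neighbour-count ties
        base = rng.normal(size=(5, 3))
        coords = np.stack(
            [base + rng.normal(size=(5, 3)) * 0.05 for _ in range(15)])
        coords[7] = coords[3]
        coords[12] = coords[1]
        traj = trajectory_from_coords(coords)
        mat = quaternion_rmsd_matrix(coords)
        for cutoff in (0.05, 0.1, 0.2):
            ours = gromos_cluster(traj, full_mask(5), cutoff=cutoff)
            ref_assign, ref_medoids, ref_sizes = greedy_cluster_reference(
                mat, cutoff)
            assert np.array_equal(ours.assignment, ref_assign)
            assert np.array_equal(ours.medoids, ref_medoids)
            assert np.array_equal(ours.sizes, ref_sizes)

    def test_sizes_non_increasing_and_partition(self, rng):
        coords = rng.normal(size=(30, 4, 3)) * 0.3
        traj = trajectory_from_coords(coords)
        result = gromos_cluster(traj, full_mask(4), cutoff=0.25)
        assert np.all(np.diff(result.sizes) <= 0)
        assert result.sizes.sum() == 30
        assert np.all(result.assignment >= 0)
        for cid, medoid in enumerate(result.medoids):
            assert result.assignment[medoid] == cid

    def test_empty_trajectory_rejected(self, rng):
        traj = trajectory_from_coords(np.zeros((0, 4, 3)))
        with pytest.raises(InsufficientDataError):
            gromos_cluster(traj, full_mask(4), cutoff=0.2)
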