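"""Shared-basis PCA, microstate clustering, medoids, histograms,
cluster-center RMSD."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

import microswitch as ms
from microswitch.microstates import (
    ProjectedScores,
    cluster_center_rmsd,
    histogram2d,
    medoid_frame,
    oblique_histogram,
    shared_edges,
)
from microswitch.trajio import BackboneMatrix


def matrix_from(frames, label="apo"):
    n = frames.shape[0]
    return BackboneMatrix(
        frame_rows=frames.reshape(n, -1),
        atom_index=[(i // 3, "NCAC"[0]) for i in range(frames.shape[1])],
        labels=pd.DataFrame({"label": [label] * n, "replica": 0, "frame": range(n)}),
    )


def scores_from(arr, label="apo"):
    arr = np.asarray(arr, float)
    return ProjectedScores(
        scores=arr,
        labels=pd.DataFrame(
            {"label": [label] * len(arr), "replica": 0, "frame": range(len(arr))}
        ),
    )


class TestFitSharedPCA:
    def test_identical_frames_have_zero_variance(self):
        frames = np.tile(np.random.default_rng(0).normal(size=(1, 6, 3)), (10, 1, 1))
        model = ms.fit_shared_pca(matrix_from(frames), 4)
        assert np.allclose(model.explained_variance, 0.0, atol=1e-12)

    def test_two_distinct_frames_are_rank_one(self, rng):
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(size=(6, 3))
        model = ms.fit_shared_pca(matrix_from(np.stack([a, b])), 3)
        assert model.explained_variance[0] > 1e-6
        assert np.allclose(model.explained_variance[1:], 0.0, atol=1e-10)
        diff = (b - a).ravel()
        cos = model.components[0] @ diff / np.linalg.norm(diff)
        assert abs(cos) == pytest.approx(1.0, abs=1e-9)

    def test_two_blob_axis_recovery(self, rng):
        axis = np.zeros(18)
        axis[3] = 1.0  # displacement of one atom along x
        base = rng.normal(size=18)
        frames = base + 4.0 * axis * rng.choice([0, 1], 500)[:, None]
        frames = frames + rng.normal(scale=0.05, size=frames.shape)
        model = ms.fit_shared_pca(matrix_from(frames.reshape(500, 6, 3)), 3)
        assert abs(model.components[0] @ axis) >= 0.99

    def test_variances_non_increasing(self, rng):
        frames = rng.normal(size=(100, 8, 3))
        model = ms.fit_shared_pca(matrix_from(frames), 10)
        assert np.all(np.diff(model.explained_variance) <= 1e-9)

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            ms.fit_shared_pca(matrix_from(rng.normal(size=(1, 4, 3))), 2)

    def test_sign_convention_deterministic(self, rng):
        frames = rng.normal(size=(50, 5, 3))
        m1 = ms.fit_shared_pca(matrix_from(frames), 4)
        m2 = ms.fit_shared_pca(matrix_from(frames.copy()), 4)
        assert np.array_equal(m1.components, m2.components)
        for comp in m1.components:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestProject:
    def test_mean_frame_projects_to_zero(self, rng):
        frames = rng.normal(size=(40, 5, 3))
        mat = matrix_from(frames)
        model = ms.fit_shared_pca(mat, 4)
        mean_mat = matrix_from(mat.frame_rows.mean(axis=0).reshape(1, 5, 3))
        sc = ms.project(model, mean_mat)
        assert np.allclose(sc.scores, 0.0, atol=1e-9)

    def test_training_variance_recovered(self, rng):
        frames = rng.normal(size=(200, 5, 3))
        mat = matrix_from(frames)
        model = ms.fit_shared_pca(mat, 5)
        sc = ms.project(model, mat)
        assert np.allclose(sc.scores.var(axis=0, ddof=1), model.explained_variance, rtol=1e-9)

    def test_column_mismatch_rejected(self, rng):
        model = ms.fit_shared_pca(matrix_from(rng.normal(size=(10, 5, 3))), 3)
        with pytest.raises(ValueError):
            ms.project(model, matrix_from(rng.normal(size=(10, 4, 3))))

    def test_unsuperposed_rotations_scatter_scores(self, rng):
        # documents why superposition must precede projection: a rigid
        # rotation moves a frame far from its superposed image in PC space
        frames = rng.normal(scale=2.0, size=(50, 6, 3))
        mat = matrix_from(frames)
        model = ms.fit_shared_pca(mat, 3)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        rotated = matrix_from(frames @ rot.T)
        sc_plain = ms.project(model, mat)
        sc_rot = ms.project(model, rotated)
        from microswitch.trajio import superpose

        sc_fit = ms.project(model, superpose(rotated, reference=0))
        d_rot = np.linalg.norm(sc_rot.scores - sc_plain.scores, axis=1)
        assert d_rot.mean() > 1.0  # rotated copies project elsewhere

    def test_shared_basis_independent_of_other_ensembles(self, rng):
        frames_a = rng.normal(size=(30, 5, 3))
        frames_b = rng.normal(size=(30, 5, 3))
        pooled = matrix_from(np.concatenate([frames_a, frames_b]))
        model = ms.fit_shared_pca(pooled, 4)
        alone = ms.project(model, matrix_from(frames_a)).scores
        with_b = ms.project(model, pooled).scores[:30]
        assert np.array_equal(alone, with_b)


class TestClusterEnsemble:
    def blobs(self, rng, centers, n_per=200, scale=0.05):
        pts, labels = [], []
        for i, c in enumerate(centers):
            pts.append(c + rng.normal(scale=scale, size=(n_per, len(c))))
            labels += [i] * n_per
        x = np.concatenate(pts)
        perm = rng.permutation(len(x))
        return x[perm], np.array(labels)[perm]

    def test_five_blobs_recovered(self, rng):
        centers = np.eye(5) * 4.0
        x, truth = self.blobs(rng, centers)
        a = ms.cluster_ensemble(scores_from(x), k_range=(4, 5, 6), n_dims=5, seed=0)
        assert a.k == 5
        assert adjusted_rand_score(truth, a.assignments) == 1.0
        assert a.populations.sum() == pytest.approx(100.0, abs=1e-9)

    def test_forced_single_cluster(self, rng):
        x, _ = self.blobs(rng, [np.zeros(3)])
        a = ms.cluster_ensemble(scores_from(x), k_range=(1,), n_dims=3, seed=0)
        assert a.k == 1 and a.populations[0] == pytest.approx(100.0)

    def test_permutation_gives_same_partition(self, rng):
        x, _ = self.blobs(rng, np.eye(4) * 5.0)
        sc = scores_from(x)
        a = ms.cluster_ensemble(sc, k_range=(4,), n_dims=4, seed=0)
        perm = rng.permutation(len(x))
        sc_p = ProjectedScores(x[perm], sc.labels.iloc[perm].reset_index(drop=True))
        b = ms.cluster_ensemble(sc_p, k_range=(4,), n_dims=4, seed=0)
        assert np.array_equal(a.assignments[perm], b.assignments)

    def test_mixed_labels_rejected(self, rng):
        sc = ProjectedScores(
            rng.normal(size=(10, 2)),
            pd.DataFrame({"label": ["a"] * 5 + ["b"] * 5, "replica": 0, "frame": range(10)}),
        )
        with pytest.raises(ValueError):
            ms.cluster_ensemble(sc, k_range=(2,), n_dims=2)

    def test_fewer_frames_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            ms.cluster_ensemble(scores_from(rng.normal(size=(3, 2))), k_range=(4,), n_dims=2)


class TestMedoid:
    def test_frame_at_center_is_medoid(self, rng):
        x = np.vstack([np.zeros(2), rng.normal(scale=2.0, size=(50, 2))])
        a = ms.cluster_ensemble(scores_from(x), k_range=(1,), n_dims=2, seed=0)
        center_shift = np.linalg.norm(x - x.mean(0), axis=1)
        expect = int(np.argmin(center_shift))
        assert a.medoids[0][1] == expect

    def test_tie_broken_toward_lower_index(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        a = ms.cluster_ensemble(scores_from(x), k_range=(1,), n_dims=2, seed=0)
        assert a.medoids[0] == (0, 0)

    def test_matches_bruteforce_distance_scan(self, rng):
        x = np.concatenate(
            [rng.normal(loc=c, scale=0.3, size=(100, 3)) for c in (np.zeros(3), np.ones(3) * 5)]
        )
        sc = scores_from(x)
        a = ms.cluster_ensemble(sc, k_range=(2,), n_dims=3, seed=0)
        for c in range(2):
            idx = np.flatnonzero(a.assignments == c)
            d = np.linalg.norm(x[idx] - a.centers[c, :3], axis=1)
            assert a.medoids[c][1] == idx[np.argmin(d)]
            # blob medoid lies within 3 sigma of the blob center
            assert d.min() <= 3 * 0.3


class TestHistograms:
    def test_point_mass_single_bin(self):
        sc = scores_from(np.tile([[0.5, 0.5]], (30, 1)))
        h, _, _ = histogram2d(sc, bins=10, normalized=True)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)
        assert (h > 0).sum() == 1

    def test_normalization_conserves_mass(self, rng):
        sc = scores_from(rng.normal(size=(500, 2)))
        h, _, _ = histogram2d(sc, bins=25, normalized=True)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)

    def test_per_ensemble_histograms_sum_to_pooled(self, rng):
        a = rng.normal(size=(300, 2))
        b = rng.normal(loc=2.0, size=(200, 2))
        sa, sb = scores_from(a, "A"), scores_from(b, "B")
        pooled = scores_from(np.concatenate([a, b]))
        edges = shared_edges([sa, sb])
        ha, _, _ = histogram2d(sa, bins=edges)
        hb, _, _ = histogram2d(sb, bins=edges)
        hp, _, _ = histogram2d(pooled, bins=edges)
        assert np.array_equal(ha + hb, hp)

    def test_empty_selection_rejected(self):
        sc = scores_from(np.empty((0, 2)))
        with pytest.raises(ValueError):
            histogram2d(sc)


class TestObliqueHistogram:
    def test_zero_angle_equals_pc0(self, rng):
        sc = scores_from(rng.normal(size=(400, 2)))
        edges = np.linspace(-4, 4, 40)
        h0, _ = oblique_histogram(sc, 0.0, bins=edges)
        hx, _ = np.histogram(sc.scores[:, 0], bins=edges)
        assert np.array_equal(h0, hx)

    def test_ninety_degrees_equals_pc1(self, rng):
        sc = scores_from(rng.normal(size=(400, 2)))
        edges = np.linspace(-4, 4, 40)
        h, _ = oblique_histogram(sc, 90.0, bins=edges)
        hy, _ = np.histogram(sc.scores[:, 1], bins=edges)
        assert np.array_equal(h, hy)

    def test_rotation_equivariance(self, rng):
        theta = 60.0
        x = rng.normal(size=(500, 2))
        t = np.radians(theta)
        rot = np.array([[np.cos(-t), -np.sin(-t)], [np.sin(-t), np.cos(-t)]])
        edges = np.linspace(-5, 5, 60)
        direct, _ = oblique_histogram(scores_from(x), theta, bins=edges)
        rotated, _ = oblique_histogram(scores_from(x @ rot.T), 0.0, bins=edges)
        assert np.array_equal(direct, rotated)


class TestClusterCenterRMSD:
    def test_diagonal_zero_and_symmetric(self, rng):
        frames = rng.normal(size=(60, 5, 3))
        mat = matrix_from(frames)
        model = ms.fit_shared_pca(mat, 4)
        sc = ms.project(model, mat)
        a = ms.cluster_ensemble(sc, k_range=(2,), n_dims=2, seed=0)
        m, names = cluster_center_rmsd([a], model)
        assert np.allclose(np.diag(m), 0.0)
        assert np.allclose(m, m.T)
        assert len(names) == 2

    def test_rigid_partial_displacement_value(self, rng):
        # Two ensembles offset by d on m of M atoms. After least-squares
        # fitting (translation + rotation), the best achievable RMSD for a
        # translation-only displacement is d*sqrt(r(1-r)), r=m/M; verified
        # against an independent brute-force superposition (scipy).
        from scipy.spatial.transform import Rotation as R

        M, m, d = 12, 3, 2.0
        base = rng.normal(scale=5.0, size=(M, 3))
        moved = base.copy()
        moved[:m, 0] += d
        noise_a = base + rng.normal(scale=0.01, size=(40, M, 3))
        noise_b = moved + rng.normal(scale=0.01, size=(40, M, 3))
        mat = BackboneMatrix(
            frame_rows=np.concatenate([noise_a, noise_b]).reshape(80, -1),
            atom_index=[(i // 3, "N") for i in range(M)],
            labels=pd.DataFrame(
                {"label": ["A"] * 40 + ["B"] * 40, "replica": 0, "frame": list(range(40)) * 2}
            ),
        )
        model = ms.fit_shared_pca(mat, 6)
        sc = ms.project(model, mat)
        aa = ms.cluster_ensemble(sc.subset("A"), k_range=(1,), n_dims=2, seed=0)
        ab = ms.cluster_ensemble(sc.subset("B"), k_range=(1,), n_dims=2, seed=0)
        mrmsd, _ = cluster_center_rmsd([aa, ab], model)

        # independent oracle: back-project and superpose with scipy
        ca = (model.mean + aa.centers[0] @ model.components).reshape(M, 3)
        cb = (model.mean + ab.centers[0] @ model.components).reshape(M, 3)
        rot, rssd = R.align_vectors(ca - ca.mean(0), cb - cb.mean(0))
        oracle = rssd / np.sqrt(M)
        r = m / M
        expected = d * np.sqrt(r * (1 - r))
        assert mrmsd[0, 1] == pytest.approx(oracle, rel=1e-6)
        assert mrmsd[0, 1] == pytest.approx(expected, rel=0.05)

    def test_rotated_center_pair_is_zero(self, rng):
        # identical conformations differing by a rigid rotation fit to zero
        from microswitch._geom import pairwise_rmsd

        base = rng.normal(size=(8, 3))
        rot = Rotation.random(random_state=4).as_matrix()
        assert pairwise_rmsd(base, base @ rot.T) < 1e-9
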