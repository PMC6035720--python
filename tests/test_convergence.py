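"""Ensemble-overlap metrics: RMSD, affinity propagation, JSD, PCA, RMSIP."""

import numpy as np
import pytest

import ensemref as er
from ensemref.convergence import cluster_occupancies


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class TestRmsdMatrix:
    def test_diagonal_zero_and_symmetry(self, small_ensemble):
        D = er.rmsd_matrix(small_ensemble)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)
        np.testing.assert_allclose(D, D.T)

    def test_rigid_rotation_gives_zero(self, small_ensemble, rng):
        frame = small_ensemble.coords[0]
        rotated = frame @ random_rotation(rng).T + [0.5, -1.0, 2.0]
        ens = er.Ensemble(np.stack([frame, rotated]),
                          small_ensemble.atom_names,
                          small_ensemble.residue_indices,
                          small_ensemble.residue_names,
                          small_ensemble.masses)
        assert er.rmsd_matrix(ens)[0, 1] < 1e-6

    def test_single_atom_displacement_formula(self):
        """Without re-superposition a single-atom shift of d gives
        RMSD = d/sqrt(N); best-fit can only reduce it."""
        n, d = 8, 0.1
        rng = np.random.default_rng(0)
        a = rng.normal(size=(n, 3))
        b = a.copy()
        b[3, 0] += d
        ens = er.Ensemble(np.stack([a, b]), ["CA"] * n, np.arange(1, n + 1),
                          ["UNK"] * n, np.ones(n))
        raw = er.rmsd_matrix(ens, superpose=False)[0, 1]
        assert raw == pytest.approx(d / np.sqrt(n), rel=1e-12)
        assert er.rmsd_matrix(ens)[0, 1] <= raw + 1e-12

    def test_agrees_with_mdtraj(self, small_ensemble):
        mdtraj = pytest.importorskip("mdtraj")
        n = small_ensemble.n_atoms
        top = mdtraj.Topology()
        chain = top.add_chain()
        prev = None
        for i in range(n):
            res = top.add_residue("GLY", chain)
            top.add_atom("CA", mdtraj.element.carbon, res)
        traj = mdtraj.Trajectory(small_ensemble.coords.copy(), top)
        ref = np.stack([mdtraj.rmsd(traj, traj, frame=i)
                        for i in range(small_ensemble.n_frames)])
        D = er.rmsd_matrix(small_ensemble, atom_selection="CA")
        assert np.abs(D - ref).max() < 1e-4


class TestAffinityPropagation:
    def test_single_point(self):
        model = er.affinity_propagation(np.array([[0.0]]))
        assert model.n_clusters == 1
        assert model.labels.tolist() == [0]
        assert model.exemplars.tolist() == [0]

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        pts = np.concatenate([rng.normal(0, 0.05, (20, 2)),
                              rng.normal(5, 0.05, (20, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        model = er.affinity_propagation(-D, preference="median")
        assert model.n_clusters == 2
        assert len(set(model.labels[:20])) == 1
        assert len(set(model.labels[20:])) == 1
        assert set(model.labels[:20]) != set(model.labels[20:])
        # exemplars belong to their own cluster
        for k, e in enumerate(model.exemplars):
            assert model.labels[e] == k

    def test_matches_reference_implementation(self):
        """Label agreement with sklearn's AP on random 30-point problems."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        from sklearn.metrics import adjusted_rand_score

        for seed in range(3):
            rng = np.random.default_rng(seed)
            S = rng.standard_normal((30, 30))
            S = (S + S.T) / 2
            pref = float(np.median(S[~np.eye(30, dtype=bool)]))
            mine = er.affinity_propagation(S, preference=pref, damping=0.9)
            ref = sklearn_cluster.AffinityPropagation(
                affinity="precomputed", preference=pref, damping=0.9,
                max_iter=1000, convergence_iter=50, random_state=0).fit(S)
            assert adjusted_rand_score(mine.labels, ref.labels_) == 1.0

    def test_preference_monotone_in_cluster_count(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(25, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        counts = [er.affinity_propagation(-D, preference=p).n_clusters
                  for p in (-60.0, -20.0, -5.0, -1.0)]
        assert counts == sorted(counts)

    def test_bad_damping_rejected(self):
        with pytest.raises(ValueError, match="damping"):
            er.affinity_propagation(np.zeros((3, 3)), damping=0.3)


class TestJsDivergence:
    def test_identical_ensembles_give_exact_zero(self):
        labels = np.array([0, 0, 1, 2, 1])
        assert er.js_divergence(labels, labels.copy()) == 0.0

    def test_disjoint_occupancies_reach_ln2(self):
        a = np.zeros(40, dtype=int)
        b = np.ones(40, dtype=int)
        assert er.js_divergence(a, b) == pytest.approx(np.log(2), rel=1e-12)

    def test_hand_computed_value(self):
        # P = (1/2, 1/2), Q = (1, 0) -> about 0.2158 nats
        a = np.array([0, 1])
        b = np.array([0, 0])
        assert er.js_divergence(a, b) == pytest.approx(0.21576, abs=1e-4)

    def test_symmetric_bounded_and_relabel_invariant(self, rng):
        a = rng.integers(0, 4, size=50)
        b = rng.integers(0, 4, size=70)
        js = er.js_divergence(a, b)
        assert 0.0 <= js <= np.log(2) + 1e-12
        assert er.js_divergence(b, a) == pytest.approx(js, rel=1e-12)
        perm = np.array([2, 0, 3, 1])
        assert er.js_divergence(perm[a], perm[b]) == pytest.approx(js, rel=1e-10)

    def test_base_two_option(self):
        a, b = np.zeros(10, dtype=int), np.ones(10, dtype=int)
        assert er.js_divergence(a, b, base=2) == pytest.approx(1.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            er.js_divergence(np.array([], dtype=int), np.array([0]))

    def test_occupancies_normalized(self):
        occ = cluster_occupancies(np.array([0, 0, 2]), 3)
        np.testing.assert_allclose(occ, [2 / 3, 0, 1 / 3])


class TestPcaRmsip:
    def test_identical_frames_zero_variance(self, small_ensemble):
        coords = np.repeat(small_ensemble.coords[:1], 12, axis=0)
        ens = er.Ensemble(coords, small_ensemble.atom_names,
                          small_ensemble.residue_indices,
                          small_ensemble.residue_names, small_ensemble.masses)
        modes = er.pca_modes(ens, n_modes=3)
        np.testing.assert_allclose(modes.eigenvalues, 0.0, atol=1e-12)

    def test_rank_one_variation(self):
        """Frames displaced along one direction leave a single mode."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 3))
        direction = np.zeros((5, 3))
        direction[2] = [1.0, 0.0, 0.0]
        amp = rng.normal(size=12)
        coords = base[None] + amp[:, None, None] * direction[None]
        ens = er.Ensemble(coords, ["CA"] * 5, np.arange(1, 6), ["UNK"] * 5,
                          np.ones(5))
        modes = er.pca_modes(ens, n_modes=4)
        assert modes.eigenvalues[0] > 1e-4
        # alignment mixes in slightly; the spectrum must stay rank-one
        assert modes.eigenvalues[1] < 1e-2 * modes.eigenvalues[0]

    def test_eigenvalue_sum_equals_total_variance(self, small_ensemble):
        sel = small_ensemble.select("CA")
        n_modes = 3 * len(sel)
        modes = er.pca_modes(small_ensemble, n_modes=min(
            n_modes, small_ensemble.n_frames - 1))
        aligned = er.superpose_ensemble(small_ensemble, atom_selection=sel)
        X = aligned.coords[:, sel].reshape(small_ensemble.n_frames, -1)
        total = np.sum(np.var(X, axis=0, ddof=1))
        assert modes.total_variance == pytest.approx(total, rel=1e-10)

    def test_too_few_frames_rejected(self, small_ensemble):
        with pytest.raises(ValueError, match="frames"):
            er.pca_modes(small_ensemble, n_modes=small_ensemble.n_frames)

    def test_rmsip_self_is_one(self, small_ensemble):
        modes = er.pca_modes(small_ensemble, n_modes=10)
        assert er.rmsip(modes, modes, n=10) == pytest.approx(1.0, abs=1e-10)

    def test_rmsip_orthogonal_subspaces(self):
        dim = 40
        eye = np.eye(dim)
        a = er.SubspaceModes(eye[:10], np.ones(10), 10.0)
        b = er.SubspaceModes(eye[10:20], np.ones(10), 10.0)
        assert er.rmsip(a, b, n=10) == pytest.approx(0.0, abs=1e-12)

    def test_rmsip_single_mode_angle(self):
        v = np.zeros((1, 6))
        w = np.zeros((1, 6))
        v[0, 0] = 1.0
        w[0, 0], w[0, 1] = np.cos(np.pi / 3), np.sin(np.pi / 3)
        a = er.SubspaceModes(v, np.ones(1), 1.0)
        b = er.SubspaceModes(w, np.ones(1), 1.0)
        assert er.rmsip(a, b, n=1) == pytest.approx(0.5, rel=1e-12)

    def test_rmsip_invariant_under_subspace_rotation(self, small_ensemble, rng):
        modes = er.pca_modes(small_ensemble, n_modes=4)
        other = er.pca_modes(small_ensemble.subset_frames(slice(0, 10)),
                             n_modes=4)
        base = er.rmsip(modes, other, n=4)
        # rotate the retained basis of one set by a random orthogonal matrix
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        rotated = er.SubspaceModes(q @ modes.vectors, modes.eigenvalues,
                                   modes.total_variance)
        assert er.rmsip(rotated, other, n=4) == pytest.approx(base, rel=1e-10)
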