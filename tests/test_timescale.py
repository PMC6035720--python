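"""Autocorrelation functions, Lipari-Szabo fits, superposition, ensemble S^2."""

import numpy as np
import pytest

import ensemref as er
from ensemref.timescale import _ls_model, kabsch_rotation


def vector_ensemble(vectors):
    """Two-atom ensemble whose bond vector runs through ``vectors``."""
    vectors = np.asarray(vectors, dtype=float)
    coords = np.zeros((len(vectors), 2, 3))
    coords[:, 1] = vectors
    return er.Ensemble(coords, ["N", "H"], np.array([1, 1]), ["ALA"] * 2,
                       np.array([14.0, 1.0]))


class TestBondVectorAcf:
    def test_static_trajectory_stays_at_one(self):
        coords = np.tile(np.array([[0, 0, 0], [0, 0, 1.0]]), (30, 1, 1))
        (acf,) = er.bond_vector_acf(coords, [(0, 1)], max_lag=10)
        np.testing.assert_allclose(acf.values, 1.0, atol=1e-12)

    def test_alternating_orthogonal_orientations(self):
        # vector flips between z and x: odd lags sample P2(0) = -1/2
        vecs = np.array([[0, 0, 1.0], [1.0, 0, 0]] * 20)
        coords = np.zeros((40, 2, 3))
        coords[:, 1] = vecs
        (acf,) = er.bond_vector_acf(coords, [(0, 1)], max_lag=5)
        np.testing.assert_allclose(acf.values[1::2], -0.5, atol=1e-12)
        np.testing.assert_allclose(acf.values[0::2], 1.0, atol=1e-12)

    def test_tumbling_vector_decorrelates(self, rng):
        e = er.simulate_tumbling_vectors(4000, dt=1.0, tau_c=50.0, rng=rng)
        coords = np.zeros((4000, 2, 3))
        coords[:, 1] = e
        (acf,) = er.bond_vector_acf(coords, [(0, 1)], max_lag=600)
        assert acf.values[0] == pytest.approx(1.0)
        assert abs(np.mean(acf.values[-100:])) < 0.1

    def test_zero_length_bond_rejected(self):
        coords = np.zeros((5, 2, 3))
        with pytest.raises(ValueError, match="zero-length"):
            er.bond_vector_acf(coords, [(0, 1)], max_lag=2)

    def test_max_lag_bounded_by_length(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 2] = 1.0
        with pytest.raises(ValueError, match="max_lag"):
            er.bond_vector_acf(coords, [(0, 1)], max_lag=5)


class TestAverageAcfs:
    def test_identity_and_midpoint(self):
        lags = np.arange(5.0)
        one = er.CorrelationFunction(lags, np.ones(5))
        zero = er.CorrelationFunction(lags, np.r_[1.0, np.zeros(4)])
        same = er.average_acfs([one, one])
        np.testing.assert_allclose(same.values, 1.0)
        mid = er.average_acfs([one, zero])
        np.testing.assert_allclose(mid.values[1:], 0.5)
        assert mid.n_traj == 2

    def test_matches_pooled_mean(self, rng):
        lags = np.arange(20.0)
        fns = []
        for _ in range(7):
            v = np.r_[1.0, rng.uniform(-0.4, 0.9, 19)]
            fns.append(er.CorrelationFunction(lags, v))
        avg = er.average_acfs(fns)
        np.testing.assert_allclose(
            avg.values, np.mean([f.values for f in fns], axis=0), rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = er.CorrelationFunction(np.arange(5.0), np.ones(5))
        b = er.CorrelationFunction(np.arange(4.0), np.ones(4))
        with pytest.raises(ValueError, match="grid"):
            er.average_acfs([a, b])


class TestLipariSzaboFit:
    lags = np.arange(0.0, 8000.0, 20.0)

    def make_acf(self, s2, tau_e, tau_c):
        return er.CorrelationFunction(self.lags,
                                      _ls_model(self.lags, s2, tau_e, tau_c))

    def test_noiseless_recovery(self):
        """S^2 = 0.85, tau_e = 50 ps, tau_c = 3000 ps recovered within 0.02."""
        acfs = [self.make_acf(0.85, 50.0, 3000.0),
                self.make_acf(0.70, 30.0, 3000.0)]
        fit = er.fit_lipari_szabo(acfs)
        assert fit.s2[0] == pytest.approx(0.85, abs=0.02)
        assert fit.s2[1] == pytest.approx(0.70, abs=0.02)

    def test_rigid_bond_limit(self):
        acfs = [self.make_acf(1.0, 50.0, 3000.0),
                self.make_acf(1.0, 50.0, 3000.0)]
        fit = er.fit_lipari_szabo(acfs)
        assert np.all(fit.s2 >= 0.99)

    def test_shared_tau_c_recovered(self):
        acfs = [self.make_acf(0.9, 40.0, 3000.0),
                self.make_acf(0.6, 80.0, 3000.0)]
        fit = er.fit_lipari_szabo(acfs)
        assert fit.tau_c == pytest.approx(3000.0, rel=0.05)

    def test_recovery_over_parameter_grid(self):
        """Noiseless model data recovered to < 1% across a small grid."""
        for s2 in (0.3, 0.6, 0.9):
            for tau_e in (20.0, 100.0):
                acfs = [self.make_acf(s2, tau_e, 2500.0),
                        self.make_acf(min(s2 + 0.05, 1.0), tau_e, 2500.0)]
                fit = er.fit_lipari_szabo(acfs)
                assert fit.s2[0] == pytest.approx(s2, rel=0.01, abs=0.005)

    def test_non_decaying_input_flagged(self):
        flat = er.CorrelationFunction(self.lags, np.ones_like(self.lags))
        fit = er.fit_lipari_szabo([flat, flat])
        assert any("non-decaying" in w for w in fit.warnings)

    def test_single_bond_rejected(self):
        with pytest.raises(ValueError, match="2 bonds"):
            er.fit_lipari_szabo([self.make_acf(0.8, 50.0, 3000.0)])


class TestSuperposition:
    def test_rigid_motions_removed(self, small_ensemble, rng):
        frame = small_ensemble.coords[0]
        frames = []
        for _ in range(8):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ])
            frames.append(frame @ R.T + rng.normal(scale=2.0, size=3))
        ens = er.Ensemble(np.array(frames), small_ensemble.atom_names,
                          small_ensemble.residue_indices,
                          small_ensemble.residue_names, small_ensemble.masses)
        aligned = er.superpose_ensemble(ens)
        spread = aligned.coords - aligned.coords.mean(axis=0)
        assert np.sqrt((spread ** 2).mean()) < 1e-6

    def test_idempotent(self, small_ensemble):
        once = er.superpose_ensemble(small_ensemble)
        twice = er.superpose_ensemble(once)
        assert np.abs(twice.coords - once.coords).max() < 1e-6

    def test_kabsch_recovers_known_rotation(self, rng):
        P = rng.normal(size=(12, 3))
        P -= P.mean(axis=0)
        theta = 0.7
        R_true = np.array([[np.cos(theta), -np.sin(theta), 0],
                           [np.sin(theta), np.cos(theta), 0],
                           [0, 0, 1.0]])
        R = kabsch_rotation(P, P @ R_true.T)
        assert np.abs(R - R_true).max() < 1e-10

    def test_collinear_selection_rejected(self):
        coords = np.zeros((3, 4, 3))
        coords[:, :, 2] = np.arange(4)  # all atoms on the z axis
        ens = er.Ensemble(coords, ["CA"] * 4, np.arange(1, 5), ["UNK"] * 4,
                          np.ones(4))
        with pytest.raises(ValueError, match="collinear"):
            er.superpose_ensemble(ens)

    def test_single_frame_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            er.superpose_ensemble(small_ensemble.subset_frames(slice(0, 1)))


class TestEnsembleS2:
    def test_rigid_bond_gives_one(self):
        ens = vector_ensemble([[0, 0, 1.0]] * 10)
        result = er.ensemble_s2(ens, [(0, 1)])
        assert result.s2[0] == pytest.approx(1.0)
        assert result.timescale == "chemical_shift"

    def test_two_orthogonal_orientations_give_quarter(self):
        ens = vector_ensemble([[0, 0, 1.0]] * 5 + [[1.0, 0, 0]] * 5)
        assert er.ensemble_s2(ens, [(0, 1)]).s2[0] == pytest.approx(0.25)

    def test_isotropic_limit(self, rng):
        v = rng.standard_normal((100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert er.ensemble_s2(vector_ensemble(v), [(0, 1)]).s2[0] < 0.01

    def test_frame_order_and_global_rotation_invariance(self, rng):
        v = rng.standard_normal((50, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        base = er.ensemble_s2(vector_ensemble(v), [(0, 1)]).s2[0]
        shuffled = er.ensemble_s2(vector_ensemble(v[::-1]), [(0, 1)]).s2[0]
        theta = 1.1
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        rotated = er.ensemble_s2(vector_ensemble(v @ R.T), [(0, 1)]).s2[0]
        assert shuffled == pytest.approx(base, rel=1e-12)
        assert rotated == pytest.approx(base, rel=1e-10)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            er.ensemble_s2(vector_ensemble([[0, 0, 1.0]]), [(0, 1)])


class TestTwoTimescaleOrdering:
    def test_chemical_shift_s2_below_relaxation_s2_for_two_basins(self, rng):
        """Short trajectories wobble inside one orientation basin (high
        relaxation-timescale S^2); the long-timescale ensemble spans two
        basins, so its S^2 must come out lower."""
        dt, n_steps, tau_c = 2.0, 3000, 400.0
        basins = [np.array([0, 0, 1.0]), np.array([1.0, 0, 0])]
        acfs, pooled = [], []
        for b, basin in enumerate(basins * 2):
            tumble = er.simulate_tumbling_vectors(
                n_steps, dt=dt, tau_c=tau_c,
                rng=np.random.default_rng(100 + b), e0=basin)
            # small fast wobble around the tumbling frame
            wob = 0.15 * np.random.default_rng(200 + b).standard_normal(
                (n_steps, 3))
            e = tumble + wob
            e /= np.linalg.norm(e, axis=1, keepdims=True)
            coords = np.zeros((n_steps, 2, 3))
            coords[:, 1] = e
            acfs.append(er.bond_vector_acf(coords, [(0, 1)],
                                           max_lag=1000, dt=dt)[0])
            # basin-frame (aligned) orientations enter the slow ensemble
            basin_e = basin + wob
            basin_e /= np.linalg.norm(basin_e, axis=1, keepdims=True)
            pooled.append(basin_e[::30])
        fit = er.fit_lipari_szabo([er.average_acfs(acfs[0::2]),
                                   er.average_acfs(acfs[1::2])])
        s2_relax = fit.s2.mean()
        s2_cs = er.ensemble_s2(vector_ensemble(np.concatenate(pooled)),
                               [(0, 1)]).s2[0]
        assert s2_cs < s2_relax - 0.05
        assert s2_relax > 0.7
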