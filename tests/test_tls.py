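"""Rigid-body TLS prediction, fitting and the TLS+ONIOM recombination."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from uriding import (DisplacementTensor, TLSModel, fit_tls, predict_adps,
                     subtract_internal, tls_plus_oniom)
from uriding.tls import _pack


def random_psd(rng, scale):
    a = rng.normal(size=(3, 3)) * scale
    return a @ a.T


def random_model(rng, origin):
    """A random TLS model with S scaled inside the joint PSD bound so it
    corresponds to an actual rigid-body motion."""
    t = random_psd(rng, 0.05)
    l = random_psd(rng, 0.02)
    s = rng.normal(size=(3, 3)) * 1e-4
    s -= np.eye(3) * np.trace(s) / 3.0
    # shrink S until [[T, S^T], [S, L]] is PSD (physical consistency)
    for _ in range(60):
        joint = np.block([[t, s.T], [s, l]])
        if np.linalg.eigvalsh(joint).min() >= 0:
            break
        s *= 0.5
    return TLSModel(T=t, L=l, S=s, origin=origin)


def random_cloud(rng, n=12, spread=3.0):
    pts = rng.normal(scale=spread, size=(n, 3))
    return {f"A{i}": pts[i] for i in range(n)}


class TestPredict:
    def test_pure_translation(self):
        t = np.diag([0.01, 0.02, 0.03])
        model = TLSModel(T=t, L=np.zeros((3, 3)), S=np.zeros((3, 3)),
                         origin=np.zeros(3))
        u = predict_adps(model, {"A": np.array([1.0, 2.0, 3.0])})
        assert np.allclose(u["A"].matrix, t, atol=1e-16)

    def test_libration_axis_invariance(self):
        # libration about z displaces nothing on the z axis through the origin
        l = np.zeros((3, 3))
        l[2, 2] = 1e-3
        t = np.eye(3) * 0.005
        model = TLSModel(T=t, L=l, S=np.zeros((3, 3)), origin=np.zeros(3))
        u = predict_adps(model, {"on": np.array([0.0, 0.0, 4.0]),
                                 "off": np.array([2.0, 0.0, 0.0])})
        assert np.allclose(u["on"].matrix, t, atol=1e-16)
        assert not np.allclose(u["off"].matrix, t, atol=1e-8)

    def test_matches_finite_rotation_monte_carlo(self):
        # independent oracle: sample correlated (t, omega), displace
        # u = t + omega x d, and compare the empirical covariance
        rng = np.random.default_rng(7)
        model = random_model(rng, origin=np.zeros(3))
        joint = np.block([[model.T, model.S.T], [model.S, model.L]])
        positions = {"P1": np.array([1.5, -2.0, 0.7]), "P2": np.array([-0.4, 2.2, 3.1])}
        pred = predict_adps(model, positions)
        samples = rng.multivariate_normal(np.zeros(6), joint, size=400_000)
        t_s, w_s = samples[:, :3], samples[:, 3:]
        for lab, r in positions.items():
            disp = t_s + np.cross(w_s, r)
            emp = disp.T @ disp / len(disp)
            assert np.abs(emp - pred[lab].matrix).max() < 0.01 * np.trace(pred[lab].matrix)


class TestFit:
    def test_forward_then_fit_round_trip(self):
        rng = np.random.default_rng(11)
        positions = random_cloud(rng)
        centroid = np.mean(list(positions.values()), axis=0)
        model = random_model(rng, origin=centroid)
        adps = predict_adps(model, positions)
        report = fit_tls(adps, positions)
        assert np.abs(_pack(report.model) - _pack(model)).max() < 1e-8
        assert report.residual < 1e-10
        assert report.n_observations == 6 * 12 and report.n_parameters == 20

    def test_isotropic_adps_give_pure_t(self):
        rng = np.random.default_rng(3)
        positions = random_cloud(rng, n=8)
        adps = {lab: DisplacementTensor(np.eye(3) * 0.02) for lab in positions}
        report = fit_tls(adps, positions)
        assert np.allclose(report.model.T, np.eye(3) * 0.02, atol=1e-10)
        assert np.abs(report.model.L).max() < 1e-10
        assert np.abs(report.model.S).max() < 1e-10
        assert report.residual < 1e-10

    def test_trace_s_exactly_zero(self):
        rng = np.random.default_rng(5)
        positions = random_cloud(rng)
        model = random_model(rng, origin=np.mean(list(positions.values()), axis=0))
        adps = predict_adps(model, positions)
        # perturb so the fit is not exact
        adps = {lab: DisplacementTensor(u.matrix + 1e-4 * np.eye(3))
                for lab, u in adps.items()}
        report = fit_tls(adps, positions)
        assert np.trace(report.model.S) == 0.0

    def test_residual_rotation_invariant(self):
        rng = np.random.default_rng(13)
        positions = random_cloud(rng)
        model = random_model(rng, origin=np.mean(list(positions.values()), axis=0))
        adps = predict_adps(model, positions)
        noise = {lab: rng.normal(scale=5e-4, size=6) for lab in positions}
        adps = {lab: DisplacementTensor(u.matrix + _sym(noise[lab]))
                for lab, u in adps.items()}
        r1 = fit_tls(adps, positions).residual
        rot = Rotation.from_euler("zxz", [33, 61, -105], degrees=True).as_matrix()
        pos2 = {lab: rot @ p for lab, p in positions.items()}
        adps2 = {lab: DisplacementTensor(rot @ u.matrix @ rot.T)
                 for lab, u in adps.items()}
        r2 = fit_tls(adps2, pos2).residual
        assert abs(r1 - r2) < 1e-9

    def test_collinear_cloud_rejected(self):
        positions = {f"A{i}": np.array([float(i), 0.0, 0.0]) for i in range(6)}
        adps = {lab: DisplacementTensor(np.eye(3) * 0.02) for lab in positions}
        with pytest.raises(ValueError, match="rank"):
            fit_tls(adps, positions)

    def test_too_few_atoms_rejected(self):
        positions = {f"A{i}": np.random.default_rng(1).normal(size=3) for i in range(3)}
        adps = {lab: DisplacementTensor(np.eye(3) * 0.02) for lab in positions}
        with pytest.raises(ValueError, match="at least 4"):
            fit_tls(adps, positions)

    def test_noise_scaling_linear(self):
        # parameter RMSE should scale ~linearly with the noise sd
        rng = np.random.default_rng(17)
        positions = random_cloud(rng)
        centroid = np.mean(list(positions.values()), axis=0)
        model = random_model(rng, origin=centroid)
        clean = predict_adps(model, positions)
        truth = _pack(model)

        def rmse(sigma, replicates=100):
            errs = []
            for _ in range(replicates):
                noisy = {lab: DisplacementTensor(
                    u.matrix + _sym(rng.normal(scale=sigma, size=6)))
                    for lab, u in clean.items()}
                report = fit_tls(noisy, positions)
                errs.append(np.sum((_pack(report.model) - truth) ** 2))
            return np.sqrt(np.mean(errs))

        r1, r2 = rmse(2e-4), rmse(4e-4)
        assert r1 > 0
        assert r2 / r1 == pytest.approx(2.0, rel=0.25)


def _sym(v):
    n11, n22, n33, n12, n13, n23 = v
    return np.array([[n11, n12, n13], [n12, n22, n23], [n13, n23, n33]])


class TestSubtract:
    def test_zero_identity_and_inverse(self):
        rng = np.random.default_rng(2)
        obs = {f"A{i}": DisplacementTensor(random_psd(rng, 0.05)) for i in range(4)}
        zeros = {lab: DisplacementTensor(np.zeros((3, 3))) for lab in obs}
        assert all(np.array_equal(subtract_internal(obs, zeros)[lab].matrix,
                                  obs[lab].matrix) for lab in obs)
        internal = {lab: DisplacementTensor(random_psd(rng, 0.01)) for lab in obs}
        ext = subtract_internal(obs, internal)
        back = {lab: DisplacementTensor(ext[lab].matrix + internal[lab].matrix)
                for lab in obs}
        for lab in obs:
            assert np.abs(back[lab].matrix - obs[lab].matrix).max() < 1e-15

    def test_label_mismatch_fatal(self):
        u = DisplacementTensor(np.eye(3) * 0.01)
        with pytest.raises(ValueError, match="label mismatch"):
            subtract_internal({"A": u}, {"B": u})

    def test_negative_eigenvalue_flagged(self):
        obs = {"A": DisplacementTensor(np.eye(3) * 0.01)}
        internal = {"A": DisplacementTensor(np.diag([0.02, 0.0, 0.0]))}
        with pytest.warns(UserWarning, match="not PSD"):
            out = subtract_internal(obs, internal)
        assert out["A"].matrix[0, 0] == pytest.approx(-0.01)


class TestTlsPlusOniom:
    def test_end_to_end_recovery(self, default_fixture):
        fx = default_fixture
        for temp in (9.0, 100.0, 250.0):
            res = tls_plus_oniom(fx.structures[temp], fx.modes, temp)
            assert res.fit.residual < 1e-10
            for h, truth in fx.truth_h_u[temp].items():
                assert np.abs(res.hydrogen_u[h].matrix - truth.matrix).max() < 1e-9

    def test_all_modes_below_cutoff_gives_pure_tls(self, default_fixture):
        fx = default_fixture
        s = fx.structures[9.0]
        with pytest.warns(UserWarning, match="cutoff"):
            res = tls_plus_oniom(s, fx.modes, 9.0, cutoff=1e5)
        pos = s.cart_positions()
        pred = predict_adps(res.fit.model,
                            {h: pos[h] for h in res.hydrogen_u})
        for h in res.hydrogen_u:
            assert np.abs(res.hydrogen_u[h].matrix - pred[h].matrix).max() < 1e-15

    def test_hydrogen_observations_ignored(self, default_fixture):
        import copy
        fx = default_fixture
        s = copy.deepcopy(fx.structures[9.0])
        res_ref = tls_plus_oniom(fx.structures[9.0], fx.modes, 9.0)
        # corrupt every hydrogen ADP: the fit must not notice
        for atom in s.atoms:
            if atom.is_hydrogen:
                atom.u_cif = DisplacementTensor(np.eye(3) * 0.77, basis="cif")
        res = tls_plus_oniom(s, fx.modes, 9.0)
        assert np.abs(_pack(res.fit.model) - _pack(res_ref.fit.model)).max() < 1e-14
        n_heavy = sum(1 for a in s.atoms if not a.is_hydrogen)
        assert res.fit.n_observations == 6 * n_heavy
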