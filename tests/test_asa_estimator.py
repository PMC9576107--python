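"""ASA direction (eigenproblem), position (regularized LS) and attached frame."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from screwaxis import (
    AngularCovariance,
    AsaConfig,
    PoseSequence,
    ScrewTwist,
    TwistSequence,
    UndefinedAxisError,
    angular_covariance,
    asa_direction,
    asa_frame,
    asa_position,
    common_normal_distance,
    estimate_asa,
)
from screwaxis.synthetic_motions import _rotation_about


def twist_seq(omegas, v0s=None):
    omegas = np.atleast_2d(omegas)
    v0s = np.zeros_like(omegas) if v0s is None else np.atleast_2d(v0s)
    return TwistSequence(
        twists=tuple(ScrewTwist(omega=w, v0=v) for w, v in zip(omegas, v0s))
    )


def sphere_grid_direction(omegas, step_deg=0.5):
    """Exhaustive maximizer of f(n) = mean((w_i . n)^2) over a spherical grid."""
    th = np.deg2rad(np.arange(0.0, 180.0 + step_deg / 2, step_deg))
    ph = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    G = np.stack(
        [np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1
    ).reshape(-1, 3)
    f = np.mean((G @ np.asarray(omegas).T) ** 2, axis=1)
    return G[int(np.argmax(f))]


class TestAngularCovariance:
    def test_repeated_unit_z(self):
        C = angular_covariance(twist_seq([(0, 0, 1), (0, 0, 1)]))
        assert np.allclose(C.C, np.diag([0, 0, 1]))

    def test_diagonal_sum(self):
        C = angular_covariance(twist_seq([(1, 0, 0), (0, 1, 0), (0, 0, 2)]))
        assert np.allclose(C.C, np.diag([1 / 3, 1 / 3, 4 / 3]))

    def test_matches_double_loop_oracle(self, rng):
        W = rng.normal(size=(15, 3))
        C = angular_covariance(twist_seq(W)).C
        acc = np.zeros((3, 3))
        for w in W:
            for a in range(3):
                for b in range(3):
                    acc[a, b] += w[a] * w[b]
        assert np.allclose(C, acc / len(W), atol=1e-12)

    def test_empty_sequence_raises(self):
        from screwaxis import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            angular_covariance(TwistSequence(twists=()))


class TestAsaDirection:
    def test_dominant_axis(self):
        C = AngularCovariance(C=np.diag([0.0, 0.0, 1.0]), N=10)
        assert np.allclose(asa_direction(C, (0, 0, 0.5)), [0, 0, 1])

    def test_sign_follows_mean_omega(self):
        C = AngularCovariance(C=np.diag([4.0, 1.0, 0.25]), N=10)
        assert np.allclose(asa_direction(C, (-1, 0, 0)), [-1, 0, 0])

    def test_all_zero_twists_raise(self):
        C = AngularCovariance(C=np.zeros((3, 3)), N=5)
        with pytest.raises(UndefinedAxisError):
            asa_direction(C, (0, 0, 0))

    def test_matches_spherical_grid_search(self, rng, make_twist_set):
        """Eigenvector solution equals the brute-force grid maximizer."""
        for _ in range(5):
            tws = make_twist_set(rng, n=25)
            C = angular_covariance(tws)
            n_eig = asa_direction(C, np.mean(tws.omegas, axis=0))
            n_grid = sphere_grid_direction(tws.omegas, step_deg=1.0)
            ang = np.degrees(np.arccos(np.clip(abs(np.dot(n_eig, n_grid)), 0, 1)))
            assert ang < 2.0  # within grid resolution


class TestAsaPosition:
    def hinge_twists(self):
        rates = np.array([0.5, 1.0, 1.5, -0.8, 2.0])
        omegas = np.array([[0, 0, w] for w in rates])
        v0s = np.array([[w, 0, 0] for w in rates])  # axis through (0, 1, 0)
        return twist_seq(omegas, v0s)

    def test_hinge_with_small_epsilon(self):
        sol = asa_position(
            self.hinge_twists(), AsaConfig(epsilon=1e-6, S0=np.zeros(3))
        )
        assert sol.regularized
        assert np.allclose(sol.S, [0, 1, 0], atol=1e-5)

    def test_huge_epsilon_pins_to_prior(self):
        sol = asa_position(
            self.hinge_twists(), AsaConfig(epsilon=1e6, S0=np.array([1.0, 2, 3]))
        )
        assert np.allclose(sol.S, [1, 2, 3], atol=1e-4)

    def test_rank_deficient_min_norm_with_flag(self):
        sol = asa_position(self.hinge_twists(), AsaConfig(epsilon=0.0))
        assert sol.rank_deficient and not sol.regularized
        assert np.allclose(sol.S, [0, 1, 0], atol=1e-9)  # min-norm lies on the axis
        assert abs(abs(sol.null_direction[2]) - 1) < 1e-9

    def test_all_zero_twists_raise(self):
        with pytest.raises(UndefinedAxisError):
            asa_position(twist_seq(np.zeros((4, 3))), AsaConfig(epsilon=0.0))

    @pytest.mark.parametrize("epsilon", [0.0, 0.01])
    def test_matches_independent_minimizer(self, rng, make_twist_set, epsilon):
        """Closed-form solution equals an iterative residual minimizer."""
        tws = make_twist_set(rng, n=30)
        S0 = np.array([0.01, -0.02, 0.03])
        sol = asa_position(tws, AsaConfig(epsilon=epsilon, S0=S0))
        W, V = tws.omegas, tws.v0s

        def residuals(S):
            res = (np.cross(W, np.broadcast_to(S, W.shape)) + V) / np.sqrt(len(W))
            out = res.ravel()
            if epsilon > 0:
                out = np.concatenate([out, np.sqrt(epsilon) * (S - S0)])
            return out

        fit = least_squares(residuals, x0=np.zeros(3), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        assert np.allclose(sol.S, fit.x, atol=1e-8)

    def test_stationarity_of_normal_equations(self, rng, make_twist_set):
        """Returned S zeroes the gradient of the regularized objective."""
        tws = make_twist_set(rng, n=20)
        cfg = AsaConfig(epsilon=0.01, S0=np.array([0.1, 0.0, -0.1]))
        sol = asa_position(tws, cfg)
        W, V = tws.omegas, tws.v0s
        N = len(tws)
        A = np.mean(np.sum(W**2, axis=1)) * np.eye(3) - W.T @ W / N
        b = np.mean(np.cross(W, V), axis=0)
        grad = (A + cfg.epsilon * np.eye(3)) @ sol.S - b - cfg.epsilon * cfg.S0
        assert np.linalg.norm(grad) < 1e-9

    def test_epsilon_continuity(self, rng, make_twist_set):
        tws = make_twist_set(rng, n=30)
        S_free = asa_position(tws, AsaConfig(epsilon=0.0)).S
        gaps = [
            np.linalg.norm(asa_position(tws, AsaConfig(epsilon=e, S0=np.ones(3))).S - S_free)
            for e in (1e-2, 1e-4, 1e-6)
        ]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-4

    def test_duplicating_twists_changes_nothing(self, rng, make_twist_set):
        tws = make_twist_set(rng, n=15)
        doubled = TwistSequence(twists=tws.twists + tws.twists)
        cfg = AsaConfig(epsilon=0.01, S0=np.array([0.05, 0.05, 0.0]))
        assert np.allclose(asa_position(tws, cfg).S, asa_position(doubled, cfg).S, atol=1e-12)
        C1 = angular_covariance(tws)
        C2 = angular_covariance(doubled)
        assert np.allclose(C1.C, C2.C, atol=1e-12)


class TestAsaFrame:
    def test_diagonal_covariance(self):
        C = AngularCovariance(C=np.diag([0.1, 0.2, 4.0]), N=10)
        T = asa_frame((0, 0, 1), (0, 0, 0), C)
        assert np.allclose(T[:3, 0], [0, 0, 1])
        assert np.allclose(T[:3, 1], [1, 0, 0])
        assert np.allclose(T[:3, 2], [0, 1, 0])

    def test_orthonormal_right_handed(self, rng, make_twist_set):
        for _ in range(5):
            tws = make_twist_set(rng, n=20)
            C = angular_covariance(tws)
            n = asa_direction(C, np.mean(tws.omegas, axis=0))
            T = asa_frame(n, rng.normal(size=3), C)
            R = T[:3, :3]
            assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-9
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_cylindrical_frame_axis(self, cylindrical_sequence):
        res = estimate_asa(cylindrical_sequence, AsaConfig(epsilon=1e-4, S0=np.array([0, -0.25, 0.0])))
        assert abs(abs(res.frame[2, 0]) - 1) < 1e-6  # e1 = +/- z


class TestEstimateAsa:
    def test_recovers_analytic_hinge(self):
        dt = 0.01
        transforms = []
        for k in range(60):
            theta = 1.5 * k * dt
            R = _rotation_about(np.array([0.0, 0, 1]), theta)
            T = np.eye(4)
            T[:3, :3] = R
            S = np.array([0.0, 1.0, 0.0])
            T[:3, 3] = S - R @ S
            transforms.append(T)
        ps = PoseSequence.from_transforms(transforms, dt=dt)
        res = estimate_asa(ps, AsaConfig(epsilon=1e-6, S0=np.zeros(3)))
        assert np.allclose(res.axis.n, [0, 0, 1], atol=1e-9)
        assert np.allclose(res.axis.S, [0, 1, 0], atol=1e-5)

    def test_cylindrical_recovers_generator_axis(self, cylindrical_sequence):
        from screwaxis import ScrewAxis

        res = estimate_asa(
            cylindrical_sequence, AsaConfig(epsilon=0.01, S0=np.array([0, -0.25, 0.0]))
        )
        truth = ScrewAxis(n=np.array([0.0, 0, 1]), S=np.array([0.0, -0.25, 0]))
        assert common_normal_distance(res.axis, truth) < 1e-3  # mm
        assert res.axis.n @ truth.n > 1 - 1e-9

    def test_identity_motion_raises(self):
        ps = PoseSequence.from_transforms([np.eye(4), np.eye(4)], dt=0.01)
        with pytest.raises(UndefinedAxisError):
            estimate_asa(ps, AsaConfig())

    def test_result_serializes(self, cylindrical_sequence):
        import json

        res = estimate_asa(cylindrical_sequence, AsaConfig(epsilon=0.01, S0=np.array([0, -0.25, 0.0])))
        doc = json.loads(res.to_json())
        assert doc["regularized"] is True
        assert len(doc["cov_omega_eigenvalues"]) == 3
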