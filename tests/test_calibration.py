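"""Hinge-geometry identification: closed-form pieces against independent
oracles, and axis/center recovery on simulated recordings."""
import numpy as np
import pytest

from imugait.calibration import (
    AXIS_STARTS,
    InsufficientExcitationError,
    axis_residuals,
    center_residuals,
    estimate_joint_axes,
    estimate_joint_centers,
    gamma,
    project_off_axis,
    resolve_axis_sign,
    spherical_to_unit,
    unit_to_spherical,
)
from imugait.simulate import HingeSimConfig, simulate_hinge
from imugait.streams import ImuStream


def axis_angle_deg(a, b):
    """Angle between two axis directions, sign-insensitive."""
    return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1.0, 1.0)))


def make_stream(t, gyro, accel):
    return ImuStream(time=t, gyro=gyro, accel=accel)


class TestSphericalToUnit:
    @pytest.mark.parametrize(
        "phi,theta,expected",
        [
            (0.0, 0.0, (1.0, 0.0, 0.0)),
            (np.pi / 2, 0.3, (0.0, 0.0, 1.0)),
            (np.pi / 2, -2.0, (0.0, 0.0, 1.0)),
        ],
    )
    def test_known_directions(self, phi, theta, expected):
        assert np.allclose(spherical_to_unit(phi, theta), expected, atol=1e-12)

    def test_unit_norm_and_roundtrip(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            phi = rng.uniform(-np.pi / 2, np.pi / 2)
            theta = rng.uniform(-np.pi, np.pi)
            j = spherical_to_unit(phi, theta)
            assert abs(np.linalg.norm(j) - 1.0) < 1e-12
            assert np.allclose(spherical_to_unit(*unit_to_spherical(j)), j, atol=1e-12)


class TestGamma:
    def test_centripetal_term(self):
        out = gamma([0, 0, 1], [0, 0, 0], [1, 0, 0])
        assert np.allclose(out, [-1.0, 0.0, 0.0], atol=1e-15)

    def test_tangential_term(self):
        out = gamma([0, 0, 0], [0, 0, 2], [1, 0, 0])
        assert np.allclose(out, [0.0, 2.0, 0.0], atol=1e-15)

    def test_matches_rigid_body_finite_difference(self):
        """Gamma equals the body-frame second derivative of a point fixed
        at offset o in a frame rotating with the given body rate."""
        from scipy.spatial.transform import Rotation

        dt = 1e-4
        t = np.arange(0.0, 0.5, dt)
        o = np.array([0.12, -0.05, 0.08])

        def body_rate(tv):
            return np.stack(
                [np.sin(2 * tv), 0.8 * np.cos(3 * tv), 0.5 * tv], axis=-1
            )

        # integrate R' = R [g]_x with RK4 (independent oracle path)
        rots = [Rotation.identity()]
        for k in range(len(t) - 1):
            def deriv(r, tv):
                return r.as_matrix() @ _skew(body_rate(tv))

            r = rots[-1].as_matrix()
            k1 = r @ _skew(body_rate(t[k]))
            k2 = (r + 0.5 * dt * k1) @ _skew(body_rate(t[k] + 0.5 * dt))
            k3 = (r + 0.5 * dt * k2) @ _skew(body_rate(t[k] + 0.5 * dt))
            k4 = (r + dt * k3) @ _skew(body_rate(t[k] + dt))
            rots.append(
                Rotation.from_matrix(r + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4))
            )
        pos = np.array([r.as_matrix() @ o for r in rots])
        mid = len(t) // 2
        acc_global = (pos[mid + 1] - 2 * pos[mid] + pos[mid - 1]) / dt**2
        acc_body = rots[mid].as_matrix().T @ acc_global
        g = body_rate(t[mid])
        g_dot = (body_rate(t[mid] + dt) - body_rate(t[mid] - dt)) / (2 * dt)
        assert np.allclose(gamma(g, g_dot, o), acc_body, atol=1e-5)


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


class TestAxisResiduals:
    def test_zero_at_truth_on_noise_free_hinge(self, zero_noise_hinge):
        _, (s1, s2, truth) = zero_noise_hinge
        g = truth.geometry["joint"]
        res = axis_residuals(s1, s2, *unit_to_spherical(g.j1), *unit_to_spherical(g.j2))
        assert np.abs(res).max() < 1e-10

    def test_symmetry_identical_streams(self, zero_noise_hinge):
        _, (s1, _, _) = zero_noise_hinge
        res = axis_residuals(s1, s1, 0.3, 1.1, 0.3, 1.1)
        assert np.abs(res).max() < 1e-14

    def test_matches_per_sample_brute_force(self, noisy_hinge):
        """Vectorized residuals equal a sample-by-sample reimplementation."""
        _, (s1, s2, _) = noisy_hinge
        params = (0.4, -1.2, -0.2, 2.5)
        res = axis_residuals(s1, s2, *params)
        j1 = spherical_to_unit(params[0], params[1])
        j2 = spherical_to_unit(params[2], params[3])
        for k in [0, 100, 999, 2500]:
            expect = np.linalg.norm(np.cross(s1.gyro[k], j1)) - np.linalg.norm(
                np.cross(s2.gyro[k], j2)
            )
            assert abs(res[k] - expect) < 1e-12

    def test_length_mismatch_rejected(self, zero_noise_hinge):
        _, (s1, s2, _) = zero_noise_hinge
        with pytest.raises(ValueError, match="length"):
            axis_residuals(s1.slice(0, 100), s2, 0, 0, 0, 0)


class TestEstimateJointAxes:
    def test_zero_noise_recovery(self, zero_noise_hinge):
        cfg, (s1, s2, _) = zero_noise_hinge
        j1, j2, rms, _ = estimate_joint_axes(s1, s2)
        assert axis_angle_deg(j1, cfg.true_axis_1) < 0.5
        assert axis_angle_deg(j2, cfg.true_axis_2) < 0.5
        assert rms < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_noisy_recovery_within_2_degrees(self, seed):
        rng = np.random.default_rng(100 + seed)
        a1 = rng.normal(size=3)
        a2 = rng.normal(size=3)
        cfg = HingeSimConfig(
            duration=60.0,
            true_axis_1=a1 / np.linalg.norm(a1),
            true_axis_2=a2 / np.linalg.norm(a2),
            gyro_noise_sd=0.01,
            seed=seed,
        )
        s1, s2, _ = simulate_hinge(cfg)
        j1, j2, _, _ = estimate_joint_axes(s1, s2)
        assert axis_angle_deg(j1, cfg.true_axis_1) < 2.0
        assert axis_angle_deg(j2, cfg.true_axis_2) < 2.0

    def test_optimizer_beats_exhaustive_coarse_grid(self):
        """TRF objective is no worse than an exhaustive spherical grid."""
        cfg = HingeSimConfig(duration=200 / 60.0, gyro_noise_sd=0.02, seed=31)
        s1, s2, _ = simulate_hinge(cfg)
        _, _, _, info = estimate_joint_axes(s1, s2)
        phis = np.radians(np.arange(-90, 91, 15))
        thetas = np.radians(np.arange(-180, 180, 15))
        best = np.inf
        for p1 in phis:
            for t1 in thetas:
                n1 = np.linalg.norm(
                    np.cross(s1.gyro, spherical_to_unit(p1, t1)), axis=1
                )
                for p2 in phis:
                    for t2 in thetas:
                        n2 = np.linalg.norm(
                            np.cross(s2.gyro, spherical_to_unit(p2, t2)), axis=1
                        )
                        best = min(best, np.sum((n1 - n2) ** 2))
        assert info["sse"] <= best + 1e-12

    def test_static_data_rejected(self):
        t = np.arange(0, 10, 1 / 60)
        quiet = make_stream(t, 1e-4 * np.ones((len(t), 3)), np.zeros((len(t), 3)))
        with pytest.raises(InsufficientExcitationError):
            estimate_joint_axes(quiet, quiet)


class TestCenterResiduals:
    def test_zero_at_truth_with_exact_gdot(self, zero_noise_hinge):
        _, (s1, s2, truth) = zero_noise_hinge
        g = truth.geometry["joint"]
        res = center_residuals(
            s1, s2, g.o1, g.o2, truth.gyro_dot["hinge1"], truth.gyro_dot["hinge2"]
        )
        assert np.abs(res).max() < 1e-10

    def test_symmetry_zero_offsets_identical_streams(self, zero_noise_hinge):
        _, (s1, _, _) = zero_noise_hinge
        res = center_residuals(s1, s1, np.zeros(3), np.zeros(3))
        assert np.abs(res).max() < 1e-14

    def test_matches_per_sample_brute_force(self, noisy_hinge):
        _, (s1, s2, _) = noisy_hinge
        o1 = np.array([0.1, -0.2, 0.05])
        o2 = np.array([-0.07, 0.0, 0.12])
        dt = s1.dt
        gd1 = np.gradient(s1.gyro, dt, axis=0)
        gd2 = np.gradient(s2.gyro, dt, axis=0)
        res = center_residuals(s1, s2, o1, o2)
        for k in [0, 57, 1400, 3000]:
            gam1 = np.cross(s1.gyro[k], np.cross(s1.gyro[k], o1)) + np.cross(gd1[k], o1)
            gam2 = np.cross(s2.gyro[k], np.cross(s2.gyro[k], o2)) + np.cross(gd2[k], o2)
            expect = np.linalg.norm(s1.accel[k] - gam1) - np.linalg.norm(
                s2.accel[k] - gam2
            )
            assert abs(res[k] - expect) < 1e-12


class TestEstimateJointCenters:
    def test_zero_noise_recovery_within_5mm(self, zero_noise_hinge):
        cfg, (s1, s2, truth) = zero_noise_hinge
        g = truth.geometry["joint"]
        o1, o2, rms = estimate_joint_centers(
            s1, s2, g.j1, g.j2,
            gdot1=truth.gyro_dot["hinge1"], gdot2=truth.gyro_dot["hinge2"],
        )
        assert np.linalg.norm(o1 - project_off_axis(cfg.true_center_1, g.j1)) < 5e-3
        assert np.linalg.norm(o2 - project_off_axis(cfg.true_center_2, g.j2)) < 5e-3

    def test_returned_offsets_orthogonal_to_axes(self, noisy_hinge):
        _, (s1, s2, truth) = noisy_hinge
        g = truth.geometry["joint"]
        o1, o2, _ = estimate_joint_centers(s1, s2, g.j1, g.j2)
        assert abs(o1 @ g.j1) < 1e-9
        assert abs(o2 @ g.j2) < 1e-9

    def test_objective_at_solution_beats_truth(self, noisy_hinge):
        """On noisy data the optimum is at least as good as ground truth."""
        cfg, (s1, s2, truth) = noisy_hinge
        g = truth.geometry["joint"]
        _, _, rms = estimate_joint_centers(s1, s2, g.j1, g.j2)
        sse_fit = s1.n * rms**2
        sse_truth = np.sum(center_residuals(s1, s2, cfg.true_center_1, cfg.true_center_2) ** 2)
        assert sse_fit <= sse_truth * (1 + 1e-8)

    def test_simultaneous_axis_shift_is_null_direction(self, zero_noise_hinge):
        """Shifting both offsets equally along their axes leaves the
        objective at zero; shifting one alone does not."""
        _, (s1, s2, truth) = zero_noise_hinge
        g = truth.geometry["joint"]
        gd = (truth.gyro_dot["hinge1"], truth.gyro_dot["hinge2"])
        both = center_residuals(s1, s2, g.o1 + 0.05 * g.j1, g.o2 + 0.05 * g.j2, *gd)
        assert np.abs(both).max() < 1e-10
        alone = center_residuals(s1, s2, g.o1 + 0.05 * g.j1, g.o2, *gd)
        assert np.abs(alone).max() > 1e-3


class TestResolveAxisSign:
    def test_largest_component_made_positive(self):
        j1, j2 = resolve_axis_sign(np.array([-1.0, 0, 0]), np.array([0, -1.0, 0]))
        assert np.allclose(j1, [1, 0, 0])
        assert np.allclose(j2, [0, 1, 0])

    def test_flipping_both_inputs_is_idempotent(self, noisy_hinge):
        _, (s1, s2, truth) = noisy_hinge
        g = truth.geometry["joint"]
        a = resolve_axis_sign(g.j1, g.j2, s1, s2)
        b = resolve_axis_sign(-g.j1, -g.j2, s1, s2)
        assert np.allclose(a[0], b[0])
        assert np.allclose(a[1], b[1])

    def test_objective_sign_invariance(self, noisy_hinge):
        """The axis SSE is unchanged when either axis is flipped."""
        _, (s1, s2, _) = noisy_hinge
        p = (0.4, 0.9, -0.3, 1.7)
        base = np.sum(axis_residuals(s1, s2, *p) ** 2)
        flip1 = np.sum(
            axis_residuals(s1, s2, *unit_to_spherical(-spherical_to_unit(p[0], p[1])), p[2], p[3]) ** 2
        )
        assert np.isclose(base, flip1, rtol=1e-12)

    def test_canonical_hinge_recovers_ground_truth_sign(self):
        """For anatomically aligned axes the fused angle tracks +truth."""
        from imugait import kinematics as kin

        cfg = HingeSimConfig(
            duration=30.0, gyro_noise_sd=0.005, accel_noise_sd=0.05,
            gyro_bias=0.002, seed=41,
        )
        s1, s2, truth = simulate_hinge(cfg)
        j1, j2, _, _ = estimate_joint_axes(s1, s2)
        o1, o2, _ = estimate_joint_centers(s1, s2, j1, j2)
        ag = kin.gyro_angle(s1, s2, j1, j2)
        aa = kin.accel_angle(
            kin.shift_accelerations(s1, o1), kin.shift_accelerations(s2, o2), j1, j2
        )
        alpha = kin.fuse_angles(aa, ag)
        corr = np.corrcoef(alpha, truth.angle_deg["joint"])[0, 1]
        assert corr > 0.99
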