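"""Angle chain: gyro integration, acceleration shifting, joint-plane
projection, complementary-filter fusion, angular velocity and vertical
acceleration."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from imugait.calibration import project_off_axis
from imugait.kinematics import (
    FusionConfig,
    accel_angle,
    angular_velocity,
    auto_plane_reference,
    fuse_angles,
    gyro_angle,
    joint_plane_axes,
    shift_accelerations,
    vertical_acceleration,
)
from imugait.streams import GRAVITY, ImuStream


def const_stream(t, gyro_vec, accel_vec):
    n = len(t)
    return ImuStream(t, np.tile(gyro_vec, (n, 1)), np.tile(accel_vec, (n, 1)))


class TestGyroAngle:
    def test_constant_rate_difference_integrates_linearly(self):
        t = np.arange(0, 10.0 + 1e-9, 1 / 60)
        j = np.array([0.0, 0.0, 1.0])
        s1 = const_stream(t, [0, 0, 0.1], [0, 0, 9.81])
        s2 = const_stream(t, [0, 0, 0.0], [0, 0, 9.81])
        ang = gyro_angle(s1, s2, j, j)
        assert ang[0] == 0.0
        assert ang[-1] == pytest.approx(np.degrees(1.0), rel=1e-6)

    def test_zero_rates_give_zero(self):
        t = np.arange(0, 5, 1 / 60)
        s = const_stream(t, [0, 0, 0], [0, 0, 9.81])
        assert np.all(gyro_angle(s, s, [0, 0, 1], [0, 0, 1]) == 0.0)

    def test_axis_bias_drifts_linearly(self):
        """A gyro bias b along the axis produces ~b*T rad terminal drift."""
        rng = np.random.default_rng(3)
        t = np.arange(0, 30.0, 1 / 60)
        j = np.array([0.0, 1.0, 0.0])
        rate = 0.5 * np.sin(2 * np.pi * 0.7 * t)
        b = 0.01
        g1 = np.outer(rate + b, j)
        g2 = np.outer(rate, j) * 0.0
        s1 = ImuStream(t, g1, np.zeros((len(t), 3)) + [0, 0, 9.81])
        s2 = ImuStream(t, g2, np.zeros((len(t), 3)) + [0, 0, 9.81])
        drift = gyro_angle(s1, s2, j, j)[-1] - np.degrees(
            np.trapezoid(rate, t)
        )
        assert drift == pytest.approx(np.degrees(b * t[-1]), rel=0.02)


class TestShiftAccelerations:
    def test_zero_offset_is_identity(self, noisy_hinge):
        _, (s1, _, _) = noisy_hinge
        assert np.array_equal(shift_accelerations(s1, np.zeros(3)), s1.accel)

    def test_static_stream_unchanged_for_any_offset(self):
        t = np.arange(0, 5, 1 / 60)
        s = const_stream(t, [0, 0, 0], [1.0, 2.0, 9.0])
        assert np.allclose(shift_accelerations(s, [0.3, -0.2, 0.1]), s.accel, atol=1e-12)

    def test_shifted_norms_agree_across_sensors(self, zero_noise_hinge):
        """Both shifted accelerations are the joint-center specific force
        expressed in different frames, so their norms coincide."""
        _, (s1, s2, truth) = zero_noise_hinge
        g = truth.geometry["joint"]
        a1 = shift_accelerations(s1, g.o1, truth.gyro_dot["hinge1"])
        a2 = shift_accelerations(s2, g.o2, truth.gyro_dot["hinge2"])
        assert np.allclose(
            np.linalg.norm(a1, axis=1), np.linalg.norm(a2, axis=1), atol=1e-9
        )


class TestJointPlaneAxes:
    def test_cross_product_arithmetic(self):
        x, y = joint_plane_axes(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
        assert np.allclose(x, [0, 1, 0])
        assert np.allclose(y, [-1, 0, 0])

    def test_orthogonality(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            j = rng.normal(size=3)
            j /= np.linalg.norm(j)
            c = rng.normal(size=3)
            x, y = joint_plane_axes(j, c)
            assert abs(x @ j) < 1e-12
            assert abs(y @ j) < 1e-12
            assert abs(x @ y) < 1e-12

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            joint_plane_axes(np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 2.0]))

    def test_auto_reference_picks_most_orthogonal_basis_vector(self):
        assert np.allclose(auto_plane_reference(np.array([0.9, 0.1, 0.42])), [0, 1, 0])
        assert np.allclose(auto_plane_reference(np.array([0.1, 0.7, 0.7])), [1, 0, 0])


class TestAccelAngle:
    @staticmethod
    def static_pair(alpha_deg, j, c="auto"):
        """Two static frames differing by a rotation about the hinge axis."""
        r1 = Rotation.from_rotvec([0.4, 0.2, -0.3])
        r2 = r1 * Rotation.from_rotvec(-np.radians(alpha_deg) * j)
        a1 = r1.inv().apply(-GRAVITY)[None, :]
        a2 = r2.inv().apply(-GRAVITY)[None, :]
        return accel_angle(a1, a2, j, j, c)[0]

    def test_identical_projections_give_zero(self):
        j = np.array([0.0, 1.0, 0.0])
        assert self.static_pair(0.0, j) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle(self):
        j = np.array([0.0, 1.0, 0.0])
        base = self.static_pair(0.0, j)
        assert self.static_pair(90.0, j) - base == pytest.approx(90.0, abs=1e-9)

    def test_static_pose_sweep_tracks_truth(self):
        """Posed hinge angles over the motion range recovered within 0.1 deg."""
        j = np.array([0.3, 0.9, 0.2])
        j /= np.linalg.norm(j)
        base = self.static_pair(0.0, j)
        for alpha in np.linspace(-80, 80, 17):
            rec = self.static_pair(alpha, j) - base
            assert rec == pytest.approx(alpha, abs=0.1)

    def test_degenerate_projection_marked_nan(self):
        j = np.array([0.0, 0.0, 1.0])
        a = np.array([[0.0, 0.0, 5.0]])  # parallel to axis: no projection
        out = accel_angle(a, a, j, j, np.array([1.0, 0.0, 0.0]))
        assert np.isnan(out[0])

    def test_reference_vector_changes_only_a_constant(self, zero_noise_hinge):
        """alpha_acc with two valid c vectors differs by a time-constant."""
        _, (s1, s2, truth) = zero_noise_hinge
        g = truth.geometry["joint"]
        a1 = shift_accelerations(s1, g.o1, truth.gyro_dot["hinge1"])
        a2 = shift_accelerations(s2, g.o2, truth.gyro_dot["hinge2"])
        c1 = np.array([1.0, 0.0, 0.0])
        c2 = np.array([0.2, 0.5, -0.8])
        d = accel_angle(a1, a2, g.j1, g.j2, c1) - accel_angle(a1, a2, g.j1, g.j2, c2)
        d = (d + 180.0) % 360.0 - 180.0
        assert np.ptp(d) < 1e-6

    def test_reference_offset_vanishes_for_equal_axes(self):
        """With j1 == j2 the constant is exactly zero for any c."""
        j = np.array([0.0, 1.0, 0.0])
        for c in (np.array([1.0, 0, 0]), np.array([0.3, 0.1, -0.9])):
            assert self.static_pair(35.0, j, c) - self.static_pair(0.0, j, c) == pytest.approx(
                35.0, abs=1e-9
            )


class TestFuseAngles:
    def test_lambda_one_collapses_to_accel(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 5, 1 / 60)
        acc = 40 * np.sin(2 * np.pi * 1.1 * t) + rng.normal(0, 3.0, t.size)
        gyr = 40 * np.sin(2 * np.pi * 1.1 * t)
        out = fuse_angles(acc, gyr, FusionConfig(lam=1.0))
        assert np.allclose(out, acc, atol=1e-12)
        # incoherent sources still agree modulo a full turn
        wild_acc = rng.uniform(-90, 90, 200)
        wild_gyr = rng.uniform(-90, 90, 200)
        out = fuse_angles(wild_acc, wild_gyr, FusionConfig(lam=1.0))
        assert np.allclose((out - wild_acc + 180) % 360 - 180, 0.0, atol=1e-9)

    def test_fixed_point_geometric_convergence(self):
        """Constant sources converge geometrically with ratio (1-lambda)."""
        lam = 0.02
        a = 25.0
        acc = np.full(400, a)
        gyr = np.zeros(400)
        out = fuse_angles(acc, gyr, FusionConfig(lam=lam))
        err = np.abs(out - a)
        # starts at alpha_acc(0) = A exactly here; use a nonzero start
        out2 = fuse_angles(np.concatenate([[0.0], acc]), np.zeros(401), FusionConfig(lam=lam))
        err2 = np.abs(out2 - a)[1:]
        ratios = err2[1:] / err2[:-1]
        assert np.allclose(ratios, 1 - lam, atol=1e-9)
        assert np.allclose(err, 0.0)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(lam=1.5)

    def test_nan_accel_propagates_by_gyro(self):
        acc = np.array([10.0, np.nan, np.nan, 10.0])
        gyr = np.array([0.0, 1.0, 2.0, 3.0])
        out = fuse_angles(acc, gyr, FusionConfig(lam=0.5))
        assert out[0] == 10.0
        assert out[1] == 11.0  # pure gyro increment
        assert out[2] == 12.0
        assert out[3] == pytest.approx(0.5 * 10.0 + 0.5 * 13.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_fusion_beats_both_sources(self, seed):
        """lambda=0.02, dt=0.016: fused RMSE below both pure sources on
        drifting + noisy signals."""
        rng = np.random.default_rng(seed)
        t = np.arange(0, 60.0, 0.016)
        truth = 30 * np.sin(2 * np.pi * 0.9 * t) + 10 * np.sin(2 * np.pi * 1.7 * t + 1)
        acc = truth + rng.normal(0, 2.0, t.size)
        gyr = truth + np.degrees(0.005) * t + rng.normal(0, 0.1, t.size)
        fused = fuse_angles(acc, gyr, FusionConfig(lam=0.02, dt=0.016))
        rmse = lambda x: np.sqrt(np.mean((x - truth) ** 2))
        assert rmse(fused) < min(rmse(acc), rmse(gyr))

    def test_bounded_under_gyro_drift(self):
        """10-minute record: fused output stays bounded while pure gyro
        integration drifts away."""
        rng = np.random.default_rng(8)
        t = np.arange(0, 600.0, 0.016)
        truth = 20 * np.sin(2 * np.pi * 0.8 * t)
        acc = truth + rng.normal(0, 1.5, t.size)
        gyr = truth + np.degrees(0.005) * t
        fused = fuse_angles(acc, gyr, FusionConfig())
        assert np.abs(gyr - truth)[-1] > 100.0
        assert np.abs(fused - truth).max() < 25.0


class TestAngularVelocity:
    def test_linear_ramp_gives_constant_slope(self):
        t = np.arange(0, 10, 1 / 60)
        av = angular_velocity(5.0 * t, 60.0)
        interior = av[60:-60]
        assert np.all(np.abs(interior - 5.0) < 0.05)

    def test_sinusoid_passband_derivative_amplitude(self):
        t = np.arange(0, 20, 1 / 60)
        a = 12.0
        av = angular_velocity(a * np.sin(2 * np.pi * 1.0 * t), 60.0)
        assert np.max(np.abs(av[120:-120])) == pytest.approx(2 * np.pi * a, rel=0.02)

    def test_constant_angle_zero_velocity(self):
        av = angular_velocity(np.full(600, 33.0), 60.0)
        assert np.allclose(av, 0.0, atol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            angular_velocity(np.ones(5), 60.0)


class TestVerticalAcceleration:
    @staticmethod
    def make_stream(t, rot, accel_global):
        accel_local = rot.inv().apply(accel_global - GRAVITY)
        quat = np.roll(rot.as_quat(), 1, axis=-1)
        if quat.ndim == 1:
            quat = np.tile(quat, (len(t), 1))
            accel_local = np.tile(accel_local, (len(t), 1))
        return ImuStream(t, np.zeros((len(t), 3)), accel_local, orientation=quat)

    def test_stationary_in_any_orientation_reads_zero(self):
        t = np.arange(0, 2, 1 / 60)
        rot = Rotation.from_rotvec([0.5, -0.8, 0.2])
        s = self.make_stream(t, rot, np.zeros(3))
        assert np.allclose(vertical_acceleration(s).a_vert, 0.0, atol=1e-9)

    def test_free_fall_reads_minus_g(self):
        t = np.arange(0, 2, 1 / 60)
        s = ImuStream(
            t, np.zeros((len(t), 3)), np.zeros((len(t), 3)),
            orientation=np.tile([1.0, 0, 0, 0], (len(t), 1)),
        )
        assert np.allclose(vertical_acceleration(s).a_vert, GRAVITY[2], atol=1e-9)

    def test_vertical_sinusoid_amplitude_recovered(self):
        t = np.arange(0, 10, 1 / 60)
        amp, f = 0.02, 1.5
        accel_z = -amp * (2 * np.pi * f) ** 2 * np.sin(2 * np.pi * f * t)
        acc_global = np.stack([np.zeros_like(t), np.zeros_like(t), accel_z], axis=1)
        rot = Rotation.from_rotvec(np.tile([0.2, 0.1, 0.0], (len(t), 1)))
        s = self.make_stream(t, rot, acc_global)
        out = vertical_acceleration(s).a_vert
        assert np.max(np.abs(out)) == pytest.approx(amp * (2 * np.pi * f) ** 2, rel=0.02)

    def test_missing_orientation_rejected(self):
        t = np.arange(0, 2, 1 / 60)
        s = ImuStream(t, np.zeros((len(t), 3)), np.zeros((len(t), 3)))
        with pytest.raises(ValueError, match="orientation"):
            vertical_acceleration(s)
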