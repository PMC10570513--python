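"""Flexion/extension angle estimation by gyro-accel fusion.

Given the calibrated hinge geometry (axes ``j1``, ``j2`` and offsets
``o1``, ``o2``), the joint angle is measured twice:

* ``alpha_gyr`` — integral of the difference of the angular rates
  projected on the joint axis. Smooth and precise on short time scales
  but drifts under gyro bias.
* ``alpha_acc`` — angle between the projections, into the joint plane,
  of the joint-center accelerations seen by the two sensors (each
  accelerometer reading shifted to the joint center by removing the
  rotation-induced term). Drift-free but noisy.

A complementary filter blends them:
``alpha(t) = lambda*alpha_acc(t) + (1-lambda)*(alpha(t-dt) + alpha_gyr(t)
- alpha_gyr(t-dt))`` with ``lambda = 0.02`` and ``dt = 0.016`` s (60 Hz)
by default.

The hinge angle is identifiable only up to sign (axis-sign degeneracy)
and an additive constant (choice of the joint-plane reference vector
``c``); downstream evaluation aligns those conventions against a
reference before computing errors.

The module also provides angular velocities (zero-phase 6 Hz low-pass,
then central differences) and the gravity-free vertical acceleration of
an orientation-equipped sensor (e.g. at the C7 vertebra).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .calibration import gamma, gyro_derivative
from .streams import GRAVITY, ImuStream

__all__ = [
    "FusionConfig",
    "AngleSeries",
    "VerticalAccelSeries",
    "gyro_angle",
    "shift_accelerations",
    "joint_plane_axes",
    "auto_plane_reference",
    "accel_angle",
    "fuse_angles",
    "angular_velocity",
    "vertical_acceleration",
]


@dataclass
class FusionConfig:
    """Complementary-filter parameters.

    ``lam`` is the accelerometer weight (0: pure gyro, 1: pure accel);
    ``dt`` the sample period in seconds; ``plane_reference`` the vector
    ``c`` used to span the joint plane, or ``"auto"`` to pick the
    standard basis vector most orthogonal to each axis.
    """

    lam: float = 0.02
    dt: float = 0.016
    plane_reference: np.ndarray | str = "auto"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class AngleSeries:
    """A joint's flexion/extension angle estimates, all in degrees."""

    time: np.ndarray
    alpha_gyr: np.ndarray
    alpha_acc: np.ndarray
    alpha: np.ndarray
    angular_velocity: np.ndarray | None = None
    joint: str = ""


@dataclass
class VerticalAccelSeries:
    """Gravity-free vertical (global Z) acceleration, m/s^2."""

    time: np.ndarray
    a_vert: np.ndarray


def gyro_angle(
    stream1: ImuStream, stream2: ImuStream, j1: np.ndarray, j2: np.ndarray
) -> np.ndarray:
    """Gyro-integrated joint angle in degrees, starting at 0.

    Cumulative trapezoidal integral of ``g1.j1 - g2.j2``.
    """
    if stream1.n != stream2.n:
        raise ValueError("streams must be equal length")
    diff = stream1.gyro @ np.asarray(j1, float) - stream2.gyro @ np.asarray(j2, float)
    dt = np.diff(stream1.time)
    integral = np.concatenate([[0.0], np.cumsum(0.5 * (diff[1:] + diff[:-1]) * dt)])
    return np.degrees(integral)


def shift_accelerations(
    stream: ImuStream, o: np.ndarray, gdot: np.ndarray | None = None
) -> np.ndarray:
    """Move accelerometer readings to the joint center: ``a - Gamma_g(o)``."""
    if gdot is None:
        gdot = gyro_derivative(stream.gyro, stream.dt)
    return stream.accel - gamma(stream.gyro, gdot, np.asarray(o, float))


def auto_plane_reference(j: np.ndarray) -> np.ndarray:
    """Standard basis vector with the smallest ``|j . e|`` (best conditioned)."""
    j = np.asarray(j, dtype=float)
    return np.eye(3)[int(np.argmin(np.abs(j)))]


def joint_plane_axes(
    j: np.ndarray, c: np.ndarray | str = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """Joint-plane basis ``x = j x c``, ``y = j x x`` for axis ``j``.

    ``c`` may be any vector not parallel to ``j``; ``"auto"`` selects the
    standard basis vector most orthogonal to ``j``.
    """
    j = np.asarray(j, dtype=float)
    if isinstance(c, str):
        if c != "auto":
            raise ValueError("plane reference must be a vector or 'auto'")
        c = auto_plane_reference(j)
    c = np.asarray(c, dtype=float)
    x = np.cross(j, c)
    if np.linalg.norm(x) < 1e-9:
        raise ValueError(
            "plane reference c is (near-)parallel to the joint axis; "
            "pass a different c or use 'auto' selection"
        )
    y = np.cross(j, x)
    return x, y


def accel_angle(
    a1_shifted: np.ndarray,
    a2_shifted: np.ndarray,
    j1: np.ndarray,
    j2: np.ndarray,
    c: np.ndarray | str = "auto",
    degenerate_tol: float = 1e-9,
) -> np.ndarray:
    """Accelerometer-based joint angle in degrees (NaN where degenerate).

    Signed angle between the joint-plane projections of the two shifted
    accelerations, via the two-argument arctangent difference, wrapped to
    (-180, 180]. The sign is the angle *from* the first projection *to*
    the second, which makes the accelerometer angle share the sense of
    the gyro-integrated angle (``g1.j1 - g2.j2``) for the same axis
    pair, as the complementary filter requires. Samples whose projection
    norm falls below ``degenerate_tol`` are returned as NaN (fusion then
    falls back to pure gyro propagation there).
    """
    x1, y1 = joint_plane_axes(j1, c)
    x2, y2 = joint_plane_axes(j2, c)
    u1 = np.stack([a1_shifted @ x1, a1_shifted @ y1], axis=1)
    u2 = np.stack([a2_shifted @ x2, a2_shifted @ y2], axis=1)
    ang = np.arctan2(u2[:, 1], u2[:, 0]) - np.arctan2(u1[:, 1], u1[:, 0])
    ang = np.degrees((ang + np.pi) % (2 * np.pi) - np.pi)
    bad = (np.linalg.norm(u1, axis=1) < degenerate_tol) | (
        np.linalg.norm(u2, axis=1) < degenerate_tol
    )
    ang[bad] = np.nan
    return ang


def fuse_angles(
    alpha_acc: np.ndarray,
    alpha_gyr: np.ndarray,
    config: FusionConfig | None = None,
) -> np.ndarray:
    """Complementary-filter fusion of the two angle sources (degrees).

    ``alpha(t) = lambda*alpha_acc(t) + (1-lambda)*(alpha(t-dt) +
    alpha_gyr(t) - alpha_gyr(t-dt))``. The accelerometer angle is only
    defined modulo 360 deg, so at each step the representative of
    ``alpha_acc`` closest to the gyro-propagated prediction is used
    (continuity assumption of the recursion); this avoids spurious
    full-turn jumps when the angle runs near the +-180 deg branch cut.
    The state starts at ``alpha_acc[0]`` (drift-free and available at
    t=0); at samples where ``alpha_acc`` is NaN the filter propagates by
    the gyro increment alone.
    """
    config = config or FusionConfig()
    alpha_acc = np.asarray(alpha_acc, dtype=float)
    alpha_gyr = np.asarray(alpha_gyr, dtype=float)
    if alpha_acc.shape != alpha_gyr.shape:
        raise ValueError("angle sources must have equal length")
    valid = np.isfinite(alpha_acc)
    lam = config.lam
    out = np.empty_like(alpha_acc)
    state = alpha_acc[0] if valid[0] else alpha_gyr[0]
    out[0] = state
    for k in range(1, len(alpha_acc)):
        pred = state + alpha_gyr[k] - alpha_gyr[k - 1]
        if valid[k]:
            innovation = (alpha_acc[k] - pred + 180.0) % 360.0 - 180.0
            state = pred + lam * innovation
        else:
            state = pred
        out[k] = state
    return out


def _lowpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    # Second-order Butterworth applied forward-backward (zero phase,
    # effective fourth order).
    b, a = butter(2, cutoff / (rate / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"series too short for zero-phase filtering (n={len(x)})")
    return filtfilt(b, a, x)


def angular_velocity(
    angle_deg: np.ndarray, rate: float, cutoff: float = 6.0
) -> np.ndarray:
    """Angular velocity (deg/s): zero-phase low-pass, then central differences."""
    filtered = _lowpass(np.asarray(angle_deg, dtype=float), rate, cutoff)
    return np.gradient(filtered, 1.0 / rate)


def lowpass_zero_phase(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Forward-backward (zero-phase) second-order Butterworth low-pass."""
    return _lowpass(np.asarray(x, dtype=float), rate, cutoff)


def vertical_acceleration(stream: ImuStream) -> VerticalAccelSeries:
    """Gravity-free global-Z acceleration from an orientation-equipped IMU.

    The specific force is rotated into the global frame with the device
    quaternion and gravity is removed; a stationary sensor yields ~0 and
    free fall yields -9.81 m/s^2.
    """
    if stream.orientation is None:
        raise ValueError(
            f"sensor {stream.name!r} has no orientation channel; vertical "
            "acceleration requires device quaternions"
        )
    quat_xyzw = np.roll(stream.orientation, -1, axis=1)
    rot = Rotation.from_quat(quat_xyzw)
    a_global = rot.apply(stream.accel) + GRAVITY
    return VerticalAccelSeries(time=stream.time, a_vert=a_global[:, 2])
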