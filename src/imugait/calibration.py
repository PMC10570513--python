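"""Hinge-joint axis and center identification from raw gyro/accel data.

Two IMUs rigidly attached to the segments on either side of a hinge joint
share kinematic constraints that identify, without any assumption about
mounting pose:

* the joint (flexion/extension) axis direction in each sensor's local
  frame, ``j1`` and ``j2`` — because both gyroscopes see the same angular
  rate up to the hinge rotation, the projections of ``g1`` and ``g2`` onto
  the joint plane have equal norms at every instant:
  ``||g1 x j1|| - ||g2 x j2|| = 0``;
* the joint-center offset in each frame, ``o1`` and ``o2`` — because the
  joint-center acceleration, obtained by removing the rotation-induced
  (centripetal + tangential) term ``Gamma_g(o) = g x (g x o) + gdot x o``
  from each accelerometer, has the same norm in both frames:
  ``||a1 - Gamma_g1(o1)|| - ||a2 - Gamma_g2(o2)|| = 0``.

Here ``o_i`` is the sensor origin's position relative to the joint center,
expressed in sensor-frame coordinates; it is identifiable only up to
translation along the axis, and the returned offsets have the
axis-parallel component projected out (``o_i . j_i = 0``).

Axes are parameterized on the unit sphere by inclination/azimuth and both
sums of squared residuals are minimized with the Trust Region Reflective
least-squares algorithm, from several deterministic starts to escape the
mirror minima of the sign-invariant objective.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .streams import ImuStream

__all__ = [
    "JointGeometry",
    "InsufficientExcitationError",
    "spherical_to_unit",
    "unit_to_spherical",
    "gamma",
    "gyro_derivative",
    "axis_residuals",
    "estimate_joint_axes",
    "center_residuals",
    "estimate_joint_centers",
    "resolve_axis_sign",
]

#: Deterministic optimizer starts (phi, theta) used for each sensor.
AXIS_STARTS = [
    (0.0, 0.0),
    (0.0, np.pi / 2),
    (np.pi / 4, np.pi),
    (-np.pi / 4, -np.pi / 2),
]

#: Minimum standard deviation of the gyro magnitude (rad/s) considered
#: sufficient excitation for a fit.
EXCITATION_FLOOR = 0.2


class InsufficientExcitationError(RuntimeError):
    """Raised when the motion is too static to identify the geometry."""


@dataclass
class JointGeometry:
    """Identified hinge geometry in both sensors' local frames.

    ``j1``/``j2`` are unit axis directions; ``o1``/``o2`` are joint-center
    offsets (sensor origin relative to the joint center, sensor frame, m)
    with the axis-parallel component removed. ``axis_residual_rms`` is in
    rad/s, ``center_residual_rms`` in m/s^2.
    """

    j1: np.ndarray
    j2: np.ndarray
    o1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    o2: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_residual_rms: float = np.nan
    center_residual_rms: float = np.nan
    spherical: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.j1 = np.asarray(self.j1, dtype=float)
        self.j2 = np.asarray(self.j2, dtype=float)
        self.o1 = np.asarray(self.o1, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        for j in (self.j1, self.j2):
            n = np.linalg.norm(j)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise ValueError("joint axes must be unit vectors")

    def to_dict(self) -> dict:
        return {
            "j1": self.j1.tolist(),
            "j2": self.j2.tolist(),
            "o1": self.o1.tolist(),
            "o2": self.o2.tolist(),
            "axis_residual_rms": float(self.axis_residual_rms),
            "center_residual_rms": float(self.center_residual_rms),
            "spherical": list(self.spherical) if self.spherical is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointGeometry":
        return cls(
            j1=np.array(d["j1"]),
            j2=np.array(d["j2"]),
            o1=np.array(d["o1"]),
            o2=np.array(d["o2"]),
            axis_residual_rms=d.get("axis_residual_rms", np.nan),
            center_residual_rms=d.get("center_residual_rms", np.nan),
            spherical=tuple(d["spherical"]) if d.get("spherical") else None,
        )


def spherical_to_unit(phi: float, theta: float) -> np.ndarray:
    """Unit vector from inclination ``phi`` and azimuth ``theta`` (rad)."""
    cp = np.cos(phi)
    return np.array([cp * np.cos(theta), cp * np.sin(theta), np.sin(phi)])


def unit_to_spherical(j: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`spherical_to_unit` for a unit vector."""
    j = np.asarray(j, dtype=float)
    phi = np.arcsin(np.clip(j[2], -1.0, 1.0))
    theta = np.arctan2(j[1], j[0])
    return float(phi), float(theta)


def gamma(g: np.ndarray, g_dot: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Rotation-induced acceleration ``g x (g x o) + g_dot x o``.

    The radial (centripetal) plus tangential acceleration of a point at
    offset ``o`` from the rotation center, for body-frame angular rate
    ``g`` and its derivative ``g_dot``. Accepts single vectors or (N, 3)
    stacks.
    """
    g = np.asarray(g, dtype=float)
    g_dot = np.asarray(g_dot, dtype=float)
    o = np.asarray(o, dtype=float)
    return np.cross(g, np.cross(g, o)) + np.cross(g_dot, o)


def gyro_derivative(gyro: np.ndarray, dt: float) -> np.ndarray:
    """Angular acceleration by central differences (one-sided at the ends)."""
    return np.gradient(np.asarray(gyro, dtype=float), dt, axis=0)


def _check_lengths(stream1: ImuStream, stream2: ImuStream) -> None:
    if stream1.n != stream2.n:
        raise ValueError(
            f"streams must be time-aligned and equal length ({stream1.n} vs {stream2.n})"
        )


def _check_excitation(stream: ImuStream, floor: float) -> None:
    sd = float(np.std(np.linalg.norm(stream.gyro, axis=1)))
    if sd <= floor:
        raise InsufficientExcitationError(
            f"gyro magnitude sd {sd:.3f} rad/s below excitation floor {floor} "
            f"(sensor {stream.name!r}); record more varied joint motion"
        )


def axis_residuals(
    stream1: ImuStream,
    stream2: ImuStream,
    phi1: float,
    theta1: float,
    phi2: float,
    theta2: float,
) -> np.ndarray:
    """Per-sample hinge-axis constraint residuals (rad/s).

    ``r_k = ||g1(t_k) x j1|| - ||g2(t_k) x j2||`` with the axes obtained
    from the spherical parameters.
    """
    _check_lengths(stream1, stream2)
    j1 = spherical_to_unit(phi1, theta1)
    j2 = spherical_to_unit(phi2, theta2)
    n1 = np.linalg.norm(np.cross(stream1.gyro, j1), axis=1)
    n2 = np.linalg.norm(np.cross(stream2.gyro, j2), axis=1)
    return n1 - n2


def estimate_joint_axes(
    stream1: ImuStream,
    stream2: ImuStream,
    starts: list[tuple[float, float]] | None = None,
    excitation_floor: float = EXCITATION_FLOOR,
    resolve_sign: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Identify the hinge-axis directions ``j1``, ``j2`` from gyro data.

    Minimizes the sum of squared :func:`axis_residuals` over the four
    spherical parameters with Trust Region Reflective least squares,
    trying every pair of deterministic starts and keeping the lowest
    objective. Returns ``(j1, j2, axis_residual_rms, info)``.
    """
    _check_lengths(stream1, stream2)
    _check_excitation(stream1, excitation_floor)
    _check_excitation(stream2, excitation_floor)
    starts = starts if starts is not None else AXIS_STARTS

    g1 = stream1.gyro
    g2 = stream2.gyro

    def residual(params: np.ndarray) -> np.ndarray:
        j1 = spherical_to_unit(params[0], params[1])
        j2 = spherical_to_unit(params[2], params[3])
        return np.linalg.norm(np.cross(g1, j1), axis=1) - np.linalg.norm(
            np.cross(g2, j2), axis=1
        )

    best = None
    for s in starts:
        x0 = np.array([s[0], s[1], s[0], s[1]])
        res = least_squares(residual, x0, method="trf")
        if best is None or res.cost < best.cost:
            best = res
    phi1, theta1, phi2, theta2 = best.x
    j1 = spherical_to_unit(phi1, theta1)
    j2 = spherical_to_unit(phi2, theta2)
    if resolve_sign:
        j1, j2 = resolve_axis_sign(j1, j2, stream1, stream2)
        phi1, theta1 = unit_to_spherical(j1)
        phi2, theta2 = unit_to_spherical(j2)
    rms = float(np.sqrt(np.mean(residual(np.array([phi1, theta1, phi2, theta2])) ** 2)))
    info = {
        "sse": float(2.0 * best.cost),
        "spherical": (float(phi1), float(theta1), float(phi2), float(theta2)),
        "success": bool(best.success),
    }
    return j1, j2, rms, info


def center_residuals(
    stream1: ImuStream,
    stream2: ImuStream,
    o1: np.ndarray,
    o2: np.ndarray,
    gdot1: np.ndarray | None = None,
    gdot2: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample joint-center constraint residuals (m/s^2).

    ``r_k = ||a1 - Gamma_g1(o1)|| - ||a2 - Gamma_g2(o2)||``. Angular
    accelerations default to central differences of the gyro channels;
    exact values may be supplied (e.g. from a simulator).
    """
    _check_lengths(stream1, stream2)
    if gdot1 is None:
        gdot1 = gyro_derivative(stream1.gyro, stream1.dt)
    if gdot2 is None:
        gdot2 = gyro_derivative(stream2.gyro, stream2.dt)
    n1 = np.linalg.norm(stream1.accel - gamma(stream1.gyro, gdot1, o1), axis=1)
    n2 = np.linalg.norm(stream2.accel - gamma(stream2.gyro, gdot2, o2), axis=1)
    return n1 - n2


def project_off_axis(o: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Remove the axis-parallel (unidentifiable) component of an offset."""
    j = np.asarray(j, dtype=float)
    o = np.asarray(o, dtype=float)
    return o - np.dot(o, j) * j


def estimate_joint_centers(
    stream1: ImuStream,
    stream2: ImuStream,
    j1: np.ndarray,
    j2: np.ndarray,
    gdot1: np.ndarray | None = None,
    gdot2: np.ndarray | None = None,
    excitation_floor: float = EXCITATION_FLOOR,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Identify the joint-center offsets ``o1``, ``o2``.

    Minimizes the sum of squared :func:`center_residuals` over
    ``(o1, o2) in R^6`` with Trust Region Reflective least squares. A
    *simultaneous* equal shift of both offsets along their axes is a
    null direction of the objective (any point on the hinge axis is a
    valid center); the returned offsets have their axis component
    projected out, i.e. each is the perpendicular offset of its sensor
    from the axis, which is invariant along the null direction.
    ``center_residual_rms`` is evaluated at the raw optimizer solution
    (on the solution manifold). Returns ``(o1, o2, center_residual_rms)``.
    """
    _check_lengths(stream1, stream2)
    _check_excitation(stream1, excitation_floor)
    _check_excitation(stream2, excitation_floor)
    if gdot1 is None:
        gdot1 = gyro_derivative(stream1.gyro, stream1.dt)
    if gdot2 is None:
        gdot2 = gyro_derivative(stream2.gyro, stream2.dt)
    a1, g1 = stream1.accel, stream1.gyro
    a2, g2 = stream2.accel, stream2.gyro

    def residual(params: np.ndarray) -> np.ndarray:
        n1 = np.linalg.norm(a1 - gamma(g1, gdot1, params[:3]), axis=1)
        n2 = np.linalg.norm(a2 - gamma(g2, gdot2, params[3:]), axis=1)
        return n1 - n2

    start = np.zeros(6) if x0 is None else np.asarray(x0, dtype=float)
    res = least_squares(residual, start, method="trf")
    o1 = project_off_axis(res.x[:3], j1)
    o2 = project_off_axis(res.x[3:], j2)
    rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
    return o1, o2, rms


def resolve_axis_sign(
    j1: np.ndarray,
    j2: np.ndarray,
    stream1: ImuStream | None = None,
    stream2: ImuStream | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Make the sign-degenerate axis pair unique.

    The hinge constraint is invariant under flipping either axis. The
    convention here: flip ``j1`` so its largest-magnitude component is
    positive; flip ``j2`` so the axis-projected rates ``g1.j1`` and
    ``g2.j2`` correlate non-negatively (both sensors then agree on the
    flexion sense). With no streams, ``j2`` is given the same
    largest-component rule.
    """
    j1 = np.asarray(j1, dtype=float).copy()
    j2 = np.asarray(j2, dtype=float).copy()
    if j1[np.argmax(np.abs(j1))] < 0:
        j1 = -j1
    if stream1 is None or stream2 is None:
        if j2[np.argmax(np.abs(j2))] < 0:
            j2 = -j2
        return j1, j2
    p1 = stream1.gyro @ j1
    p2 = stream2.gyro @ j2
    s1 = p1 - p1.mean()
    s2 = p2 - p2.mean()
    denom = np.linalg.norm(s1) * np.linalg.norm(s2)
    if denom < 1e-12:
        import warnings

        warnings.warn("near-zero axis-rate correlation; j2 sign left as produced")
        return j1, j2
    if float(s1 @ s2) / denom < 0:
        j2 = -j2
    return j1, j2
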