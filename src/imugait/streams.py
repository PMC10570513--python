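"""Time-series containers for IMU and force-plate recordings.

An :class:`ImuStream` holds one sensor's synchronized channels: timestamps,
3-axis angular rate (rad/s), 3-axis specific force (m/s^2) and, optionally,
the device orientation as unit quaternions (scalar-first, local->global).
A :class:`ForceSeries` holds a body-weight-normalized vertical ground
reaction force record.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gravitational acceleration in the global frame (Z up), m/s^2.
GRAVITY = np.array([0.0, 0.0, -9.81])


class StreamValidationError(ValueError):
    """Raised when a stream's channels violate the container invariants."""


def _as_float_array(x, name: str, ncols: int | None) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if ncols is None:
        if arr.ndim != 1:
            raise StreamValidationError(f"{name} must be 1-D, got shape {arr.shape}")
    else:
        if arr.ndim != 2 or arr.shape[1] != ncols:
            raise StreamValidationError(
                f"{name} must have shape (N, {ncols}), got {arr.shape}"
            )
    return arr


@dataclass
class ImuStream:
    """One inertial sensor's synchronized time series.

    Parameters
    ----------
    time : (N,) array
        Sample times in seconds, strictly increasing and approximately
        uniform (spacing within 1% of the median).
    gyro : (N, 3) array
        Angular rate in rad/s, sensor frame.
    accel : (N, 3) array
        Specific force in m/s^2, sensor frame (a stationary sensor reads
        +9.81 m/s^2 along the local "up" direction).
    orientation : (N, 4) array, optional
        Unit quaternions, scalar-first ``(qw, qx, qy, qz)``, rotating
        sensor-frame vectors into the global frame.
    name : str
        Free-form sensor label (e.g. ``"thigh"``).
    """

    time: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    orientation: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time", None)
        self.gyro = _as_float_array(self.gyro, "gyro", 3)
        self.accel = _as_float_array(self.accel, "accel", 3)
        n = self.time.shape[0]
        if self.gyro.shape[0] != n or self.accel.shape[0] != n:
            raise StreamValidationError("time, gyro and accel lengths differ")
        if n < 2:
            raise StreamValidationError("stream needs at least 2 samples")
        if not np.all(np.isfinite(self.time)):
            raise StreamValidationError("non-finite timestamps")
        bad = np.flatnonzero(
            ~(np.isfinite(self.gyro).all(axis=1) & np.isfinite(self.accel).all(axis=1))
        )
        if bad.size:
            raise StreamValidationError(f"NaN/inf rows at indices {bad[:10].tolist()}")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise StreamValidationError("time must be strictly increasing")
        med = np.median(dt)
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise StreamValidationError("sampling must be uniform within 1%")
        if self.orientation is not None:
            self.orientation = _as_float_array(self.orientation, "orientation", 4)
            if self.orientation.shape[0] != n:
                raise StreamValidationError("orientation length differs")
            norms = np.linalg.norm(self.orientation, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-3):
                raise StreamValidationError("orientation quaternions must be unit-norm")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def dt(self) -> float:
        """Median sample period in seconds."""
        return float(np.median(np.diff(self.time)))

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def slice(self, start: int, stop: int) -> "ImuStream":
        """Return a contiguous sub-record ``[start:stop]``."""
        return ImuStream(
            time=self.time[start:stop],
            gyro=self.gyro[start:stop],
            accel=self.accel[start:stop],
            orientation=None if self.orientation is None else self.orientation[start:stop],
            name=self.name,
        )


@dataclass
class ForceSeries:
    """Body-weight-normalized vertical ground reaction force record."""

    time: np.ndarray
    vgrf: np.ndarray  # BW
    name: str = "vgrf"

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time", None)
        self.vgrf = _as_float_array(self.vgrf, "vgrf", None)
        if self.time.shape != self.vgrf.shape:
            raise StreamValidationError("time and vgrf lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise StreamValidationError("time must be strictly increasing")
        if not np.all(np.isfinite(self.vgrf)):
            raise StreamValidationError("non-finite force samples")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def n(self) -> int:
        return self.time.shape[0]
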