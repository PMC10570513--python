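"""Readers, writers and run manifests.

Time series travel as CSV (diff-able, language-neutral), structured
results as JSON, and model archives as joblib bundles. Column
conventions:

* IMU CSV — ``time_s, gx, gy, gz`` (rad/s), ``ax, ay, az`` (m/s^2) and
  optionally ``qw, qx, qy, qz`` (unit quaternion, scalar first);
* force CSV — ``time_s, vgrf_bw``;
* angle CSV — ``time_s, alpha_gyr_deg, alpha_acc_deg, alpha_deg,
  angvel_dps``;
* cycle-dataset CSV — the ten study columns (subject, speed, stride,
  cycle percent, three angles, three angular velocities, vertical
  acceleration, vGRF label).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import JointGeometry
from .gait_events import ContactList
from .kinematics import AngleSeries
from .streams import ForceSeries, ImuStream, StreamValidationError

IMU_COLUMNS = ("time_s", "gx", "gy", "gz", "ax", "ay", "az")
QUAT_COLUMNS = ("qw", "qx", "qy", "qz")


def read_imu_csv(path: str | Path, name: str = "") -> ImuStream:
    """Read and validate one sensor's CSV record.

    Rejects missing columns, NaN rows (reported with their row numbers)
    and non-monotone or non-uniform timestamps.
    """
    frame = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in frame.columns]
    if missing:
        raise StreamValidationError(f"{path}: missing columns {missing}")
    nan_rows = frame.index[frame[list(IMU_COLUMNS)].isna().any(axis=1)].tolist()
    if nan_rows:
        raise StreamValidationError(f"{path}: NaN rows at {nan_rows[:10]}")
    orientation = None
    if all(c in frame.columns for c in QUAT_COLUMNS):
        orientation = frame[list(QUAT_COLUMNS)].to_numpy(dtype=float)
    return ImuStream(
        time=frame["time_s"].to_numpy(dtype=float),
        gyro=frame[["gx", "gy", "gz"]].to_numpy(dtype=float),
        accel=frame[["ax", "ay", "az"]].to_numpy(dtype=float),
        orientation=orientation,
        name=name or Path(path).stem,
    )


def write_imu_csv(stream: ImuStream, path: str | Path) -> None:
    data = {
        "time_s": stream.time,
        "gx": stream.gyro[:, 0],
        "gy": stream.gyro[:, 1],
        "gz": stream.gyro[:, 2],
        "ax": stream.accel[:, 0],
        "ay": stream.accel[:, 1],
        "az": stream.accel[:, 2],
    }
    if stream.orientation is not None:
        for i, c in enumerate(QUAT_COLUMNS):
            data[c] = stream.orientation[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def read_force_csv(path: str | Path) -> ForceSeries:
    frame = pd.read_csv(path)
    for c in ("time_s", "vgrf_bw"):
        if c not in frame.columns:
            raise StreamValidationError(f"{path}: missing column {c}")
    return ForceSeries(
        time=frame["time_s"].to_numpy(dtype=float),
        vgrf=frame["vgrf_bw"].to_numpy(dtype=float),
    )


def write_force_csv(force: ForceSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": force.time, "vgrf_bw": force.vgrf}).to_csv(path, index=False)


def write_angles_csv(series: AngleSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": series.time,
            "alpha_gyr_deg": series.alpha_gyr,
            "alpha_acc_deg": series.alpha_acc,
            "alpha_deg": series.alpha,
            "angvel_dps": (
                series.angular_velocity
                if series.angular_velocity is not None
                else np.full_like(series.alpha, np.nan)
            ),
        }
    ).to_csv(path, index=False)


def write_geometry_json(
    geometry: JointGeometry | dict[str, JointGeometry], path: str | Path, seed: int | None = None
) -> None:
    if isinstance(geometry, JointGeometry):
        payload: dict = geometry.to_dict()
    else:
        payload = {joint: g.to_dict() for joint, g in geometry.items()}
    payload["_meta"] = {"tool": "imugait", "version": __version__, "seed": seed}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_geometry_json(path: str | Path) -> JointGeometry | dict[str, JointGeometry]:
    payload = json.loads(Path(path).read_text())
    payload.pop("_meta", None)
    if "j1" in payload:
        return JointGeometry.from_dict(payload)
    return {joint: JointGeometry.from_dict(d) for joint, d in payload.items()}


def write_contacts_json(contacts: ContactList, path: str | Path, seed: int | None = None) -> None:
    payload = {
        "source": contacts.source,
        "times_s": contacts.times.tolist(),
        "toeoffs_s": contacts.toeoffs.tolist() if contacts.toeoffs is not None else None,
        "_meta": {"tool": "imugait", "version": __version__, "seed": seed},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_contacts_json(path: str | Path) -> ContactList:
    payload = json.loads(Path(path).read_text())
    toeoffs = payload.get("toeoffs_s")
    return ContactList(
        times=np.array(payload["times_s"], dtype=float),
        source=payload["source"],
        toeoffs=None if toeoffs is None else np.array(toeoffs, dtype=float),
    )


def write_dataset_csv(dataset: pd.DataFrame, path: str | Path) -> None:
    dataset.to_csv(path, index=False, float_format="%.10g")


def read_dataset_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, artifacts: list[str | Path], seed: int, config: dict | None = None
) -> Path:
    """Write a manifest reconciling every produced artifact with its hash."""
    out_dir = Path(out_dir)
    entries = {
        str(Path(p).relative_to(out_dir)): sha256_file(p) for p in artifacts
    }
    config_hash = (
        hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        if config is not None
        else None
    )
    manifest = {
        "tool": "imugait",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash,
        "artifacts": entries,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
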