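"""Foot-contact detection, stride segmentation and cycle normalization.

Contacts are detected in two modalities:

* IMU — the anteroposterior hip acceleration is zero-phase low-pass
  filtered at 2 Hz; its local maxima mark foot-ground contacts.
* Force plate — the vGRF onset: a rising crossing of a small threshold
  (default 0.03 BW) sustained for a few samples, backtracked to the last
  unloaded sample, so a contact that falls exactly on a force sample is
  recovered exactly. Toe-offs (stance ends) are located symmetrically.

Each inter-contact interval is a stride; strides are mapped onto a fixed
0-100% cycle grid (101 points) by linear interpolation, and the two
modalities are joined row-wise on (stride, cycle %) so every kinematic
sample receives the vGRF value at the same gait instant. The 60 Hz IMU
and 100 Hz force records are each interpolated onto the cycle grid
directly; no time-domain resampling occurs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .kinematics import lowpass_zero_phase

__all__ = [
    "ContactList",
    "CYCLE_GRID",
    "detect_contacts_imu",
    "detect_contacts_grf",
    "segment_and_normalize",
    "synchronize",
]

logger = logging.getLogger(__name__)

#: Fixed gait-cycle grid in percent (standard 101-point convention).
CYCLE_GRID = np.linspace(0.0, 100.0, 101)

#: Stride-duration validation bounds in seconds (covers 1.5-4.5 km/h walking).
STRIDE_BOUNDS = (0.5, 3.0)


@dataclass
class ContactList:
    """Foot-ground contact instants from one modality."""

    times: np.ndarray
    source: str  # "imu" | "grf"
    toeoffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("contact times must be strictly increasing")
        if self.toeoffs is not None:
            self.toeoffs = np.asarray(self.toeoffs, dtype=float)

    @property
    def n_strides(self) -> int:
        return max(0, self.times.size - 1)


def detect_contacts_imu(
    ap_accel: np.ndarray,
    rate: float,
    time: np.ndarray | None = None,
    cutoff: float = 2.0,
    min_separation_factor: float = 0.4,
    min_prominence_frac: float = 0.1,
    edge_guard_s: float = 0.0,
) -> ContactList:
    """Contacts from the anteroposterior hip acceleration.

    Zero-phase 2 Hz low-pass, then local maxima with a prominence of at
    least ``min_prominence_frac`` of the filtered signal's range and a
    minimum peak separation of ``min_separation_factor`` times the
    median inter-peak interval (two-pass). ``edge_guard_s`` discards
    maxima closer than that to either record edge, where the zero-phase
    filter's transient can distort or invent peaks. Returns an empty
    list (with a warning log) when the signal carries no maxima.
    """
    ap_accel = np.asarray(ap_accel, dtype=float)
    if ap_accel.size < 3 * rate:
        raise ValueError("need at least 3 s of data for contact detection")
    t = np.arange(ap_accel.size) / rate if time is None else np.asarray(time, float)
    filtered = lowpass_zero_phase(ap_accel, rate, cutoff)
    if np.ptp(filtered) < 1e-12:
        logger.warning("constant hip acceleration; no contacts found")
        return ContactList(times=np.array([]), source="imu")
    prominence = min_prominence_frac * np.ptp(filtered)
    peaks, _ = find_peaks(filtered, prominence=prominence)
    if peaks.size == 0:
        logger.warning("no maxima in filtered hip acceleration")
        return ContactList(times=np.array([]), source="imu")
    if peaks.size > 2:
        med = np.median(np.diff(peaks))
        peaks, _ = find_peaks(
            filtered,
            prominence=prominence,
            distance=max(1, int(min_separation_factor * med)),
        )
    if edge_guard_s > 0:
        keep = (t[peaks] >= t[0] + edge_guard_s) & (t[peaks] <= t[-1] - edge_guard_s)
        peaks = peaks[keep]
    return ContactList(times=t[peaks], source="imu")


def detect_contacts_grf(
    force,
    threshold: float = 0.03,
    sustain: int = 3,
    time: np.ndarray | None = None,
) -> ContactList:
    """Contact onsets (and toe-offs) from the vGRF record.

    An onset is a rising crossing of ``threshold`` (BW) sustained for
    ``sustain`` samples, backtracked to the last unloaded sample — the
    instant the force starts growing. A toe-off is the matching falling
    crossing, advanced to the first unloaded sample.
    ``force`` may be a :class:`~imugait.streams.ForceSeries` or an array
    (then ``time`` must be given).
    """
    if hasattr(force, "vgrf"):
        values = np.asarray(force.vgrf, dtype=float)
        t = force.time
    else:
        values = np.asarray(force, dtype=float)
        if time is None:
            raise ValueError("time array required when force is a plain array")
        t = np.asarray(time, dtype=float)
    if np.any(values < 0):
        raise ValueError("vGRF must be non-negative")
    n = values.size
    above = values >= threshold
    onsets, toeoffs = [], []
    loaded = bool(above[0])
    for k in range(1, n):
        if not loaded and above[k]:
            if not np.all(above[k : min(n, k + sustain)]):
                continue
            i = k
            while i > 0 and 0 < values[i - 1] < values[i]:
                i -= 1
            if i > 0 and values[i - 1] == 0:
                i -= 1
            onsets.append(i)
            loaded = True
        elif loaded and not above[k]:
            i = k
            while i + 1 < n and 0 < values[i + 1] < values[i]:
                i += 1
            if values[i] > 0 and i + 1 < n and values[i + 1] == 0:
                i += 1
            toeoffs.append(i)
            loaded = False
    return ContactList(
        times=t[np.array(onsets, dtype=int)] if onsets else np.array([]),
        source="grf",
        toeoffs=t[np.array(toeoffs, dtype=int)] if toeoffs else np.array([]),
    )


def match_contacts(
    imu: ContactList, grf: ContactList, tol_frac: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Pair IMU and force-plate contacts marking the same physical stride.

    Greedy nearest-time matching: a pair is accepted when the two
    instants differ by less than ``tol_frac`` of the median stride
    period, and matches are kept strictly increasing in both lists.
    Synchronization then starts from the first contact seen by *both*
    modalities, and unpaired contacts (filter warm-up, partial strides
    at the record edges) are discarded.
    """
    ti, tg = imu.times, grf.times
    if ti.size == 0 or tg.size == 0:
        return np.array([]), np.array([])
    ref = tg if tg.size >= 2 else ti
    tol = tol_frac * float(np.median(np.diff(ref))) if ref.size >= 2 else np.inf
    mi, mg = [], []
    last_i = -1
    for g in tg:
        j = int(np.argmin(np.abs(ti - g)))
        if abs(ti[j] - g) <= tol and j > last_i:
            mi.append(ti[j])
            mg.append(g)
            last_i = j
    return np.asarray(mi), np.asarray(mg)


def segment_and_normalize(
    time: np.ndarray,
    values: np.ndarray,
    contacts: ContactList | np.ndarray,
    grid: np.ndarray = CYCLE_GRID,
    stride_bounds: tuple[float, float] = STRIDE_BOUNDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Map each inter-contact interval onto the fixed cycle grid.

    Returns ``(curves, kept)`` where ``curves`` has one row of
    ``len(grid)`` linearly interpolated samples per retained stride and
    ``kept`` holds the indices of the retained strides (strides whose
    duration falls outside ``stride_bounds`` are dropped and logged).
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    ctimes = contacts.times if isinstance(contacts, ContactList) else np.asarray(contacts, float)
    if ctimes.size < 2:
        return np.empty((0, len(grid))), np.array([], dtype=int)
    curves, kept = [], []
    n_dropped = 0
    for k in range(ctimes.size - 1):
        t0, t1 = ctimes[k], ctimes[k + 1]
        dur = t1 - t0
        if not (stride_bounds[0] <= dur <= stride_bounds[1]):
            n_dropped += 1
            logger.info("stride %d dropped: duration %.3f s outside %s", k, dur, stride_bounds)
            continue
        sample_t = t0 + grid / 100.0 * dur
        curves.append(np.interp(sample_t, time, values))
        kept.append(k)
    if n_dropped:
        logger.info("%d/%d strides dropped by duration validation", n_dropped, ctimes.size - 1)
    return np.asarray(curves).reshape(len(kept), len(grid)), np.asarray(kept, dtype=int)


def synchronize(
    imu_curves: dict[str, np.ndarray],
    grf_curves: np.ndarray,
    grid: np.ndarray = CYCLE_GRID,
    subject: int = 0,
    speed: float = np.nan,
) -> pd.DataFrame:
    """Join cycle-domain kinematics with cycle-domain vGRF labels.

    ``imu_curves`` maps feature names to per-stride cycle curves (all of
    shape ``(n_strides, len(grid))``); ``grf_curves`` is the matching
    vGRF array. Both modalities must have been segmented starting from
    their first common foot contact; a stride-count mismatch beyond one
    stride raises, within one stride the surplus tail is trimmed. Empty
    inputs yield an empty frame.
    """
    names = list(imu_curves)
    if not names:
        raise ValueError("no kinematic curves supplied")
    n_imu = imu_curves[names[0]].shape[0]
    for name in names:
        if imu_curves[name].shape != (n_imu, len(grid)):
            raise ValueError(f"curve {name!r} has inconsistent shape")
    n_grf = grf_curves.shape[0]
    if abs(n_imu - n_grf) > 1:
        raise ValueError(
            f"stride-count mismatch between modalities: {n_imu} IMU vs {n_grf} GRF strides"
        )
    n = min(n_imu, n_grf)
    if n == 0:
        return pd.DataFrame(
            columns=["subject", "speed", "stride", "cycle_pct", *names, "vgrf"]
        )
    rows = {
        "subject": np.repeat(subject, n * len(grid)),
        "speed": np.repeat(speed, n * len(grid)),
        "stride": np.repeat(np.arange(n), len(grid)),
        "cycle_pct": np.tile(grid, n),
    }
    for name in names:
        rows[name] = imu_curves[name][:n].ravel()
    rows["vgrf"] = grf_curves[:n].ravel()
    return pd.DataFrame(rows)
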