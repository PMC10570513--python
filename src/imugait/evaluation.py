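"""Accuracy metrics for estimated vGRF waveforms and joint angles.

Implements the per-stride RMSE (BW), the range-normalized RMSE
(``RMSE / (max(vGRF_measured) - min(vGRF_measured))``), Pearson's
correlation, and the characteristic-peak analysis of the walking vGRF
double bump: loading peak (LP, local maximum in the first half of
stance), mid-stance minimum (MP) and terminal-stance peak (TP, local
maximum in the second half of stance), with magnitude errors (BW,
absolute) and timing delays (% cycle, signed: positive = estimated peak
late).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeakSet",
    "PeaksNotFoundError",
    "rmse",
    "rmse_per_stride",
    "nrmse",
    "pearson_correlation",
    "detect_vgrf_peaks",
    "peak_errors",
    "align_angle_convention",
    "angle_rmse",
    "evaluate_predictions",
]


class PeaksNotFoundError(RuntimeError):
    """Raised when a stance window carries no double-bump structure."""


@dataclass
class PeakSet:
    """LP/MP/TP magnitudes (BW) and timings (% of gait cycle) of one stride."""

    lp: float
    mp: float
    tp: float
    t_lp: float
    t_mp: float
    t_tp: float

    def __post_init__(self) -> None:
        if not (self.t_lp < self.t_mp < self.t_tp):
            raise ValueError("peak timings must be ordered LP < MP < TP")
        if self.mp > min(self.lp, self.tp) + 1e-12:
            raise ValueError("mid-stance value must not exceed LP or TP")
        if min(self.lp, self.mp, self.tp) < 0:
            raise ValueError("peak magnitudes must be non-negative")

    def magnitudes(self) -> np.ndarray:
        return np.array([self.lp, self.mp, self.tp])

    def timings(self) -> np.ndarray:
        return np.array([self.t_lp, self.t_mp, self.t_tp])


def rmse(measured: np.ndarray, estimated: np.ndarray) -> float:
    """Root mean squared difference of two equal-length series."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape:
        raise ValueError("series must have equal shapes")
    return float(np.sqrt(np.mean((measured - estimated) ** 2)))


def rmse_per_stride(
    measured: np.ndarray, estimated: np.ndarray, stride_index: np.ndarray
) -> pd.Series:
    """Per-stride RMSE (BW), indexed by stride label."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    stride_index = np.asarray(stride_index)
    if not (measured.shape == estimated.shape == stride_index.shape):
        raise ValueError("inputs must share one grid per stride")
    df = pd.DataFrame(
        {"sq": (measured - estimated) ** 2, "stride": stride_index}
    )
    return df.groupby("stride", sort=True)["sq"].mean().pow(0.5)


def nrmse(measured: np.ndarray, estimated: np.ndarray) -> float:
    """RMSE normalized by the range of the *measured* signal."""
    measured = np.asarray(measured, dtype=float)
    rng = float(measured.max() - measured.min())
    if rng <= 0:
        raise ValueError("measured series is constant; NRMSE undefined")
    return rmse(measured, estimated) / rng


def pearson_correlation(measured: np.ndarray, estimated: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if np.std(measured) == 0 or np.std(estimated) == 0:
        raise ValueError("correlation undefined for constant series")
    return float(stats.pearsonr(measured, estimated).statistic)


def detect_vgrf_peaks(
    vgrf: np.ndarray,
    cycle_pct: np.ndarray | None = None,
    stance_start: float = 0.0,
    stance_end: float = 62.0,
) -> PeakSet:
    """Locate LP, MP and TP on a cycle-domain vGRF curve.

    LP is the maximum over the first half of the stance window, TP the
    maximum over the second half, and MP the minimum strictly between
    them. Raises :class:`PeaksNotFoundError` when stance has no interior
    minimum (e.g. a flat or monotone curve).
    """
    vgrf = np.asarray(vgrf, dtype=float)
    cycle_pct = (
        np.linspace(0.0, 100.0, len(vgrf))
        if cycle_pct is None
        else np.asarray(cycle_pct, dtype=float)
    )
    mid = 0.5 * (stance_start + stance_end)
    first = np.flatnonzero((cycle_pct >= stance_start) & (cycle_pct <= mid))
    second = np.flatnonzero((cycle_pct > mid) & (cycle_pct <= stance_end))
    if first.size == 0 or second.size == 0:
        raise PeaksNotFoundError("stance window contains no samples")
    i_lp = first[np.argmax(vgrf[first])]
    i_tp = second[np.argmax(vgrf[second])]
    interior = np.arange(i_lp + 1, i_tp)
    if interior.size == 0:
        raise PeaksNotFoundError("no samples between LP and TP candidates")
    i_mp = interior[np.argmin(vgrf[interior])]
    if not (vgrf[i_mp] < vgrf[i_lp] and vgrf[i_mp] < vgrf[i_tp]):
        raise PeaksNotFoundError(
            "stance has no interior minimum between its halves "
            f"(LP={vgrf[i_lp]:.3f}, min={vgrf[i_mp]:.3f}, TP={vgrf[i_tp]:.3f} BW); "
            "the curve is flat or monotone over stance"
        )
    return PeakSet(
        lp=float(vgrf[i_lp]),
        mp=float(vgrf[i_mp]),
        tp=float(vgrf[i_tp]),
        t_lp=float(cycle_pct[i_lp]),
        t_mp=float(cycle_pct[i_mp]),
        t_tp=float(cycle_pct[i_tp]),
    )


def peak_errors(
    measured: PeakSet, estimated: PeakSet
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute magnitude errors (BW) and signed delays (% cycle).

    Delay = estimated timing - measured timing; positive means the
    estimated peak occurs later in the cycle.
    """
    mag = np.abs(estimated.magnitudes() - measured.magnitudes())
    delay = estimated.timings() - measured.timings()
    return mag, delay


def align_angle_convention(
    estimated: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Resolve the sign/offset ambiguity of a hinge-angle estimate.

    The gyro/accel angle chain measures the hinge angle up to an overall
    sign (axis-sign degeneracy) and an additive constant (joint-plane
    reference choice). Returns the estimate with the sign and constant
    offset chosen to minimize the RMSE against the reference; drift and
    noise are unaffected.
    """
    estimated = np.asarray(estimated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    best = None
    for sign in (1.0, -1.0):
        offset = float(np.mean(reference - sign * estimated))
        cand = sign * estimated + offset
        err = float(np.sqrt(np.mean((cand - reference) ** 2)))
        if best is None or err < best[0]:
            best = (err, cand)
    return best[1]


def angle_rmse(estimated: np.ndarray, reference: np.ndarray) -> float:
    """RMSE (deg) after sign/offset convention alignment."""
    return rmse(reference, align_angle_convention(estimated, reference))


def evaluate_predictions(
    frame: pd.DataFrame,
    measured_col: str = "vgrf",
    estimated_col: str = "vgrf_pred",
    group_cols: tuple[str, ...] = ("speed",),
    stride_cols: tuple[str, ...] = ("subject", "speed", "stride"),
    stance_end: float = 62.0,
) -> dict:
    """Grouped evaluation report for a predictions table.

    ``frame`` must carry cycle-domain rows with measured and estimated
    vGRF plus stride/grouping metadata. Returns per-group RMSE mean/sd
    over strides, NRMSE, Pearson correlation, and mean LP/MP/TP
    magnitude errors and delays over the strides where both curves carry
    a double bump.
    """
    report: dict = {"groups": {}}

    def _group_metrics(g: pd.DataFrame) -> dict:
        meas = g[measured_col].to_numpy()
        est = g[estimated_col].to_numpy()
        stride_key = pd.MultiIndex.from_frame(g[list(stride_cols)])
        per_stride = rmse_per_stride(meas, est, stride_key.to_numpy())
        mags, delays, n_failed = [], [], 0
        for _, s in g.groupby(list(stride_cols), sort=False):
            try:
                pk_m = detect_vgrf_peaks(
                    s[measured_col].to_numpy(),
                    s["cycle_pct"].to_numpy(),
                    stance_end=stance_end,
                )
                pk_e = detect_vgrf_peaks(
                    s[estimated_col].to_numpy(),
                    s["cycle_pct"].to_numpy(),
                    stance_end=stance_end,
                )
            except (PeaksNotFoundError, ValueError):
                n_failed += 1
                continue
            m, d = peak_errors(pk_m, pk_e)
            mags.append(m)
            delays.append(d)
        out = {
            "rmse_mean": float(per_stride.mean()),
            "rmse_sd": float(per_stride.std(ddof=1)) if len(per_stride) > 1 else 0.0,
            "nrmse": nrmse(meas, est),
            "pearson_r": pearson_correlation(meas, est),
            "n_strides": int(len(per_stride)),
            "n_peak_failures": n_failed,
        }
        if mags:
            mag_mean = np.mean(mags, axis=0)
            delay_mean = np.mean(delays, axis=0)
            out["peak_magnitude_error"] = {
                "LP": float(mag_mean[0]),
                "MP": float(mag_mean[1]),
                "TP": float(mag_mean[2]),
            }
            out["peak_delay"] = {
                "LP": float(delay_mean[0]),
                "MP": float(delay_mean[1]),
                "TP": float(delay_mean[2]),
            }
        return out

    for keys, g in frame.groupby(list(group_cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        label = "/".join(str(k) for k in keys)
        report["groups"][label] = _group_metrics(g)
    report["global"] = _group_metrics(frame)
    return report
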