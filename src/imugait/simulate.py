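"""Synthetic IMU and force-plate data with exact ground truth.

Two generators stand in for treadmill recordings that a gait laboratory
would otherwise supply:

``simulate_hinge``
    Exact rigid-body motion of two segments coupled by a hinge, with an
    IMU mounted at an arbitrary pose on each segment. Angular rates,
    angular accelerations and specific forces are evaluated analytically,
    so at zero noise the hinge-axis constraint
    ``||g1 x j1|| = ||g2 x j2||`` and the joint-center constraint
    ``||a1 - Gamma(o1)|| = ||a2 - Gamma(o2)||`` hold to machine
    precision at the true geometry.

``simulate_gait``
    A planar (sagittal) lower-limb chain — pelvis, thigh, shank, foot —
    driven by periodic joint-angle templates, plus a C7 trunk sensor,
    walked at several treadmill speeds. Produces the five IMU streams at
    60 Hz, a body-weight-normalized vGRF record at 100 Hz built from a
    monotone-cubic double-bump template (exactly zero in swing), and the
    full ground truth: mounting geometry, joint angles, contact times,
    per-stride peak sets and per-sample force.

All randomness is drawn from a single seeded generator; equal seeds give
bitwise-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.spatial.transform import Rotation

from .calibration import JointGeometry
from .evaluation import PeakSet
from .streams import GRAVITY, ForceSeries, ImuStream

__all__ = [
    "HingeSimConfig",
    "GaitSimConfig",
    "GroundTruth",
    "GaitTrial",
    "simulate_hinge",
    "vgrf_template",
    "simulate_gait",
    "default_peak_template",
    "default_kinematic_templates",
]

JOINTS = ("hip", "knee", "ankle")
SENSORS = ("pelvis", "thigh", "shank", "foot", "c7")
#: Sensor pair spanning each joint (proximal, distal).
JOINT_SENSORS = {"hip": ("pelvis", "thigh"), "knee": ("thigh", "shank"), "ankle": ("shank", "foot")}


# ---------------------------------------------------------------------------
# hinge simulation
# ---------------------------------------------------------------------------


@dataclass
class HingeSimConfig:
    """Two-segment hinge recording parameters.

    The hinge angle follows a named waveform (``"sinusoid"`` or
    ``"gait_like"``, a multi-harmonic knee-like profile) with the given
    amplitude (deg) and fundamental frequency (Hz). The assembly as a
    whole rotates slowly about two fixed axes and its joint center
    translates sinusoidally with ``base_motion_amplitude`` (m), so that
    both sensors are richly excited. Gyro bias may be a 3-vector
    (applied to both sensors) or a scalar magnitude given a seeded random
    direction per sensor.
    """

    duration: float = 60.0
    rate: float = 60.0
    true_axis_1: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    true_axis_2: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    true_center_1: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.02, -0.20]))
    true_center_2: np.ndarray = field(default_factory=lambda: np.array([0.03, -0.01, 0.15]))
    angle_waveform: str = "gait_like"
    amplitude_deg: float = 60.0
    frequency_hz: float = 0.9
    base_motion_amplitude: float = 0.08
    base_rotation_amplitude: float = 0.45
    gyro_noise_sd: float = 0.0
    accel_noise_sd: float = 0.0
    gyro_bias: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be positive")
        if self.gyro_noise_sd < 0 or self.accel_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for name in ("true_axis_1", "true_axis_2"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be a unit vector")
            setattr(self, name, v)
        self.true_center_1 = np.asarray(self.true_center_1, dtype=float)
        self.true_center_2 = np.asarray(self.true_center_2, dtype=float)
        if self.angle_waveform not in ("sinusoid", "gait_like"):
            raise ValueError("angle_waveform must be 'sinusoid' or 'gait_like'")


@dataclass
class GroundTruth:
    """Known quantities of a simulated recording (fields filled as relevant)."""

    geometry: dict[str, JointGeometry] | None = None
    angle_deg: dict[str, np.ndarray] | None = None
    angular_velocity_dps: dict[str, np.ndarray] | None = None
    gyro_dot: dict[str, np.ndarray] | None = None
    clean_streams: dict[str, ImuStream] | None = None
    contact_times: np.ndarray | None = None
    toeoff_times: np.ndarray | None = None
    peak_sets: list[PeakSet] | None = None
    vgrf: np.ndarray | None = None
    vgrf_time: np.ndarray | None = None
    a_vert: np.ndarray | None = None
    stance_fraction: float | None = None


def _hinge_waveform(cfg: HingeSimConfig, t: np.ndarray):
    """Hinge angle (rad) and its first two analytic derivatives."""
    A = np.radians(cfg.amplitude_deg)
    w = 2 * np.pi * cfg.frequency_hz
    if cfg.angle_waveform == "sinusoid":
        terms = [(1.0, 1, 0.0)]
    else:  # knee-like: dominant fundamental plus two harmonics
        terms = [(0.55, 1, 0.0), (0.30, 2, 1.2), (0.15, 3, -0.5)]
    a = np.zeros_like(t)
    da = np.zeros_like(t)
    dda = np.zeros_like(t)
    for amp, mult, phase in terms:
        wm = w * mult
        a += A * amp * np.sin(wm * t + phase)
        da += A * amp * wm * np.cos(wm * t + phase)
        dda += -A * amp * wm**2 * np.sin(wm * t + phase)
    return a, da, dda


def _sinusoid(t, amp, freq, phase):
    w = 2 * np.pi * freq
    x = amp * np.sin(w * t + phase)
    dx = amp * w * np.cos(w * t + phase)
    ddx = -amp * w**2 * np.sin(w * t + phase)
    return x, dx, ddx


def _align_rotation(a: np.ndarray, b: np.ndarray) -> Rotation:
    """A rotation sending unit vector ``a`` to unit vector ``b``."""
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        # 180 degrees about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis)
    axis = v / s
    return Rotation.from_rotvec(np.arctan2(s, c) * axis)


def _quat_scalar_first(rot: Rotation) -> np.ndarray:
    return np.roll(rot.as_quat(), 1, axis=-1)


def simulate_hinge(config: HingeSimConfig) -> tuple[ImuStream, ImuStream, GroundTruth]:
    """Simulate one hinge-joint recording with exact ground truth.

    Returns the two sensor streams (with configured noise and bias
    applied) and a :class:`GroundTruth` carrying the true geometry, the
    hinge angle (deg), the exact angular accelerations, and noise-free
    copies of both streams.
    """
    cfg = config
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    rng = np.random.default_rng(cfg.seed)

    j1, j2 = cfg.true_axis_1, cfg.true_axis_2
    o1, o2 = cfg.true_center_1, cfg.true_center_2

    # Whole-assembly rotation: R1 = Rot(u, psi) Rot(v, chi).
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([0.0, 1.0, 0.0])
    psi, dpsi, ddpsi = _sinusoid(t, cfg.base_rotation_amplitude, 0.31, 0.4)
    chi, dchi, ddchi = _sinusoid(t, 0.65 * cfg.base_rotation_amplitude, 0.53, 1.1)
    alpha, dalpha, ddalpha = _hinge_waveform(cfg, t)

    rot_u = Rotation.from_rotvec(np.outer(psi, u))
    rot_v = Rotation.from_rotvec(np.outer(chi, v))
    r1 = rot_u * rot_v
    ru_v = rot_u.apply(v)  # Rot(u, psi) v
    omega1 = dpsi[:, None] * u + dchi[:, None] * ru_v
    domega1 = (
        ddpsi[:, None] * u
        + ddchi[:, None] * ru_v
        + (dchi * dpsi)[:, None] * np.cross(u, ru_v)
    )

    # Hinge convention: the ground-truth angle is the rotation of segment 1
    # relative to segment 2 about the axis, i.e. the quantity the axis-
    # projected rate difference g1.j1 - g2.j2 integrates to.
    nvec = r1.apply(j1)  # global hinge axis
    omega2 = omega1 - dalpha[:, None] * nvec
    domega2 = domega1 - ddalpha[:, None] * nvec - dalpha[:, None] * np.cross(omega1, nvec)

    align = _align_rotation(j2, j1)  # C j2 = j1
    r2 = r1 * Rotation.from_rotvec(np.outer(-alpha, j1)) * align

    # Joint-center translation with analytic second derivative.
    p_ddot = np.zeros((n, 3))
    for axis, (freq, phase) in enumerate(((1.1, 0.0), (0.8, 1.0), (1.4, 2.1))):
        _, _, dd = _sinusoid(t, cfg.base_motion_amplitude, freq, phase)
        p_ddot[:, axis] = dd

    g1 = r1.inv().apply(omega1)
    g2 = r2.inv().apply(omega2)
    gdot1 = r1.inv().apply(domega1)
    gdot2 = r2.inv().apply(domega2)

    def specific_force(r: Rotation, g, gdot, o):
        gam = np.cross(g, np.cross(g, o)) + np.cross(gdot, o)
        return r.inv().apply(p_ddot - GRAVITY) + gam

    a1 = specific_force(r1, g1, gdot1, o1)
    a2 = specific_force(r2, g2, gdot2, o2)

    bias = np.asarray(cfg.gyro_bias, dtype=float)
    if bias.ndim == 0:
        def _bias_vec():
            d = rng.normal(size=3)
            return float(bias) * d / np.linalg.norm(d)
        bias1, bias2 = _bias_vec(), _bias_vec()
    else:
        bias1 = bias2 = bias

    def _noisy(arr, sd, b):
        out = arr + b
        if sd > 0:
            out = out + rng.normal(scale=sd, size=arr.shape)
        return out

    quat1 = _quat_scalar_first(r1)
    quat2 = _quat_scalar_first(r2)
    clean1 = ImuStream(t, g1, a1, orientation=quat1, name="hinge1")
    clean2 = ImuStream(t, g2, a2, orientation=quat2, name="hinge2")
    s1 = ImuStream(
        t, _noisy(g1, cfg.gyro_noise_sd, bias1), _noisy(a1, cfg.accel_noise_sd, 0.0),
        orientation=quat1, name="hinge1",
    )
    s2 = ImuStream(
        t, _noisy(g2, cfg.gyro_noise_sd, bias2), _noisy(a2, cfg.accel_noise_sd, 0.0),
        orientation=quat2, name="hinge2",
    )

    truth = GroundTruth(
        geometry={"joint": JointGeometry(j1=j1, j2=j2, o1=o1, o2=o2,
                                         axis_residual_rms=0.0, center_residual_rms=0.0)},
        angle_deg={"joint": np.degrees(alpha)},
        angular_velocity_dps={"joint": np.degrees(dalpha)},
        gyro_dot={"hinge1": gdot1, "hinge2": gdot2},
        clean_streams={"hinge1": clean1, "hinge2": clean2},
    )
    return s1, s2, truth


# ---------------------------------------------------------------------------
# vGRF template
# ---------------------------------------------------------------------------


def vgrf_template(
    cycle_pct: np.ndarray | float,
    peaks: PeakSet,
    stance_end: float = 62.0,
) -> np.ndarray | float:
    """Double-bump walking vGRF (BW) as a function of cycle percent.

    Monotone cubic (PCHIP) interpolation through ``(0, 0)``, the LP, MP
    and TP anchors and ``(stance_end, 0)``; identically zero in swing.
    The monotone segments guarantee the configured peaks are the exact
    extrema of the template.
    """
    if not (0.0 < peaks.t_lp and peaks.t_tp < stance_end <= 100.0):
        raise ValueError("peak timings must lie strictly inside stance")
    c = np.asarray(cycle_pct, dtype=float)
    if np.any(c < 0.0) or np.any(c > 100.0):
        raise ValueError("cycle_pct must lie in [0, 100]")
    x = np.array([0.0, peaks.t_lp, peaks.t_mp, peaks.t_tp, stance_end])
    y = np.array([0.0, peaks.lp, peaks.mp, peaks.tp, 0.0])
    interp = PchipInterpolator(x, y)
    out = np.where(c < stance_end, interp(np.clip(c, 0.0, stance_end)), 0.0)
    return float(out) if np.isscalar(cycle_pct) else out


# ---------------------------------------------------------------------------
# gait simulation
# ---------------------------------------------------------------------------


def default_peak_template() -> dict[float, PeakSet]:
    """Per-speed LP/MP/TP anchors (BW, % cycle) for treadmill walking.

    Slower walking flattens the double bump; faster walking deepens the
    mid-stance valley and raises both maxima.
    """
    return {
        1.5: PeakSet(lp=1.02, mp=0.95, tp=1.00, t_lp=15.0, t_mp=30.0, t_tp=45.0),
        2.5: PeakSet(lp=1.05, mp=0.88, tp=1.03, t_lp=15.0, t_mp=30.0, t_tp=45.0),
        3.5: PeakSet(lp=1.10, mp=0.80, tp=1.07, t_lp=15.0, t_mp=30.0, t_tp=45.0),
        4.5: PeakSet(lp=1.15, mp=0.72, tp=1.10, t_lp=15.0, t_mp=30.0, t_tp=45.0),
    }


def default_kinematic_templates() -> dict[str, list[tuple[float, float]]]:
    """Control points (cycle %, deg) of smooth periodic joint-angle curves."""
    return {
        "hip": [(0, 25), (10, 22), (30, 5), (50, -10), (62, -6), (75, 15), (90, 25)],
        "knee": [(0, 5), (15, 18), (40, 5), (60, 35), (73, 60), (85, 25), (95, 8)],
        "ankle": [(0, 0), (10, -5), (30, 5), (50, 10), (62, -15), (75, -5), (90, 2)],
        "pelvis": [(0, 2.0), (25, -1.0), (50, 2.0), (75, -1.0)],
    }


def _periodic_spline(points: list[tuple[float, float]]) -> CubicSpline:
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    x = np.append(x, x[0] + 100.0)
    y = np.append(y, y[0])
    return CubicSpline(x / 100.0, y, bc_type="periodic")  # argument: cycle fraction


@dataclass
class GaitSimConfig:
    """Multi-subject, multi-speed synthetic gait study parameters.

    Defaults emulate treadmill walking at 1.5/2.5/3.5/4.5 km/h with the
    right-leg kinematics of an able-bodied adult: IMUs at 60 Hz, force
    plate at 100 Hz, vGRF normalized by body weight, stance occupying
    62% of the cycle and exactly zero force in swing.
    """

    n_subjects: int = 12
    speeds: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5)
    strides_per_speed: int = 8
    cadence_spm: tuple[float, ...] = (42.0, 47.0, 52.0, 57.0)  # strides/min per speed
    peak_template: dict[float, PeakSet] = field(default_factory=default_peak_template)
    kinematic_templates: dict[str, list[tuple[float, float]]] = field(
        default_factory=default_kinematic_templates
    )
    stance_end: float = 62.0
    vertical_accel_amplitude: float = 2.0  # m/s^2 at C7
    ap_accel_amplitude: float = 1.5  # m/s^2 anteroposterior bump at the hip
    imu_rate: float = 60.0
    grf_rate: float = 100.0
    gyro_noise_sd: float = 0.01
    accel_noise_sd: float = 0.1
    gyro_bias: float = 0.005
    grf_noise_rel: float = 0.01  # multiplicative, stance only
    subject_var: float = 0.05  # relative inter-subject template scatter
    stride_var: float = 0.02  # relative stride-to-stride scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.speeds) == 0:
            raise ValueError("speeds list must not be empty")
        if len(self.cadence_spm) != len(self.speeds):
            raise ValueError("cadence_spm must match speeds")
        if self.strides_per_speed < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")


@dataclass
class GaitTrial:
    """One subject-speed recording: five IMU streams, force, ground truth."""

    subject: int
    speed: float
    streams: dict[str, ImuStream]
    force: ForceSeries
    truth: GroundTruth


@dataclass
class _SubjectParams:
    mounts: dict[str, Rotation]
    mount_pos: dict[str, np.ndarray]
    lengths: dict[str, float]
    joint_amp: dict[str, float]
    cadence_factor: float
    peak_factor: np.ndarray  # per LP/MP/TP
    bias: dict[str, np.ndarray]


def _draw_subject(rng: np.random.Generator, cfg: GaitSimConfig) -> _SubjectParams:
    mounts = {}
    bias = {}
    for s in SENSORS:
        rotvec = rng.uniform(-1.0, 1.0, size=3)
        rotvec *= np.radians(15.0) * rng.uniform(0, 1) / np.linalg.norm(rotvec)
        mounts[s] = Rotation.from_rotvec(rotvec)
        d = rng.normal(size=3)
        bias[s] = cfg.gyro_bias * d / np.linalg.norm(d)
    mount_pos = {
        "pelvis": np.array([-0.10, 0.08, 0.05]),
        "thigh": np.array([0.04, 0.02, -0.22]),
        "shank": np.array([0.03, 0.01, -0.20]),
        "foot": np.array([0.08, 0.00, -0.05]),
    }
    lengths = {
        "thigh": 0.42 * (1 + cfg.subject_var * rng.standard_normal()),
        "shank": 0.43 * (1 + cfg.subject_var * rng.standard_normal()),
    }
    joint_amp = {
        j: 1.0 + cfg.subject_var * rng.standard_normal() for j in (*JOINTS, "pelvis")
    }
    return _SubjectParams(
        mounts=mounts,
        mount_pos=mount_pos,
        lengths=lengths,
        joint_amp=joint_amp,
        cadence_factor=1.0 + 0.03 * rng.standard_normal(),
        peak_factor=1.0 + 0.03 * rng.standard_normal(3),
        bias=bias,
    )


def subject_joint_geometry(params: _SubjectParams) -> dict[str, JointGeometry]:
    """Exact hinge geometry of each joint's sensor pair for one subject."""
    ey = np.array([0.0, 1.0, 0.0])
    geoms = {}
    seg_distal = {"thigh": np.array([0.0, 0.0, -1.0]), "shank": np.array([0.0, 0.0, -1.0])}
    for joint, (prox, dist) in JOINT_SENSORS.items():
        m_p, m_d = params.mounts[prox], params.mounts[dist]
        if joint == "hip":
            o_p = m_p.inv().apply(params.mount_pos["pelvis"])
            o_d = m_d.inv().apply(params.mount_pos["thigh"])
        elif joint == "knee":
            knee_in_thigh = seg_distal["thigh"] * params.lengths["thigh"]
            o_p = m_p.inv().apply(params.mount_pos["thigh"] - knee_in_thigh)
            o_d = m_d.inv().apply(params.mount_pos["shank"])
        else:  # ankle
            ankle_in_shank = seg_distal["shank"] * params.lengths["shank"]
            o_p = m_p.inv().apply(params.mount_pos["shank"] - ankle_in_shank)
            o_d = m_d.inv().apply(params.mount_pos["foot"])
        geoms[joint] = JointGeometry(
            j1=m_p.inv().apply(ey),
            j2=m_d.inv().apply(ey),
            o1=o_p,
            o2=o_d,
            axis_residual_rms=0.0,
            center_residual_rms=0.0,
        )
    return geoms


def _simulate_trial(
    cfg: GaitSimConfig,
    subject: int,
    params: _SubjectParams,
    speed: float,
    cadence_spm: float,
    rng: np.random.Generator,
    speed_amp: float,
) -> GaitTrial:
    splines = {k: _periodic_spline(v) for k, v in cfg.kinematic_templates.items()}
    base_peaks = cfg.peak_template[speed]

    # --- stride schedule -------------------------------------------------
    # Two warm-up and two cool-down strides pad the record so edge-guarded
    # contact detection still yields the configured stride count.
    k = cfg.strides_per_speed + 4
    mean_period = 60.0 / (cadence_spm * params.cadence_factor)
    periods = mean_period * (1.0 + cfg.stride_var * rng.standard_normal(k + 2))
    lead = 0.6
    knot_times = lead + np.concatenate([[-periods[0]], np.cumsum(periods)])
    knot_phase = np.arange(-1, k + 2, dtype=float)
    contacts = knot_times[1 : k + 2]  # contact 0..k (k strides between them)
    duration = contacts[-1] + 0.4

    def phase(tv: np.ndarray) -> np.ndarray:
        return np.interp(tv, knot_times, knot_phase)

    # --- per-stride peak sets -------------------------------------------
    peak_sets = []
    all_factors = {}
    for s_idx in range(-1, k + 1):
        f = params.peak_factor * (1.0 + cfg.stride_var * rng.standard_normal(3))
        all_factors[s_idx] = f
        if 0 <= s_idx < k:
            peak_sets.append(
                PeakSet(
                    lp=base_peaks.lp * f[0],
                    mp=min(base_peaks.mp * f[1], base_peaks.lp * f[0], base_peaks.tp * f[2]),
                    tp=base_peaks.tp * f[2],
                    t_lp=base_peaks.t_lp,
                    t_mp=base_peaks.t_mp,
                    t_tp=base_peaks.t_tp,
                )
            )

    # --- force channel ---------------------------------------------------
    n_grf = int(round(duration * cfg.grf_rate))
    t_grf = np.arange(n_grf) / cfg.grf_rate
    ph_grf = phase(t_grf)
    stride_idx = np.floor(ph_grf).astype(int)
    cyc = (ph_grf - stride_idx) * 100.0
    vgrf = np.zeros(n_grf)
    for s_idx in np.unique(stride_idx):
        f = all_factors.get(int(s_idx), params.peak_factor)
        pk = PeakSet(
            lp=base_peaks.lp * f[0],
            mp=min(base_peaks.mp * f[1], base_peaks.lp * f[0], base_peaks.tp * f[2]),
            tp=base_peaks.tp * f[2],
            t_lp=base_peaks.t_lp,
            t_mp=base_peaks.t_mp,
            t_tp=base_peaks.t_tp,
        )
        mask = stride_idx == s_idx
        vgrf[mask] = vgrf_template(cyc[mask], pk, cfg.stance_end)
    vgrf_clean = vgrf.copy()
    if cfg.grf_noise_rel > 0:
        vgrf = vgrf * (1.0 + cfg.grf_noise_rel * rng.standard_normal(n_grf))
        vgrf = np.maximum(vgrf, 0.0)
    force = ForceSeries(time=t_grf, vgrf=vgrf)

    # --- kinematic chain -------------------------------------------------
    n_imu = int(round(duration * cfg.imu_rate))
    t_imu = np.arange(n_imu) / cfg.imu_rate
    ph = phase(t_imu)
    cyc_frac = ph - np.floor(ph)
    phase_rate = np.gradient(ph, t_imu)  # strides/s, piecewise ~constant

    ang = {
        j: params.joint_amp[j] * speed_amp * splines[j](cyc_frac) for j in JOINTS
    }
    ang["pelvis"] = params.joint_amp["pelvis"] * splines["pelvis"](cyc_frac)
    dang = {
        j: params.joint_amp[j] * speed_amp * splines[j](cyc_frac, 1) * phase_rate
        for j in JOINTS
    }
    dang["pelvis"] = params.joint_amp["pelvis"] * splines["pelvis"](cyc_frac, 1) * phase_rate

    # Segment angles chained so that each joint's proximal-minus-distal
    # rate difference integrates to its template (the convention the
    # gyro/accel angle chain measures).
    theta = {"pelvis": np.radians(ang["pelvis"])}
    theta["thigh"] = theta["pelvis"] - np.radians(ang["hip"])
    theta["shank"] = theta["thigh"] - np.radians(ang["knee"])
    theta["foot"] = theta["shank"] - np.radians(ang["ankle"])
    dtheta = {"pelvis": np.radians(dang["pelvis"])}
    dtheta["thigh"] = dtheta["pelvis"] - np.radians(dang["hip"])
    dtheta["shank"] = dtheta["thigh"] - np.radians(dang["knee"])
    dtheta["foot"] = dtheta["shank"] - np.radians(dang["ankle"])

    stride_freq = 1.0 / mean_period
    # Pelvis translation: AP bump peaking at each right contact plus a
    # double vertical oscillation per stride.
    amp_ap = cfg.ap_accel_amplitude / (2 * np.pi * stride_freq) ** 2
    amp_v = 0.5 * cfg.vertical_accel_amplitude / (4 * np.pi * stride_freq) ** 2
    x_hip = -amp_ap * np.cos(2 * np.pi * ph)
    z_hip = 0.95 - amp_v * np.cos(4 * np.pi * ph)
    p_hip = np.stack([x_hip, np.zeros(n_imu), z_hip], axis=1)

    def rot_y(th: np.ndarray) -> Rotation:
        return Rotation.from_rotvec(np.outer(th, [0.0, 1.0, 0.0]))

    seg_rot = {s: rot_y(theta[s]) for s in ("pelvis", "thigh", "shank", "foot")}
    p_knee = p_hip + seg_rot["thigh"].apply([0.0, 0.0, -params.lengths["thigh"]])
    p_ankle = p_knee + seg_rot["shank"].apply([0.0, 0.0, -params.lengths["shank"]])
    joint_origin = {"pelvis": p_hip, "thigh": p_hip, "shank": p_knee, "foot": p_ankle}

    # C7 trunk point: larger vertical oscillation, slight AP sway and tilt.
    amp_c7 = cfg.vertical_accel_amplitude / (4 * np.pi * stride_freq) ** 2
    p_c7 = np.stack(
        [
            x_hip + 0.02 * np.sin(2 * np.pi * ph),
            np.zeros(n_imu),
            z_hip + 0.55 - amp_c7 * np.cos(4 * np.pi * ph),
        ],
        axis=1,
    )
    theta_c7 = np.radians(2.0) * np.sin(2 * np.pi * ph)
    seg_rot["c7"] = rot_y(theta_c7)
    dtheta["c7"] = np.radians(2.0) * 2 * np.pi * phase_rate * np.cos(2 * np.pi * ph)

    dt = 1.0 / cfg.imu_rate
    streams: dict[str, ImuStream] = {}
    segment_of = {"pelvis": "pelvis", "thigh": "thigh", "shank": "shank", "foot": "foot", "c7": "c7"}
    ey = np.array([0.0, 1.0, 0.0])
    a_vert_truth = None
    for sensor in SENSORS:
        seg = segment_of[sensor]
        mount = params.mounts[sensor]
        rot = seg_rot[seg] * mount
        if sensor == "c7":
            pos = p_c7
        else:
            pos = joint_origin[seg] + seg_rot[seg].apply(params.mount_pos[sensor])
        acc_global = CubicSpline(t_imu, pos).derivative(2)(t_imu)
        if sensor == "c7":
            a_vert_truth = acc_global[:, 2].copy()
        gyro = dtheta[seg][:, None] * mount.inv().apply(ey)[None, :]
        accel = rot.inv().apply(acc_global - GRAVITY)
        gyro = gyro + params.bias[sensor]
        if cfg.gyro_noise_sd > 0:
            gyro = gyro + rng.normal(scale=cfg.gyro_noise_sd, size=gyro.shape)
        if cfg.accel_noise_sd > 0:
            accel = accel + rng.normal(scale=cfg.accel_noise_sd, size=accel.shape)
        streams[sensor] = ImuStream(
            t_imu,
            gyro,
            accel,
            orientation=_quat_scalar_first(rot),
            name=sensor,
        )

    truth = GroundTruth(
        geometry=subject_joint_geometry(params),
        angle_deg={j: ang[j] for j in JOINTS},
        angular_velocity_dps={j: dang[j] for j in JOINTS},
        contact_times=contacts[:-1].copy(),
        toeoff_times=(contacts[:-1] + periods[1 : k + 1] * cfg.stance_end / 100.0),
        peak_sets=peak_sets,
        vgrf=vgrf_clean,
        vgrf_time=t_grf,
        a_vert=a_vert_truth,
        stance_fraction=cfg.stance_end / 100.0,
    )
    return GaitTrial(subject=subject, speed=speed, streams=streams, force=force, truth=truth)


def simulate_gait(config: GaitSimConfig) -> list[GaitTrial]:
    """Simulate the full study: one trial per subject per speed.

    Speed modulates both cadence and the kinematic/force templates
    (faster walking: larger joint excursions, deeper mid-stance valley).
    Subjects differ in segment lengths, template amplitudes, cadence,
    sensor mounting pose and gyro bias, all drawn from the seeded
    generator.
    """
    cfg = config
    trials: list[GaitTrial] = []
    speed_amps = np.linspace(0.85, 1.15, len(cfg.speeds))
    for subject in range(cfg.n_subjects):
        s_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject]))
        params = _draw_subject(s_rng, cfg)
        for speed, cadence, amp in zip(cfg.speeds, cfg.cadence_spm, speed_amps):
            trials.append(
                _simulate_trial(cfg, subject, params, speed, cadence, s_rng, amp)
            )
    return trials
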