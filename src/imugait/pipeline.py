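"""End-to-end synthetic gait study: simulate, calibrate, fuse, train, evaluate.

``run_study`` reproduces the full processing chain on simulated data:

1. simulate a multi-subject, multi-speed treadmill study (five IMUs at
   60 Hz + force plate at 100 Hz);
2. per subject and joint, identify the hinge geometry from dedicated
   calibration recordings (walking-like motion for the axes, circling
   motion for the centers);
3. estimate hip/knee/ankle flexion/extension angles by gyro-accel
   fusion, their 6 Hz-filtered angular velocities, and the gravity-free
   C7 vertical acceleration;
4. detect foot contacts in both modalities (2 Hz-filtered hip AP
   acceleration; vGRF onsets), segment strides, normalize to the
   0-100% cycle grid and synchronize kinematics with force labels;
5. split by the intra/inter-participant protocol, min-max scale on the
   training partition, train the RF and FNN regressors under both
   feature sets, and evaluate RMSE/NRMSE/correlation/peak metrics plus
   permutation feature importance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as cal
from . import gait_events as ev
from . import grf_models as gm
from . import kinematics as kin
from .evaluation import evaluate_predictions
from .fnn import FNNConfig
from .simulate import (
    JOINT_SENSORS,
    JOINTS,
    GaitSimConfig,
    GaitTrial,
    HingeSimConfig,
    simulate_gait,
    simulate_hinge,
)
from .streams import GRAVITY, ImuStream

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "calibrate_subject", "trial_to_cycles"]


@dataclass
class StudyConfig:
    """Configuration of the synthetic end-to-end study."""

    gait: GaitSimConfig = field(default_factory=GaitSimConfig)
    inter_subjects: tuple[int, ...] = (10, 11)
    calibrate: bool = True
    calib_duration: float = 30.0
    rf: gm.RFConfig = field(default_factory=gm.RFConfig)
    fnn: FNNConfig = field(default_factory=FNNConfig)
    feature_specs: tuple[str, ...] = ("Kinematics", "C7")
    models: tuple[str, ...] = ("rf", "fnn")
    include_noise_feature: bool = False
    importance_repeats: int = 5
    importance_max_rows: int = 5000
    seed: int = 0


def calibrate_subject(
    geometry_truth: dict[str, cal.JointGeometry],
    duration: float = 30.0,
    rate: float = 60.0,
    noise: tuple[float, float, float] = (0.01, 0.1, 0.005),
    seed: int = 0,
) -> dict[str, cal.JointGeometry]:
    """Identify each joint's geometry from synthetic calibration records.

    For every joint, a walking-like hinge recording provides the axis
    fit and a circling recording (larger base rotation and translation,
    slower sinusoidal hinge motion) provides the center fit, mirroring
    the usual calibration protocol.
    """
    gyro_sd, accel_sd, bias = noise
    out: dict[str, cal.JointGeometry] = {}
    for k, (joint, g_true) in enumerate(geometry_truth.items()):
        walk_cfg = HingeSimConfig(
            duration=duration,
            rate=rate,
            true_axis_1=g_true.j1,
            true_axis_2=g_true.j2,
            true_center_1=g_true.o1,
            true_center_2=g_true.o2,
            angle_waveform="gait_like",
            amplitude_deg=45.0,
            frequency_hz=0.9,
            base_motion_amplitude=0.05,
            gyro_noise_sd=gyro_sd,
            accel_noise_sd=accel_sd,
            gyro_bias=bias,
            seed=seed * 7 + 2 * k,
        )
        circle_cfg = HingeSimConfig(
            duration=duration,
            rate=rate,
            true_axis_1=g_true.j1,
            true_axis_2=g_true.j2,
            true_center_1=g_true.o1,
            true_center_2=g_true.o2,
            angle_waveform="sinusoid",
            amplitude_deg=40.0,
            frequency_hz=0.5,
            base_motion_amplitude=0.10,
            base_rotation_amplitude=0.6,
            gyro_noise_sd=gyro_sd,
            accel_noise_sd=accel_sd,
            gyro_bias=bias,
            seed=seed * 7 + 2 * k + 1,
        )
        w1, w2, _ = simulate_hinge(walk_cfg)
        c1, c2, _ = simulate_hinge(circle_cfg)
        j1, j2, axis_rms, _ = cal.estimate_joint_axes(w1, w2)
        o1, o2, center_rms = cal.estimate_joint_centers(c1, c2, j1, j2)
        out[joint] = cal.JointGeometry(
            j1=j1, j2=j2, o1=o1, o2=o2,
            axis_residual_rms=axis_rms, center_residual_rms=center_rms,
        )
    return out


def _global_accel(stream: ImuStream) -> np.ndarray:
    """Rotate specific force to the global frame and remove gravity."""
    from scipy.spatial.transform import Rotation

    quat_xyzw = np.roll(stream.orientation, -1, axis=1)
    return Rotation.from_quat(quat_xyzw).apply(stream.accel) + GRAVITY


def trial_to_cycles(
    trial: GaitTrial,
    geometry: dict[str, cal.JointGeometry],
    fusion: kin.FusionConfig | None = None,
) -> pd.DataFrame:
    """Process one recording into synchronized cycle-domain rows.

    Runs the angle chain for the three joints with the given (estimated
    or true) geometry, derives angular velocities and the C7 vertical
    acceleration, detects contacts in both modalities, segments and
    normalizes every signal to the cycle grid, and joins kinematics
    with vGRF labels.
    """
    fusion = fusion or kin.FusionConfig()
    streams = trial.streams
    rate = streams["pelvis"].rate
    signals: dict[str, np.ndarray] = {}
    for joint in JOINTS:
        prox, dist = JOINT_SENSORS[joint]
        g = geometry[joint]
        s1, s2 = streams[prox], streams[dist]
        ag = kin.gyro_angle(s1, s2, g.j1, g.j2)
        aa = kin.accel_angle(
            kin.shift_accelerations(s1, g.o1),
            kin.shift_accelerations(s2, g.o2),
            g.j1,
            g.j2,
            fusion.plane_reference,
        )
        alpha = kin.fuse_angles(aa, ag, fusion)
        signals[f"{joint}_angle"] = alpha
        signals[f"{joint}_angvel"] = kin.angular_velocity(alpha, rate)
    signals["a_vert"] = kin.vertical_acceleration(streams["c7"]).a_vert

    ap_accel = _global_accel(streams["pelvis"])[:, 0]
    imu_contacts = ev.detect_contacts_imu(
        ap_accel, rate, time=streams["pelvis"].time, edge_guard_s=2.5
    )
    grf_contacts = ev.detect_contacts_grf(trial.force)
    t_i, t_g = ev.match_contacts(imu_contacts, grf_contacts)

    t_imu = streams["pelvis"].time
    imu_curves: dict[str, np.ndarray] = {}
    for name, sig in signals.items():
        curves, _ = ev.segment_and_normalize(t_imu, sig, t_i)
        imu_curves[name] = curves
    grf_curves, _ = ev.segment_and_normalize(trial.force.time, trial.force.vgrf, t_g)
    return ev.synchronize(
        imu_curves, grf_curves, subject=trial.subject, speed=trial.speed
    )


def build_study_dataset(config: StudyConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the study and assemble the full cycle dataset."""
    trials = simulate_gait(config.gait)
    geometries: dict[int, dict[str, cal.JointGeometry]] = {}
    frames = []
    cal_report: dict[int, dict] = {}
    for trial in trials:
        if trial.subject not in geometries:
            if config.calibrate:
                geometries[trial.subject] = calibrate_subject(
                    trial.truth.geometry,
                    duration=config.calib_duration,
                    noise=(
                        config.gait.gyro_noise_sd,
                        config.gait.accel_noise_sd,
                        config.gait.gyro_bias,
                    ),
                    seed=config.seed * 1009 + trial.subject,
                )
            else:
                geometries[trial.subject] = trial.truth.geometry
            cal_report[trial.subject] = {
                j: g.to_dict() for j, g in geometries[trial.subject].items()
            }
        frames.append(trial_to_cycles(trial, geometries[trial.subject]))
    dataset = pd.concat(frames, ignore_index=True)
    # Reference-posture normalization: the accelerometer angle's additive
    # constant depends on the arbitrary joint-plane reference and on the
    # mounting pose, so each subject's angles are centered on their own
    # session mean (angular velocities are offset-free already).
    for col in ("hip_angle", "knee_angle", "ankle_angle"):
        dataset[col] = dataset[col] - dataset.groupby("subject")[col].transform("mean")
    if config.include_noise_feature:
        rng = np.random.default_rng(config.seed + 77)
        dataset["noise"] = rng.standard_normal(len(dataset))
    info = {"n_trials": len(trials), "calibration": cal_report}
    return dataset, info


def _spec_by_name(name: str, include_noise: bool) -> gm.FeatureSpec:
    base = {"Kinematics": gm.KINEMATICS_SPEC, "C7": gm.C7_SPEC}[name]
    if include_noise:
        return gm.FeatureSpec(base.name + "+noise", (*base.columns, "noise"))
    return base


def run_study(config: StudyConfig, dataset: pd.DataFrame | None = None) -> dict:
    """Run the complete synthetic study; returns a nested results dict.

    ``results["models"][<spec>][<model>]`` holds per-partition
    evaluation reports (validation = intra-participant, test =
    inter-participant) and the permutation feature importance computed
    on the validation rows. A prebuilt cycle dataset may be passed to
    skip the simulation/calibration stages.
    """
    if dataset is None:
        dataset, info = build_study_dataset(config)
    else:
        info = {"n_trials": None, "calibration": "external dataset"}
    plan = gm.SplitPlan(inter_subjects=config.inter_subjects)
    train, val, test = gm.split_data(dataset, plan, seed=config.seed)
    results: dict = {
        "config": {"seed": config.seed, "inter_subjects": list(config.inter_subjects)},
        "dataset": {
            "rows": int(len(dataset)),
            "subjects": sorted(int(s) for s in dataset["subject"].unique()),
            "speeds": sorted(float(s) for s in dataset["speed"].unique()),
            "partition_rows": {
                "train": int(len(train)),
                "validation": int(len(val)),
                "test": int(len(test)),
            },
        },
        "info": info,
        "models": {},
    }
    for spec_name in config.feature_specs:
        spec = _spec_by_name(spec_name, config.include_noise_feature)
        x_train, y_train, _ = gm.build_feature_table(train, spec)
        x_val, y_val, _ = gm.build_feature_table(val, spec)
        x_test, y_test, _ = gm.build_feature_table(test, spec)
        scaler = gm.fit_scaler(x_train, columns=spec.columns)
        xs_train = scaler.transform(x_train)
        xs_val = scaler.transform(x_val)
        xs_test = scaler.transform(x_test)
        results["models"][spec.name] = {}
        for model_name in config.models:
            if model_name == "rf":
                rf_cfg = gm.RFConfig(**{**vars(config.rf), "seed": config.seed})
                model = gm.train_rf(xs_train, y_train, rf_cfg)
            elif model_name == "fnn":
                fnn_cfg = FNNConfig(**{**vars(config.fnn), "seed": config.seed})
                model = gm.train_fnn(xs_train, y_train, fnn_cfg, x_val=xs_val, y_val=y_val)
            else:
                raise ValueError(f"unknown model {model_name!r}")
            entry: dict = {"train_rmse": float(np.sqrt(np.mean(
                (gm.predict_vgrf(model, xs_train) - y_train) ** 2)))}
            for part, (frame, xs, y) in {
                "validation": (val, xs_val, y_val),
                "test": (test, xs_test, y_test),
            }.items():
                pred_frame = frame.copy()
                pred_frame["vgrf_pred"] = gm.predict_vgrf(model, xs)
                entry[part] = evaluate_predictions(pred_frame)
            rng = np.random.default_rng(config.seed + 13)
            if len(xs_val) > config.importance_max_rows:
                idx = rng.choice(len(xs_val), config.importance_max_rows, replace=False)
                xs_imp, y_imp = xs_val[idx], y_val[idx]
            else:
                xs_imp, y_imp = xs_val, y_val
            importance = gm.permutation_importance(
                model,
                xs_imp,
                y_imp,
                repeats=config.importance_repeats,
                seed=config.seed + 29,
                feature_names=spec.columns,
            )
            entry["importance"] = {k: float(v) for k, v in importance.items()}
            results["models"][spec.name][model_name] = entry
            logger.info(
                "%s/%s: train RMSE %.4f BW, val RMSE %.4f BW",
                spec.name,
                model_name,
                entry["train_rmse"],
                entry["validation"]["global"]["rmse_mean"],
            )
    return results
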