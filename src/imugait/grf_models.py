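"""vGRF regression models, data splitting and feature importance.

Two regressors estimate the body-weight-normalized vGRF from cycle-domain
gait features:

* a random forest (scikit-learn): 170 trees, maximum depth 35, minimum
  samples per leaf 1, minimum samples to split 2, and ``log2`` of the
  feature count considered at each split;
* a feedforward network (:mod:`imugait.fnn`): five hidden layers of ten
  rectified-linear units, Adam, RMSE loss, dropout with a max-norm-4
  weight constraint.

Two feature sets are compared: *Kinematics* — the hip/knee/ankle
flexion/extension angles and angular velocities plus the gait-cycle
percent (7 inputs) — and *C7*, which adds the vertical acceleration of
the trunk at the C7 vertebra (8 inputs). Inputs are min-max scaled to
[0, 1] on the training partition only; the training scaler is reused
unchanged (no clipping) for validation and test data.

The split protocol holds complete subjects out for inter-participant
testing and divides the remaining rows 80/20 at random for training and
intra-participant validation. Feature relevance is measured by
permutation importance: the mean increase in prediction RMSE when one
input column is shuffled on evaluation data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .fnn import FeedForwardNet, FNNConfig

__all__ = [
    "FeatureSpec",
    "KINEMATICS_SPEC",
    "C7_SPEC",
    "MinMaxScaler",
    "RFConfig",
    "FNNConfig",
    "SplitPlan",
    "build_feature_table",
    "fit_scaler",
    "apply_scaler",
    "train_rf",
    "train_fnn",
    "predict_vgrf",
    "split_data",
    "permutation_importance",
]

KINEMATIC_COLUMNS = (
    "hip_angle",
    "knee_angle",
    "ankle_angle",
    "hip_angvel",
    "knee_angvel",
    "ankle_angvel",
)
METADATA_COLUMNS = ("subject", "speed", "stride", "cycle_pct")
LABEL_COLUMN = "vgrf"


@dataclass(frozen=True)
class FeatureSpec:
    """Named, ordered input-column selection for a model."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if LABEL_COLUMN in self.columns:
            raise ValueError("label column cannot be a feature")


#: Joint angles, angular velocities and cycle percent (7 inputs).
KINEMATICS_SPEC = FeatureSpec("Kinematics", (*KINEMATIC_COLUMNS, "cycle_pct"))
#: Kinematics plus the C7 vertical acceleration (8 inputs).
C7_SPEC = FeatureSpec("C7", (*KINEMATIC_COLUMNS, "a_vert", "cycle_pct"))


def build_feature_table(
    dataset: pd.DataFrame, spec: FeatureSpec
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Extract ``(X, y, metadata)`` from a cycle dataset.

    Column order is fixed by the spec; ``y`` is the vGRF in BW; the
    metadata frame retains subject, speed, stride and cycle percent.
    """
    missing = [c for c in (*spec.columns, LABEL_COLUMN) if c not in dataset.columns]
    if missing:
        raise KeyError(f"dataset is missing columns {missing}")
    x = dataset.loc[:, list(spec.columns)].to_numpy(dtype=float)
    y = dataset[LABEL_COLUMN].to_numpy(dtype=float)
    meta_cols = [c for c in METADATA_COLUMNS if c in dataset.columns]
    return x, y, dataset.loc[:, meta_cols].reset_index(drop=True)


@dataclass
class MinMaxScaler:
    """Per-feature min-max scaling fitted on training data only.

    ``transform`` maps training columns into [0, 1]; data outside the
    training range scales beyond [0, 1] and is deliberately not clipped.
    """

    mins: np.ndarray
    maxs: np.ndarray
    columns: tuple[str, ...] | None = None

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.mins) / (self.maxs - self.mins)

    def inverse_transform(self, x_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(x_scaled, dtype=float) * (self.maxs - self.mins) + self.mins

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "columns": list(self.columns) if self.columns else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        return cls(
            mins=np.array(d["mins"]),
            maxs=np.array(d["maxs"]),
            columns=tuple(d["columns"]) if d.get("columns") else None,
        )


def fit_scaler(
    x_train: np.ndarray, columns: tuple[str, ...] | None = None
) -> MinMaxScaler:
    """Fit a min-max scaler; a constant column is an error naming it."""
    x_train = np.asarray(x_train, dtype=float)
    mins = x_train.min(axis=0)
    maxs = x_train.max(axis=0)
    degenerate = np.flatnonzero(maxs <= mins)
    if degenerate.size:
        names = (
            [columns[i] for i in degenerate]
            if columns is not None
            else degenerate.tolist()
        )
        raise ValueError(f"constant feature column(s) cannot be scaled: {names}")
    return MinMaxScaler(mins=mins, maxs=maxs, columns=columns)


def apply_scaler(scaler: MinMaxScaler, x: np.ndarray) -> np.ndarray:
    """Transform with a fitted scaler (training min/max, no clipping)."""
    return scaler.transform(x)


@dataclass
class RFConfig:
    """Random-forest hyperparameters (field-standard gait settings)."""

    n_trees: int = 170
    max_depth: int = 35
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    max_features: str | int = "log2"  # floor(log2(n_features)) per split
    bootstrap: bool = True
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.min_samples_leaf, self.min_samples_split) < 1:
            raise ValueError("RF config values must be positive integers")


@dataclass
class SplitPlan:
    """Subject-level held-out test plus a random 80/20 row split."""

    inter_subjects: tuple[int, ...]
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("training data contains NaN or inf")
    return x, y


def train_rf(x: np.ndarray, y: np.ndarray, config: RFConfig | None = None):
    """Fit the random-forest vGRF regressor on scaled features."""
    config = config or RFConfig()
    x, y = _check_xy(x, y)
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        min_samples_split=config.min_samples_split,
        max_features=config.max_features,
        bootstrap=config.bootstrap,
        random_state=config.seed,
        n_jobs=config.n_jobs,
    )
    model.fit(x, y)
    return model


def train_fnn(
    x: np.ndarray,
    y: np.ndarray,
    config: FNNConfig | None = None,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> FeedForwardNet:
    """Fit the feedforward vGRF regressor on scaled features."""
    x, y = _check_xy(x, y)
    net = FeedForwardNet(x.shape[1], config or FNNConfig())
    net.fit(x, y, x_val=x_val, y_val=y_val)
    return net


def predict_vgrf(model, x: np.ndarray) -> np.ndarray:
    """Predictions in BW, one per row, reported as-is (no clipping)."""
    x = np.asarray(x, dtype=float)
    n_expected = getattr(model, "n_features_in_", getattr(model, "n_features", None))
    if n_expected is not None and x.shape[1] != n_expected:
        raise ValueError(
            f"feature count mismatch: model expects {n_expected}, got {x.shape[1]}"
        )
    yhat = np.asarray(model.predict(x), dtype=float)
    if not np.all(np.isfinite(yhat)):
        raise RuntimeError("model produced non-finite predictions")
    return yhat


def split_data(
    dataset: pd.DataFrame, plan: SplitPlan, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split rows into (train, validation, test) per the study protocol.

    Rows of the held-out subjects form the inter-participant test set;
    the remaining (intra-participant) rows are split at random,
    ``train_fraction`` for training and the rest for validation.
    """
    subjects = set(dataset["subject"].unique())
    inter = set(plan.inter_subjects)
    if not inter.issubset(subjects):
        raise ValueError(f"held-out subjects {inter - subjects} absent from dataset")
    if len(subjects - inter) < 1:
        raise ValueError("no intra-participant subjects left to train on")
    test = dataset[dataset["subject"].isin(inter)]
    intra = dataset[~dataset["subject"].isin(inter)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(intra))
    n_train = int(round(plan.train_fraction * len(intra)))
    train = intra.iloc[order[:n_train]]
    val = intra.iloc[order[n_train:]]
    return train, val, test


def permutation_importance(
    model,
    x_val: np.ndarray,
    y_val: np.ndarray,
    repeats: int = 5,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> pd.Series:
    """Per-feature increase in RMSE when that column is shuffled.

    For each feature in order, draws ``repeats`` random permutations
    from one seeded generator, re-predicts with the single column
    shuffled, and averages ``RMSE(shuffled) - RMSE(baseline)``. Larger
    values mean the model relies more on that feature.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    x_val = np.asarray(x_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    rng = np.random.default_rng(seed)
    baseline = float(np.sqrt(np.mean((predict_vgrf(model, x_val) - y_val) ** 2)))
    increases = np.zeros(x_val.shape[1])
    for j in range(x_val.shape[1]):
        deltas = []
        for _ in range(repeats):
            perm = rng.permutation(x_val.shape[0])
            x_shuf = x_val.copy()
            x_shuf[:, j] = x_val[perm, j]
            shuffled = float(np.sqrt(np.mean((predict_vgrf(model, x_shuf) - y_val) ** 2)))
            deltas.append(shuffled - baseline)
        increases[j] = np.mean(deltas)
    index = (
        list(feature_names)
        if feature_names is not None
        else [f"feature_{j}" for j in range(x_val.shape[1])]
    )
    return pd.Series(increases, index=index, name="rmse_increase_bw")
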