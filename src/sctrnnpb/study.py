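"""The standard desk-scale synthetic study.

One place defines the study conditions that the test suite and the
reproduction script both run: 6 emotions x 5 synthetic sequences per
emotion, emotion-balanced 5-fold split with one fold held out (24 training
/ 6 test sequences), networks with 50 lower-level neurons and a 2-D PB,
and the standard training settings.  The heterogeneous condition uses
K = 1000 (typical-development model), the homogeneous condition K = 0.001
(ASD-like model), and the ablation retrains the heterogeneous network with
first-frame normalization disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import generate_dataset, make_folds
from .evaluation import activity_profile, closed_loop_mse_at, silhouette_index
from .network import NetworkConfig, NetworkParams, PaddedBatch, _forward_batch
from .preprocessing import NormalFaceScaler, TargetSequence
from .recognition import RecognitionConfig, infer_pb_batch
from .training import TrainingConfig, _batch_metrics, train

N_PER_EMOTION = 5
LENGTH_RANGE = (10, 40)
NOISE_SD = 0.02
N_FOLDS = 5
TEST_FOLD = 0
N_LOWER = 50
K_HETEROGENEOUS = 1000.0
K_HOMOGENEOUS = 0.001


@dataclass
class StudyRun:
    """Everything measured for one condition/seed of the standard study."""

    K: float
    seed: int
    normalization_enabled: bool
    config: NetworkConfig
    params: NetworkParams
    train_targets: list[TargetSequence]
    test_targets: list[TargetSequence]
    train_labels: np.ndarray
    test_labels: np.ndarray
    pb_internal: np.ndarray       # learned, (n_train, n_pb)
    pb_activity: np.ndarray
    test_pb_internal: np.ndarray  # inferred, (n_test, n_pb)
    test_pb_activity: np.ndarray
    curves: dict[str, list]
    metrics: dict[str, float] = field(default_factory=dict)


def standard_split(seed: int, normalization_enabled: bool = True):
    """Generate the standard dataset and return scaled train/test targets."""
    data = generate_dataset(
        n_per_emotion=N_PER_EMOTION, length_range=LENGTH_RANGE,
        noise_sd=NOISE_SD, seed=seed,
    )
    folds = make_folds(data, N_FOLDS, seed=seed + 100)
    train_raw = [s for s, f in zip(data, folds) if f != TEST_FOLD]
    test_raw = [s for s, f in zip(data, folds) if f == TEST_FOLD]
    scaler = NormalFaceScaler(normalization_enabled=normalization_enabled)
    scaler.fit(train_raw)
    return scaler.transform(train_raw), scaler.transform(test_raw), scaler


def nearest_centroid_accuracy(
    train_pb: np.ndarray, train_labels: np.ndarray,
    test_pb: np.ndarray, test_labels: np.ndarray,
) -> float:
    """Fraction of test PBs whose nearest training-emotion centroid
    (Euclidean, PB-activity space) matches their own emotion."""
    emotions = np.unique(train_labels)
    centroids = np.array([train_pb[train_labels == e].mean(axis=0) for e in emotions])
    assigned = emotions[
        np.argmin(((test_pb[:, None] - centroids[None]) ** 2).sum(axis=2), axis=1)
    ]
    return float(np.mean(assigned == test_labels))


def run_study_condition(
    K: float,
    seed: int,
    normalization_enabled: bool = True,
    n_iterations: int | None = None,
    with_recognition: bool = True,
) -> StudyRun:
    """Train and evaluate one condition of the standard study."""
    train_t, test_t, _ = standard_split(seed, normalization_enabled)
    config = NetworkConfig(
        n_input=train_t[0].n_features, n_lower=N_LOWER, n_pb=2, K=K, seed=seed,
    )
    tkw = {} if n_iterations is None else {"n_iterations": n_iterations}
    tconfig = TrainingConfig(eval_every=500, seed=seed, **tkw)
    result = train(train_t, config, tconfig)

    train_labels = np.array([s.emotion_id for s in train_t])
    test_labels = np.array([s.emotion_id for s in test_t])
    metrics = {
        "initial_train_mse": result.curves["train_mse"][0],
        "train_mse": result.curves["train_mse"][-1],
        "mean_variance": result.curves["mean_v"][-1],
        "silhouette_train": silhouette_index(result.pb_activity, train_labels),
        "fraction_inactive": activity_profile(
            result.params, config, train_t, result.pb_internal
        ).fraction_inactive,
    }

    test_pb_internal = np.zeros((len(test_t), config.n_pb))
    test_pb_activity = np.zeros((len(test_t), config.n_pb))
    if with_recognition:
        rec = infer_pb_batch(
            result.params, config, RecognitionConfig(), test_t, result.pb_internal
        )
        test_pb_internal = np.array([r.pb_internal for r in rec])
        test_pb_activity = np.array([r.pb_activity for r in rec])
        test_batch = PaddedBatch(test_t)
        fwd = _forward_batch(result.params, config, test_batch, test_pb_internal)
        metrics["test_mse"] = _batch_metrics(fwd, test_batch)[0]
        metrics["recognition_accuracy"] = nearest_centroid_accuracy(
            result.pb_activity, train_labels, test_pb_activity, test_labels
        )

    return StudyRun(
        K=K, seed=seed, normalization_enabled=normalization_enabled,
        config=config, params=result.params,
        train_targets=train_t, test_targets=test_t,
        train_labels=train_labels, test_labels=test_labels,
        pb_internal=result.pb_internal, pb_activity=result.pb_activity,
        test_pb_internal=test_pb_internal, test_pb_activity=test_pb_activity,
        curves=result.curves, metrics=metrics,
    )


def snap_to_grid(pb_activity: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Nearest grid coordinate per PB dimension."""
    return np.column_stack(
        [grid[np.argmin(np.abs(grid - pb_activity[:, d][:, None]), axis=1)]
         for d in range(pb_activity.shape[1])]
    )


def self_consistency_fraction(
    run: StudyRun, grid_resolution: int = 41, mse_threshold: float = 0.005,
    pb_limit: float = 0.98,
) -> float:
    """Fraction of training sequences regenerated in closed loop with
    averaged MSE below threshold at the grid point nearest their own PB."""
    grid = np.linspace(-pb_limit, pb_limit, grid_resolution)
    snapped = snap_to_grid(run.pb_activity, grid)
    mse = closed_loop_mse_at(run.params, run.config, run.train_targets, snapped)
    return float(np.mean(np.diag(mse) < mse_threshold))
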