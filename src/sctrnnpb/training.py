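"""Developmental-learning phase.

Jointly optimizes the network weights, the trainable output-head
thresholds, and one PB internal state per training sequence by full-batch
gradient descent on the summed precision-weighted NLL.  Emotion labels are
never read: the PB representation self-organizes purely from the demand of
predicting each sequence.  Lower-level activity thresholds stay at their
initial N(0, K) draw throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    NetworkConfig,
    NetworkParams,
    PaddedBatch,
    compute_gradients,
    init_params,
)
from .preprocessing import TargetSequence


@dataclass
class TrainingConfig:
    n_iterations: int = 15000
    learning_rate: float = 1e-3
    pb_learning_rate: float = 0.1
    optimizer: str = "adam"  # "adam" | "sgd"
    gradient_clip: float | None = 1.0
    input_noise_sd: float = 0.15  # sd of Gaussian noise on fed-in values
    eval_every: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.learning_rate <= 0 or self.pb_learning_rate <= 0:
            raise ValueError("learning rates must be > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainingResult:
    params: NetworkParams
    pb_internal: np.ndarray          # (n_sequences, n_pb)
    curves: dict[str, list] = field(default_factory=dict)

    @property
    def pb_activity(self) -> np.ndarray:
        return np.tanh(self.pb_internal)


class AdamState:
    """Adam moment accumulators for a dict of named arrays."""

    def __init__(self, shapes: dict[str, tuple], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Return update directions (to be scaled by the learning rate)."""
        self.t += 1
        out = {}
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            out[k] = mhat / (np.sqrt(vhat) + self.eps)
        return out


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float | None) -> None:
    if max_norm is None:
        return
    total = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def _batch_metrics(fwd: dict, batch: PaddedBatch) -> tuple[float, float]:
    """(averaged MSE, mean estimated variance): steps -> features -> seqs."""
    err = fwd["Y"] - np.transpose(batch.targets[:, 1:], (1, 0, 2))
    mask = batch.step_mask.T[:, :, None]
    steps = (batch.lengths - 1)[:, None]
    mse = float(np.mean((err**2 * mask).sum(axis=0) / steps))
    mv = float(np.mean((fwd["V"] * mask).sum(axis=0) / steps))
    return mse, mv


def train(
    dataset: list[TargetSequence],
    config: NetworkConfig,
    tconfig: TrainingConfig,
    monitor: list[TargetSequence] | None = None,
    params: NetworkParams | None = None,
) -> TrainingResult:
    """Full-batch gradient descent on the summed NLL.

    When ``input_noise_sd > 0`` the fed-in values are corrupted with fresh
    seeded Gaussian noise each iteration while the loss targets stay clean;
    predicting clean from corrupted input makes the learned dynamics
    contracting around the training trajectories, which is what lets the
    network regenerate them in closed loop.  ``monitor`` sequences, when
    given, are scored teacher-forced with a zero PB at every evaluation
    point (a cheap generalization proxy for learning curves; proper test
    error uses inferred PBs).  Divergence (non-finite loss) raises with the
    iteration index.
    """
    if len(dataset) < 1:
        raise ValueError("need at least one training sequence")
    batch = PaddedBatch(dataset)
    if batch.n_features != config.n_input:
        raise ValueError(
            f"dataset has {batch.n_features} features but config.n_input="
            f"{config.n_input}"
        )
    if params is None:
        params = init_params(config)
    else:
        params = params.copy()
    a_l_frozen = params.a_l.copy()
    pb_u = np.zeros((batch.n_sequences, config.n_pb))

    trainable = params.trainable()
    shapes = {k: v.shape for k, v in trainable.items()}
    shapes["pb"] = pb_u.shape
    opt = AdamState(shapes) if tconfig.optimizer == "adam" else None

    curves = {k: [] for k in ("iteration", "train_nll", "train_mse", "mean_v")}
    if monitor is not None:
        curves["monitor_mse"] = []
        monitor_batch = PaddedBatch(monitor)

    noise_rng = np.random.default_rng(tconfig.seed)
    clean_inputs = batch.targets[:, :-1]
    for it in range(1, tconfig.n_iterations + 1):
        if tconfig.input_noise_sd > 0:
            inputs = clean_inputs + noise_rng.normal(
                0.0, tconfig.input_noise_sd, size=clean_inputs.shape
            )
        else:
            inputs = None
        try:
            grads, pb_grad, total, fwd = compute_gradients(
                params, config, pb_u, batch, inputs=inputs
            )
        except FloatingPointError as exc:
            raise RuntimeError(f"training diverged at iteration {it}") from exc
        grads["pb"] = pb_grad
        clip_global_norm(grads, tconfig.gradient_clip)
        updates = opt.step(grads) if opt is not None else grads
        for k in trainable:
            trainable[k] -= tconfig.learning_rate * updates[k]
        pb_u -= tconfig.pb_learning_rate * updates["pb"]

        if it % tconfig.eval_every == 0 or it == 1 or it == tconfig.n_iterations:
            if inputs is not None:
                # curves report clean teacher-forced metrics, not the
                # noise-corrupted pass used for the weight update
                from .network import _forward_batch

                fwd = _forward_batch(params, config, batch, pb_u)
            mse, mv = _batch_metrics(fwd, batch)
            curves["iteration"].append(it)
            curves["train_nll"].append(total / batch.n_valid_steps / batch.n_features)
            curves["train_mse"].append(mse)
            curves["mean_v"].append(mv)
            if monitor is not None:
                from .network import _forward_batch

                mfwd = _forward_batch(
                    params, config, monitor_batch,
                    np.zeros((monitor_batch.n_sequences, config.n_pb)),
                )
                curves["monitor_mse"].append(_batch_metrics(mfwd, monitor_batch)[0])

    assert np.array_equal(params.a_l, a_l_frozen), "frozen thresholds moved"
    return TrainingResult(params=params, pb_internal=pb_u, curves=curves)
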