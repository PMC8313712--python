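"""Evaluation statistics for the trained networks.

Covers the quantities the study design compares across network conditions:
averaged prediction MSE, mean estimated variance, silhouette clustering of
the self-organized PB space, PB-grid tolerance maps (how many training
sequences each PB activity can regenerate in closed loop), and the
activity-range-vs-threshold profile that separates anatomical from
functional network size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkConfig, NetworkParams, PaddedBatch, _forward_batch
from .preprocessing import TargetSequence


def averaged_mse(
    predictions: list[np.ndarray], targets: list[TargetSequence] | list[np.ndarray]
) -> float:
    """Mean squared error averaged steps -> features -> sequences.

    ``predictions[i]`` holds the predicted means for steps ``2..T`` of
    sequence ``i`` (shape ``(T_i - 1, F)``); targets supply the true values.
    The averaging order is fixed: per-sequence mean over steps, then over
    features, then over sequences.
    """
    if not predictions:
        raise ValueError("empty input")
    per_seq = []
    for pred, tgt in zip(predictions, targets):
        values = tgt.targets if isinstance(tgt, TargetSequence) else np.asarray(tgt)
        if pred.shape[0] != values.shape[0] - 1:
            raise ValueError("prediction/target length mismatch")
        per_seq.append(float(np.mean((pred - values[1:]) ** 2)))
    return float(np.mean(per_seq))


def mean_estimated_variance(
    variances: list[np.ndarray],
) -> float:
    """Estimated variance averaged with the same steps->features->sequences order."""
    if not variances:
        raise ValueError("empty input")
    return float(np.mean([float(np.mean(v)) for v in variances]))


def silhouette_index(pb_points: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width with Euclidean distance.

    For each point, ``a`` is its mean distance to the other members of its
    own cluster and ``b`` the smallest mean distance to any other cluster;
    the width is ``(b - a) / max(a, b)``.  Points in singleton clusters
    contribute 0, as do exactly coincident configurations where
    ``max(a, b) = 0``.
    """
    pts = np.asarray(pb_points, dtype=float)
    labels = np.asarray(labels)
    if pts.ndim != 2 or pts.shape[0] != labels.shape[0]:
        raise ValueError("pb_points must be (n, d) aligned with labels")
    unique = np.unique(labels)
    if unique.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    widths = np.zeros(pts.shape[0])
    for i in range(pts.shape[0]):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own < 2:
            continue  # singleton: width 0 by convention
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == c].mean() for c in unique if c != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(widths.mean())


# ---------------------------------------------------------------------------
# tolerance map: closed-loop regeneration over a PB-activity grid

@dataclass
class ToleranceMap:
    grid: np.ndarray        # (R,) PB-activity coordinates per axis
    counts: np.ndarray      # (R, R) well-predicted training sequences; [i, j] = (pb1=grid[i], pb2=grid[j])
    mse_threshold: float
    n_sequences: int

    def max_count(self) -> int:
        return int(self.counts.max())


def _closed_loop_mse(
    params: NetworkParams,
    config: NetworkConfig,
    batch: PaddedBatch,
    pb_activity: np.ndarray,
) -> np.ndarray:
    """Averaged (steps->features) closed-loop MSE for every (grid point,
    sequence) pair; ``pb_activity`` is (G, n_pb), returns (G, B)."""
    G = pb_activity.shape[0]
    B, T, F = batch.targets.shape
    tau = params.tau
    p = np.clip(pb_activity, -1 + 1e-12, 1 - 1e-12)
    pb_drive = p @ params.w_pl.T + params.a_l  # (G, n_lower)
    u = np.zeros((G, B, config.n_lower))
    l = np.tanh(u)
    x = np.broadcast_to(batch.targets[:, 0], (G, B, F)).copy()
    sq = np.zeros((G, B, F))
    mask = batch.step_mask  # (B, T-1)
    for k in range(T - 1):
        drive = x @ params.w_xl.T + l @ params.w_ll.T + pb_drive[:, None, :]
        u = drive / tau + (1.0 - 1.0 / tau) * u
        l = np.tanh(u)
        y = np.tanh(l @ params.w_ly.T + params.a_y)
        err = y - batch.targets[:, k + 1]
        sq += err**2 * mask[:, k][None, :, None]
        x = y
    return (sq / (batch.lengths - 1)[None, :, None]).mean(axis=2)


def tolerance_map(
    params: NetworkParams,
    config: NetworkConfig,
    training_targets: list[TargetSequence],
    grid_resolution: int = 41,
    mse_threshold: float = 0.005,
    pb_limit: float = 0.98,
) -> ToleranceMap:
    """Count, per PB-activity grid point, the training sequences that the
    frozen network regenerates in closed loop with averaged MSE below the
    threshold.  The grid stays inside ``[-pb_limit, pb_limit]^2`` to avoid
    the atanh singularity at the tanh bounds.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    if config.n_pb != 2:
        raise ValueError("tolerance_map assumes a 2-D PB space")
    batch = PaddedBatch(training_targets)
    grid = np.linspace(-pb_limit, pb_limit, grid_resolution)
    g1, g2 = np.meshgrid(grid, grid, indexing="ij")
    pts = np.column_stack([g1.ravel(), g2.ravel()])
    counts = np.zeros(pts.shape[0], dtype=int)
    chunk = max(1, 4096 // max(1, batch.n_sequences))
    for s in range(0, pts.shape[0], chunk):
        mse = _closed_loop_mse(params, config, batch, pts[s : s + chunk])
        counts[s : s + chunk] = (mse < mse_threshold).sum(axis=1)
    return ToleranceMap(
        grid=grid,
        counts=counts.reshape(grid_resolution, grid_resolution),
        mse_threshold=mse_threshold,
        n_sequences=batch.n_sequences,
    )


def closed_loop_mse_at(
    params: NetworkParams,
    config: NetworkConfig,
    training_targets: list[TargetSequence],
    pb_activity: np.ndarray,
) -> np.ndarray:
    """Closed-loop averaged MSE of every training sequence at given PB
    activities; ``pb_activity`` (G, 2) -> (G, B)."""
    batch = PaddedBatch(training_targets)
    return _closed_loop_mse(params, config, batch, np.asarray(pb_activity, dtype=float))


# ---------------------------------------------------------------------------
# activity profile: functional vs anatomical network size

@dataclass
class ActivityProfile:
    abs_threshold: np.ndarray     # (n_lower,) |a_i|
    activity_range: np.ndarray    # (n_lower,) max - min of tanh activity
    epsilon_active: float = 0.05

    @property
    def fraction_inactive(self) -> float:
        """Share of lower-level neurons whose activity barely moves."""
        return float(np.mean(self.activity_range < self.epsilon_active))


def activity_profile(
    params: NetworkParams,
    config: NetworkConfig,
    training_targets: list[TargetSequence],
    pb_internal: np.ndarray,
    epsilon_active: float = 0.05,
) -> ActivityProfile:
    """Per-neuron activity range over all steps of all training sequences,
    run teacher-forced at each sequence's learned PB state."""
    batch = PaddedBatch(training_targets)
    fwd = _forward_batch(params, config, batch, np.asarray(pb_internal, dtype=float))
    L = fwd["L"]  # (n_steps, B, n_lower)
    mask = batch.step_mask.T[:, :, None]
    lo = np.where(mask, L, np.inf).min(axis=(0, 1))
    hi = np.where(mask, L, -np.inf).max(axis=(0, 1))
    return ActivityProfile(
        abs_threshold=np.abs(params.a_l),
        activity_range=hi - lo,
        epsilon_active=epsilon_active,
    )


def plot_pb_space(
    train_pb: np.ndarray,
    train_labels: np.ndarray,
    test_pb: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    path: str | None = None,
    ax=None,
):
    """Scatter of PB-activity space colored by emotion: outlined markers
    for training sequences, filled for test sequences.  Requires
    matplotlib (optional dependency)."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    for i, emotion in enumerate(np.unique(train_labels)):
        color = cmap(i % 10)
        sel = train_labels == emotion
        ax.scatter(train_pb[sel, 0], train_pb[sel, 1], facecolors="none",
                   edgecolors=[color], label=f"emotion {emotion} (train)")
        if test_pb is not None:
            tsel = test_labels == emotion
            ax.scatter(test_pb[tsel, 0], test_pb[tsel, 1], color=[color],
                       marker="o", label=f"emotion {emotion} (test)")
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("PB 1 activity")
    ax.set_ylabel("PB 2 activity")
    ax.legend(fontsize=6, loc="best")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax


@dataclass
class EvalReport:
    """Summary statistics of one condition/fold/seed unit."""

    train_mse: float
    test_mse: float | None = None
    mean_variance: float | None = None
    silhouette_train: float | None = None
    silhouette_test: float | None = None
    fraction_inactive: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "train_mse": self.train_mse,
            "test_mse": self.test_mse,
            "mean_variance": self.mean_variance,
            "silhouette_train": self.silhouette_train,
            "silhouette_test": self.silhouette_test,
            "fraction_inactive": self.fraction_inactive,
        }
        d.update(self.extra)
        return d
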