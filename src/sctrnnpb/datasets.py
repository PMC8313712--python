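"""Synthetic facial-expression movie sequences.

Generates emotion-labeled multivariate landmark-displacement trajectories
with the statistical structure of neutral-to-peak facial expression movies:
each sequence starts near a neutral configuration and ramps smoothly toward
an emotion-specific peak displacement pattern over 9 feature channels, with
per-sequence amplitude/phase variation, a nonzero per-sequence baseline
offset, and additive observation noise.  Emotion labels are carried as
metadata only and are never consumed by the network model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_FEATURES = 9
N_EMOTIONS = 6

EMOTION_NAMES = {
    1: "Anger",
    2: "Disgust",
    3: "Fear",
    4: "Happiness",
    5: "Sadness",
    6: "Surprise",
}


@dataclass(frozen=True)
class EmotionPrototype:
    """Peak displacement pattern and ramp steepness for one basic emotion."""

    emotion_id: int
    peak_pattern: np.ndarray  # (9,) signed displacement amplitudes
    ramp_shape: float = 5.0   # logistic steepness in normalized time
    ramp_center: float = 0.25  # logistic midpoint in normalized time

    def __post_init__(self) -> None:
        pattern = np.asarray(self.peak_pattern, dtype=float)
        if pattern.shape != (N_FEATURES,):
            raise ValueError(
                f"peak_pattern must have shape ({N_FEATURES},), got {pattern.shape}"
            )
        object.__setattr__(self, "peak_pattern", pattern)


@dataclass
class RawSequence:
    """One unnormalized landmark-displacement trajectory with its label.

    ``values`` is a (length, 9) array; ``emotion_id`` is metadata only.
    """

    sequence_id: int
    emotion_id: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (length, features) array")
        if self.length < 3:
            raise ValueError(f"sequence length must be >= 3, got {self.length}")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def default_prototypes(amplitude: float = 2.0) -> list[EmotionPrototype]:
    """Six pairwise-distinct peak patterns in arbitrary landmark units.

    Patterns are fixed (not random) so the emotion geometry of the synthetic
    task is stable across seeds; signs and magnitudes loosely mimic how the
    nine retained landmarks move differently across the basic emotions
    (e.g. brow lowering in anger vs. brow raise in surprise, lip-corner pull
    in happiness vs. lip-corner depression in sadness).

    The ramp midpoint sits at 25% of the movie with moderate steepness:
    onset-to-peak expression clips are trimmed so that facial motion begins
    essentially at the first frame and the peak is held toward the end,
    rather than the face staying frozen for half the movie.
    """
    base = np.array(
        [
            #  lipX  browM  browI  nose   upLip  upVrm  lipC   loLip  loVrm
            [-0.3, -1.0, -0.9, 0.2, 0.4, 0.3, -0.2, 0.3, 0.2],  # anger
            [-0.2, -0.5, -0.3, 0.8, 0.9, 0.8, -0.1, -0.4, -0.5],  # disgust
            [0.3, 0.7, 0.8, 0.1, -0.3, -0.2, 0.2, 0.8, 0.7],  # fear
            [0.9, 0.2, 0.1, 0.3, -0.2, -0.3, 0.8, -0.2, -0.1],  # happiness
            [-0.4, 0.3, 0.6, -0.1, 0.1, 0.2, -0.7, 0.1, 0.3],  # sadness
            [0.1, 0.9, 1.0, -0.2, -0.6, -0.7, 0.1, -0.9, -1.0],  # surprise
        ]
    )
    return [
        EmotionPrototype(emotion_id=k + 1, peak_pattern=amplitude * base[k])
        for k in range(N_EMOTIONS)
    ]


def _ramp(t_norm: np.ndarray, steepness: float, center: float) -> np.ndarray:
    """Normalized logistic ramp: exactly 0 at t=0 and 1 at t=1."""
    raw = 1.0 / (1.0 + np.exp(-steepness * (t_norm - center)))
    lo = 1.0 / (1.0 + np.exp(steepness * center))
    hi = 1.0 / (1.0 + np.exp(-steepness * (1.0 - center)))
    return (raw - lo) / (hi - lo)


def generate_dataset(
    n_per_emotion: int = 16,
    length_range: tuple[int, int] = (10, 40),
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    prototypes: list[EmotionPrototype] | None = None,
    amplitude_jitter_sd: float = 0.2,
    phase_jitter_sd: float = 0.05,
    baseline_range: float = 1.0,
) -> list[RawSequence]:
    """Generate ``6 * n_per_emotion`` neutral-to-peak expression sequences.

    Each channel follows ``baseline + jitter * peak[j] * ramp(t) + noise``
    where the ramp is a logistic sigmoid in normalized time reaching its
    peak by the final frame.  Amplitude jitter is lognormal with mean 1
    (``amplitude_jitter_sd`` is the log-scale sigma; 0 disables it), phase
    jitter shifts the per-channel ramp midpoint, and the baseline offset is
    drawn uniformly on ``[-baseline_range, baseline_range]`` per sequence
    and channel so that first-frame normalization has an observable effect.

    Identical arguments and seed give bit-identical output.
    """
    if n_per_emotion < 1:
        raise ValueError(f"n_per_emotion must be >= 1, got {n_per_emotion}")
    lo, hi = int(length_range[0]), int(length_range[1])
    if lo < 3 or hi < lo:
        raise ValueError(f"invalid length_range {length_range}: need 3 <= min <= max")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    protos = prototypes if prototypes is not None else default_prototypes()
    rng = np.random.default_rng(seed)

    sequences: list[RawSequence] = []
    seq_id = 1
    for proto in protos:
        for _ in range(n_per_emotion):
            length = int(rng.integers(lo, hi + 1))
            t_norm = np.linspace(0.0, 1.0, length)
            baseline = rng.uniform(-baseline_range, baseline_range, size=N_FEATURES)
            if amplitude_jitter_sd > 0:
                # mean-1 lognormal so E[peak displacement] equals the prototype
                jitter = rng.lognormal(
                    mean=-0.5 * amplitude_jitter_sd**2,
                    sigma=amplitude_jitter_sd,
                )
            else:
                jitter = 1.0
            centers = proto.ramp_center + (
                rng.normal(0.0, phase_jitter_sd, size=N_FEATURES)
                if phase_jitter_sd > 0
                else np.zeros(N_FEATURES)
            )
            values = np.empty((length, N_FEATURES))
            for j in range(N_FEATURES):
                ramp = _ramp(t_norm, proto.ramp_shape, centers[j])
                values[:, j] = baseline[j] + jitter * proto.peak_pattern[j] * ramp
            values += rng.normal(0.0, noise_sd, size=values.shape)
            sequences.append(
                RawSequence(
                    sequence_id=seq_id,
                    emotion_id=proto.emotion_id,
                    values=values,
                )
            )
            seq_id += 1
    return sequences


def make_folds(
    dataset: list[RawSequence], n_folds: int, seed: int = 0
) -> np.ndarray:
    """Assign each sequence to a cross-validation fold, emotion-balanced.

    Returns an integer array of fold indices in ``[0, n_folds)`` aligned with
    ``dataset``.  Every fold receives exactly ``count / n_folds`` sequences
    of each emotion; counts not divisible by ``n_folds`` are an error.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    emotion_ids = np.array([s.emotion_id for s in dataset])
    rng = np.random.default_rng(seed)
    folds = np.empty(len(dataset), dtype=int)
    for emotion in np.unique(emotion_ids):
        idx = np.flatnonzero(emotion_ids == emotion)
        if len(idx) % n_folds != 0:
            raise ValueError(
                f"emotion {emotion} has {len(idx)} sequences, "
                f"not divisible by n_folds={n_folds}"
            )
        perm = rng.permutation(idx)
        per_fold = len(idx) // n_folds
        for f in range(n_folds):
            folds[perm[f * per_fold : (f + 1) * per_fold]] = f
    return folds


# ---------------------------------------------------------------------------
# long-form delimited IO

_COLUMNS = ["sequence_id", "emotion", "t", "feature_index", "value"]


def to_frame(dataset: list[RawSequence]) -> pd.DataFrame:
    """Long-form table: one row per (sequence, time step, feature)."""
    records = []
    for seq in dataset:
        t_idx, f_idx = np.meshgrid(
            np.arange(1, seq.length + 1),
            np.arange(1, seq.n_features + 1),
            indexing="ij",
        )
        records.append(
            pd.DataFrame(
                {
                    "sequence_id": seq.sequence_id,
                    "emotion": seq.emotion_id,
                    "t": t_idx.ravel(),
                    "feature_index": f_idx.ravel(),
                    "value": seq.values.ravel(),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def write_csv(dataset: list[RawSequence], path: str | Path) -> None:
    to_frame(dataset).to_csv(path, index=False)


def from_frame(frame: pd.DataFrame) -> list[RawSequence]:
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    sequences = []
    for seq_id, group in frame.groupby("sequence_id", sort=True):
        pivot = group.pivot(index="t", columns="feature_index", values="value")
        pivot = pivot.sort_index().sort_index(axis=1)
        sequences.append(
            RawSequence(
                sequence_id=int(seq_id),
                emotion_id=int(group["emotion"].iloc[0]),
                values=pivot.to_numpy(),
            )
        )
    return sequences


def read_csv(path: str | Path) -> list[RawSequence]:
    """Read either one long-form file or a directory of per-sequence files."""
    path = Path(path)
    if path.is_dir():
        frames = [pd.read_csv(p) for p in sorted(path.glob("*.csv"))]
        if not frames:
            raise FileNotFoundError(f"no .csv files under {path}")
        return from_frame(pd.concat(frames, ignore_index=True))
    return from_frame(pd.read_csv(path))
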