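"""Target-sequence preprocessing.

Two steps turn raw landmark-displacement trajectories into the "target
sequences" the network predicts:

1. *Mapping to normal face*: subtract each sequence's first frame so every
   feature starts at exactly zero, unifying the neutral starting
   configuration across subjects.
2. *Min-max scaling*: per feature, over all sequences and steps, map the
   global minimum to -0.9 and the global maximum to +0.9, matching the
   linear range of the tanh output units.

Both are implemented by :class:`NormalFaceScaler`, a scikit-learn style
transformer over lists of variable-length ``(T, F)`` arrays.  Feature
reduction (dropping near-immobile and strongly correlated channels) is
provided by :class:`FeatureReducer`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import RawSequence


@dataclass
class TargetSequence:
    """A normalized trajectory ready for network training.

    ``targets`` lie in [-0.9, 0.9] when scaling statistics were fit on a
    dataset containing this sequence; under train-fold statistics a test
    sequence may escape the band slightly (left unclipped on purpose: the
    prediction-error signal must not be distorted).
    """

    sequence_id: int
    emotion_id: int
    targets: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.targets.shape[0]

    @property
    def n_features(self) -> int:
        return self.targets.shape[1]


def map_to_normal_face(seq: RawSequence) -> RawSequence:
    """Subtract the first frame: output[t, j] = input[t, j] - input[0, j]."""
    if seq.length < 1:
        raise ValueError("empty sequence")
    return RawSequence(
        sequence_id=seq.sequence_id,
        emotion_id=seq.emotion_id,
        values=seq.values - seq.values[0],
    )


class NormalFaceScaler(BaseEstimator, TransformerMixin):
    """First-frame normalization followed by per-feature min-max scaling.

    Parameters
    ----------
    normalization_enabled : bool
        If False, the first-frame subtraction is skipped and scaling applies
        to raw values (the ablation condition); scaling itself always runs.
    feature_range : tuple of float
        Target band for the per-feature global min/max, default (-0.9, 0.9).

    Attributes
    ----------
    min_, max_ : (F,) arrays — per-feature extrema of the (optionally
        first-frame-normalized) training data.
    """

    def __init__(
        self,
        normalization_enabled: bool = True,
        feature_range: tuple[float, float] = (-0.9, 0.9),
    ):
        self.normalization_enabled = normalization_enabled
        self.feature_range = feature_range

    def _normalized_values(self, seqs: list[RawSequence]) -> list[np.ndarray]:
        if self.normalization_enabled:
            return [s.values - s.values[0] for s in seqs]
        return [s.values for s in seqs]

    def fit(self, X: list[RawSequence], y=None) -> "NormalFaceScaler":
        if not X:
            raise ValueError("cannot fit on an empty dataset")
        stacked = np.vstack(self._normalized_values(X))
        self.min_ = stacked.min(axis=0)
        self.max_ = stacked.max(axis=0)
        degenerate = np.flatnonzero(self.max_ <= self.min_)
        if degenerate.size:
            raise ValueError(
                f"degenerate features (MAX == MIN): {degenerate.tolist()}"
            )
        self.n_features_in_ = stacked.shape[1]
        return self

    def transform(self, X: list[RawSequence]) -> list[TargetSequence]:
        self._check_fitted()
        lo, hi = self.feature_range
        span = hi - lo
        out = []
        for seq, values in zip(X, self._normalized_values(X)):
            scaled = (values - self.min_) / (self.max_ - self.min_) * span + lo
            out.append(
                TargetSequence(
                    sequence_id=seq.sequence_id,
                    emotion_id=seq.emotion_id,
                    targets=scaled,
                )
            )
        return out

    def inverse_transform(self, X: list[TargetSequence]) -> list[np.ndarray]:
        """Undo the min-max scaling (first-frame subtraction is lossy)."""
        self._check_fitted()
        lo, hi = self.feature_range
        span = hi - lo
        return [
            (seq.targets - lo) / span * (self.max_ - self.min_) + self.min_
            for seq in X
        ]

    def _check_fitted(self) -> None:
        if not hasattr(self, "min_"):
            raise RuntimeError("NormalFaceScaler is not fitted")

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        self._check_fitted()
        payload = json.dumps(
            {
                "normalization_enabled": self.normalization_enabled,
                "feature_range": list(self.feature_range),
                "min": self.min_.tolist(),
                "max": self.max_.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "NormalFaceScaler":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        data = json.loads(text)
        scaler = cls(
            normalization_enabled=data["normalization_enabled"],
            feature_range=tuple(data["feature_range"]),
        )
        scaler.min_ = np.asarray(data["min"], dtype=float)
        scaler.max_ = np.asarray(data["max"], dtype=float)
        scaler.n_features_in_ = scaler.min_.size
        return scaler


def fit_and_scale(
    seqs: list[RawSequence], normalization_enabled: bool = True
) -> tuple[list[TargetSequence], NormalFaceScaler]:
    """Fit the scaler on ``seqs`` and return the scaled target sequences."""
    scaler = NormalFaceScaler(normalization_enabled=normalization_enabled)
    return scaler.fit(seqs).transform(seqs), scaler


class FeatureReducer(BaseEstimator, TransformerMixin):
    """Drop near-immobile channels, then strongly correlated duplicates.

    A feature is immobile when its displacement range across the whole
    dataset falls below ``motion_threshold``.  Remaining features are
    scanned in input order; a feature is dropped when its absolute Pearson
    correlation (on concatenated sequences) with an already-retained
    feature exceeds ``corr_threshold``.  Deterministic given input order.
    """

    def __init__(self, corr_threshold: float = 0.95, motion_threshold: float | None = None):
        self.corr_threshold = corr_threshold
        self.motion_threshold = motion_threshold

    def fit(self, X: list[RawSequence], y=None) -> "FeatureReducer":
        if not X:
            raise ValueError("cannot fit on an empty dataset")
        stacked = np.vstack([s.values for s in X])
        if stacked.shape[1] < 2:
            raise ValueError("need at least 2 features")
        ranges = stacked.max(axis=0) - stacked.min(axis=0)
        if self.motion_threshold is None:
            thr = 0.05 * float(np.median(ranges))
        else:
            thr = float(self.motion_threshold)
        mobile = np.flatnonzero(ranges >= thr)
        retained: list[int] = []
        for j in mobile:
            duplicate = False
            for k in retained:
                sd_j, sd_k = stacked[:, j].std(), stacked[:, k].std()
                if sd_j == 0 or sd_k == 0:
                    continue
                r = np.corrcoef(stacked[:, j], stacked[:, k])[0, 1]
                if abs(r) > self.corr_threshold:
                    duplicate = True
                    break
            if not duplicate:
                retained.append(int(j))
        if not retained:
            raise ValueError("all features removed by reduction")
        self.retained_ = np.array(retained, dtype=int)
        self.n_features_in_ = stacked.shape[1]
        return self

    def transform(self, X: list[RawSequence]) -> list[RawSequence]:
        if not hasattr(self, "retained_"):
            raise RuntimeError("FeatureReducer is not fitted")
        return [
            RawSequence(
                sequence_id=s.sequence_id,
                emotion_id=s.emotion_id,
                values=s.values[:, self.retained_],
            )
            for s in X
        ]


def reduce_features(
    seqs: list[RawSequence],
    corr_threshold: float = 0.95,
    motion_threshold: float | None = None,
) -> tuple[list[RawSequence], np.ndarray]:
    reducer = FeatureReducer(corr_threshold, motion_threshold)
    return reducer.fit(seqs).transform(seqs), reducer.retained_
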