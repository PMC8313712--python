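"""scikit-learn style estimator facade over the S-CTRNNPB.

``fit`` runs the developmental-learning phase (weights + one PB state per
training sequence); ``transform`` runs test-phase error regression,
mapping unseen sequences to PB activities with weights frozen.  The
estimator composes with sklearn model-selection utilities via
``get_params``/``set_params``; inputs are lists of ``TargetSequence`` or
``(T, F)`` arrays rather than a rectangular design matrix, since the
sequences have variable length.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .evaluation import silhouette_index
from .network import NetworkConfig, PaddedBatch, _forward_batch
from .preprocessing import TargetSequence
from .recognition import RecognitionConfig, RecognitionResult, infer_pb_batch
from .training import TrainingConfig, _batch_metrics, train


def _as_arrays(X) -> list[np.ndarray]:
    return [
        s.targets if isinstance(s, TargetSequence) else np.asarray(s, dtype=float)
        for s in X
    ]


class SCTRNNPB(BaseEstimator, TransformerMixin):
    """Stochastic continuous-time RNN with parametric bias.

    Parameters
    ----------
    n_lower : int
        Lower-level (leaky-integrator) neuron count.
    n_pb : int
        Parametric-bias dimensionality (2 in the reference design).
    K : float
        Variance of the fixed lower-level activity thresholds; large K
        gives heterogeneous intrinsic excitability (typical-development
        condition), small K a homogeneous network.
    tau : float
        Shared lower-level time constant (>= 1); 1/tau is the integration
        rate of the leaky update.
    n_iterations, learning_rate, pb_learning_rate, optimizer,
    gradient_clip, eval_every : training-phase settings.
    n_update_iterations, recognition_learning_rate, pb_init :
        test-phase (error-regression) settings.
    random_state : int
        Seed for parameter initialization.

    Attributes
    ----------
    params_ : NetworkParams — trained weights and thresholds.
    pb_internal_, pb_activity_ : (n_sequences, n_pb) — learned PB states.
    loss_curve_ : dict of per-evaluation lists (iteration, train_nll,
        train_mse, mean_v).
    """

    def __init__(
        self,
        n_lower: int = 50,
        n_pb: int = 2,
        K: float = 1000.0,
        tau: float = 2.0,
        variance_floor: float = 1e-6,
        n_iterations: int = 15000,
        learning_rate: float = 1e-3,
        pb_learning_rate: float = 0.1,
        optimizer: str = "adam",
        gradient_clip: float | None = 1.0,
        eval_every: int = 50,
        n_update_iterations: int = 300,
        recognition_learning_rate: float = 1e-2,
        pb_init: str = "zero",
        random_state: int = 0,
    ):
        self.n_lower = n_lower
        self.n_pb = n_pb
        self.K = K
        self.tau = tau
        self.variance_floor = variance_floor
        self.n_iterations = n_iterations
        self.learning_rate = learning_rate
        self.pb_learning_rate = pb_learning_rate
        self.optimizer = optimizer
        self.gradient_clip = gradient_clip
        self.eval_every = eval_every
        self.n_update_iterations = n_update_iterations
        self.recognition_learning_rate = recognition_learning_rate
        self.pb_init = pb_init
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _network_config(self, n_features: int) -> NetworkConfig:
        return NetworkConfig(
            n_input=n_features,
            n_lower=self.n_lower,
            n_pb=self.n_pb,
            K=self.K,
            tau_lower=self.tau,
            variance_floor=self.variance_floor,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        """Learn weights and per-sequence PB states; ``y`` is ignored
        (emotion labels play no role in learning)."""
        arrays = _as_arrays(X)
        if len(arrays) < 1:
            raise ValueError("need at least one sequence")
        self.n_features_in_ = arrays[0].shape[1]
        self.config_ = self._network_config(self.n_features_in_)
        tconfig = TrainingConfig(
            n_iterations=self.n_iterations,
            learning_rate=self.learning_rate,
            pb_learning_rate=self.pb_learning_rate,
            optimizer=self.optimizer,
            gradient_clip=self.gradient_clip,
            eval_every=self.eval_every,
            seed=self.random_state,
        )
        result = train(
            [TargetSequence(i, 0, a) for i, a in enumerate(arrays)],
            self.config_,
            tconfig,
        )
        self.params_ = result.params
        self.pb_internal_ = result.pb_internal
        self.pb_activity_ = result.pb_activity
        self.loss_curve_ = result.curves
        return self

    def transform(self, X) -> np.ndarray:
        """Infer PB activities for unseen sequences by error regression."""
        return np.array([r.pb_activity for r in self.infer(X)])

    def infer(self, X) -> list[RecognitionResult]:
        """Full per-sequence recognition results (PB, NLL, MSE, trajectory)."""
        self._check_fitted()
        arrays = _as_arrays(X)
        rconfig = RecognitionConfig(
            n_update_iterations=self.n_update_iterations,
            pb_learning_rate=self.recognition_learning_rate,
            pb_init=self.pb_init,
            optimizer=self.optimizer,
            gradient_clip=self.gradient_clip,
            seed=self.random_state,
        )
        return infer_pb_batch(
            self.params_,
            self.config_,
            rconfig,
            [TargetSequence(i, 0, a) for i, a in enumerate(arrays)],
            training_pb=self.pb_internal_,
        )

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit, then return the *learned* (training) PB activities."""
        return self.fit(X, y).pb_activity_

    def predict(self, X, pb_internal: np.ndarray | None = None) -> list[np.ndarray]:
        """Teacher-forced one-step-ahead predicted means per sequence.

        Uses zero PB states unless ``pb_internal`` (n_sequences, n_pb) is
        given (e.g. the learned or inferred states).
        """
        self._check_fitted()
        batch = PaddedBatch(_as_arrays(X))
        if pb_internal is None:
            pb_internal = np.zeros((batch.n_sequences, self.config_.n_pb))
        fwd = _forward_batch(self.params_, self.config_, batch, np.asarray(pb_internal))
        return [
            fwd["Y"][: batch.lengths[i] - 1, i, :] for i in range(batch.n_sequences)
        ]

    def score(self, X, y=None) -> float:
        """Negative teacher-forced averaged MSE under zero PB (higher is
        better, sklearn convention)."""
        self._check_fitted()
        batch = PaddedBatch(_as_arrays(X))
        fwd = _forward_batch(
            self.params_, self.config_, batch,
            np.zeros((batch.n_sequences, self.config_.n_pb)),
        )
        return -_batch_metrics(fwd, batch)[0]

    def silhouette(self, labels: np.ndarray) -> float:
        """Silhouette of the learned training-PB activities by emotion."""
        self._check_fitted()
        return silhouette_index(self.pb_activity_, np.asarray(labels))

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("SCTRNNPB is not fitted")
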