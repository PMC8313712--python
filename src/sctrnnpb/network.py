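"""S-CTRNNPB forward model and backpropagation through time.

The network has three levels:

* **Parametric bias (PB)** — a few higher-level units whose internal state
  is constant across the time steps of a sequence.  One PB state per
  sequence is learned during training and inferred for unseen sequences.
* **Lower level** — leaky-integrator (continuous-time) neurons with fixed
  activity thresholds ``a_i ~ N(0, K)``.  The variance ``K`` controls the
  heterogeneity of intrinsic excitability: at small ``K`` every neuron
  operates near the sensitive center of tanh, at large ``K`` many neurons
  saturate and the functional network shrinks.
* **Output heads** — non-recurrent units producing the predicted mean
  ``y = tanh(u)`` and the estimated variance ``v = exp(u)`` of the next
  sensory state.

Internal-state update for one step::

    u_t[PB]    = u_{t-1}[PB]                                   (held)
    u_t[lower] = (W_x x_t + W_l l_{t-1} + W_p p_t + a) / tau
                 + (1 - 1/tau) u_{t-1}[lower]
    u_t[head]  = W_y l_t + a                                   (no leak)

Training minimizes the precision-weighted negative log-likelihood

    L = ln(2 pi v) / 2 + (y_hat - y)^2 / (2 v)

summed over features, steps and sequences, so the network learns to weight
its prediction errors by the precision (1/v) it estimates for each input.
Gradients are exact BPTT, written out by hand below and verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import TargetSequence

TRAINABLE_KEYS = ("w_xl", "w_ll", "w_pl", "w_ly", "a_y", "w_lv", "a_v")


@dataclass(frozen=True)
class NetworkConfig:
    n_input: int = 9
    n_lower: int = 500
    n_pb: int = 2
    K: float = 1000.0
    tau_lower: float = 2.0
    variance_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_input < 1 or self.n_lower < 1 or self.n_pb < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.K < 0:
            raise ValueError("K (threshold variance) must be >= 0")
        if self.tau_lower < 1:
            raise ValueError("tau_lower must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be > 0")


@dataclass(frozen=True)
class NeuronIndexSets:
    """Disjoint index ranges of the five neuron groups in one flat layout."""

    pb: range
    lower: range
    inputs: range
    mean: range
    variance: range

    @classmethod
    def from_config(cls, config: NetworkConfig) -> "NeuronIndexSets":
        o = 0
        ranges = []
        for size in (config.n_pb, config.n_lower, config.n_input,
                     config.n_input, config.n_input):
            ranges.append(range(o, o + size))
            o += size
        return cls(*ranges)


@dataclass
class NetworkParams:
    """Connection weights and thresholds.

    Lower-level thresholds ``a_l`` are drawn once from N(0, K) and frozen;
    output-head thresholds ``a_y``/``a_v`` are trainable.  ``w_ab`` maps
    group ``a`` onto group ``b`` reading left-to-right (e.g. ``w_xl`` is
    input -> lower), stored as (target, source) matrices.
    """

    w_xl: np.ndarray  # (n_lower, n_input)
    w_ll: np.ndarray  # (n_lower, n_lower) recurrent
    w_pl: np.ndarray  # (n_lower, n_pb)
    a_l: np.ndarray   # (n_lower,) frozen activity thresholds
    w_ly: np.ndarray  # (n_input, n_lower) mean head
    a_y: np.ndarray   # (n_input,)
    w_lv: np.ndarray  # (n_input, n_lower) variance head
    a_v: np.ndarray   # (n_input,)
    tau: float = 2.0

    def trainable(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in TRAINABLE_KEYS}

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            **{k: getattr(self, k).copy() for k in TRAINABLE_KEYS},
            a_l=self.a_l.copy(),
            tau=self.tau,
        )


def init_params(config: NetworkConfig) -> NetworkParams:
    """Draw initial parameters; deterministic under ``config.seed``.

    Weights are uniform on [-1/sqrt(fan_in), +1/sqrt(fan_in)] per connection
    group; head thresholds start at 0; lower-level thresholds are Gaussian
    with variance ``K`` and are never updated afterwards.
    """
    rng = np.random.default_rng(config.seed)

    def uniform(shape: tuple[int, int]) -> np.ndarray:
        bound = 1.0 / np.sqrt(shape[1])
        return rng.uniform(-bound, bound, size=shape)

    n_l, n_in, n_pb = config.n_lower, config.n_input, config.n_pb
    return NetworkParams(
        w_xl=uniform((n_l, n_in)),
        w_ll=uniform((n_l, n_l)),
        w_pl=uniform((n_l, n_pb)),
        a_l=rng.normal(0.0, np.sqrt(config.K), size=n_l),
        w_ly=uniform((n_in, n_l)),
        a_y=np.zeros(n_in),
        w_lv=uniform((n_in, n_l)),
        a_v=np.zeros(n_in),
        tau=config.tau_lower,
    )


# ---------------------------------------------------------------------------
# forward pass

def forward_step(
    params: NetworkParams,
    config: NetworkConfig,
    u_prev: np.ndarray,
    x_t: np.ndarray,
    pb_internal: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One update of the lower level plus both output heads.

    Returns ``(u, l, y, v)`` for lower-level internal state, lower-level
    activity, predicted mean and estimated variance.
    """
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(u_prev))):
        raise FloatingPointError("non-finite inputs to forward_step")
    tau = params.tau
    p = np.tanh(pb_internal)
    l_prev = np.tanh(u_prev)
    drive = params.w_xl @ x_t + params.w_ll @ l_prev + params.w_pl @ p + params.a_l
    u = drive / tau + (1.0 - 1.0 / tau) * u_prev
    l = np.tanh(u)
    y = np.tanh(params.w_ly @ l + params.a_y)
    v = np.exp(params.w_lv @ l + params.a_v) + config.variance_floor
    return u, l, y, v


@dataclass
class SequenceTrace:
    """Per-step record of one sequence pass.

    Row ``k`` holds the state after consuming input ``x[k]`` and predicting
    the target at step ``k + 1`` (0-based); there are ``length - 1``
    prediction rows for a sequence of ``length`` steps.
    """

    inputs: np.ndarray        # (T-1, F) what the network consumed
    u_lower: np.ndarray       # (T-1, n_lower)
    lower: np.ndarray         # (T-1, n_lower) tanh activities
    pb_activity: np.ndarray   # (n_pb,) constant over the sequence
    y_mean: np.ndarray        # (T-1, F) predicted means
    variance: np.ndarray      # (T-1, F) estimated variances
    losses: np.ndarray = field(default=None)  # (T-1, F) per-step NLL

    @property
    def n_steps(self) -> int:
        return self.y_mean.shape[0]


def forward_sequence(
    params: NetworkParams,
    config: NetworkConfig,
    targets: TargetSequence | np.ndarray,
    pb_internal: np.ndarray,
    mode: str = "teacher_forced",
    sample_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> SequenceTrace:
    """Run one sequence and record all per-step quantities.

    ``teacher_forced`` feeds the true target at step ``k`` as input when
    predicting step ``k + 1``; ``closed_loop`` feeds the model's own
    previous predicted mean (the first target seeds the loop).  With
    ``sample_noise`` in closed loop, the fed-back value is sampled from
    the predicted Gaussian, ``y + sqrt(v) * xi``, instead of the mean;
    off by default — all reported analyses use deterministic means.
    """
    values = targets.targets if isinstance(targets, TargetSequence) else np.asarray(targets)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 steps to form a prediction")
    if mode not in ("teacher_forced", "closed_loop"):
        raise ValueError(f"unknown mode {mode!r}")
    n_steps = values.shape[0] - 1
    p = np.tanh(pb_internal)
    if sample_noise and rng is None:
        rng = np.random.default_rng(config.seed)
    u_prev = np.zeros(config.n_lower)
    xs, us, ls, ys, vs = [], [], [], [], []
    x_t = values[0]
    for k in range(n_steps):
        u_prev, l, y, v = forward_step(params, config, u_prev, x_t, pb_internal)
        xs.append(x_t)
        us.append(u_prev)
        ls.append(l)
        ys.append(y)
        vs.append(v)
        if mode == "teacher_forced":
            x_t = values[k + 1]
        else:
            x_t = y + np.sqrt(v) * rng.standard_normal(y.shape) if sample_noise else y
    trace = SequenceTrace(
        inputs=np.array(xs),
        u_lower=np.array(us),
        lower=np.array(ls),
        pb_activity=p,
        y_mean=np.array(ys),
        variance=np.array(vs),
    )
    err = trace.y_mean - values[1:]
    trace.losses = 0.5 * np.log(2.0 * np.pi * trace.variance) + err**2 / (2.0 * trace.variance)
    return trace


def nll_step(y_hat: float, y: float, v: float) -> float:
    """Precision-weighted Gaussian NLL of one prediction."""
    if v <= 0:
        raise ValueError("variance must be positive")
    return 0.5 * np.log(2.0 * np.pi * v) + (y_hat - y) ** 2 / (2.0 * v)


def sequence_nll(trace: SequenceTrace, targets: TargetSequence | np.ndarray) -> float:
    """Total NLL over all prediction steps and features of one sequence.

    The sum starts at the first step for which a prediction exists (the
    first target step has no preceding input).  Per-step diagnostics are
    available as ``trace.losses``.
    """
    values = targets.targets if isinstance(targets, TargetSequence) else np.asarray(targets)
    if values.shape[0] - 1 != trace.n_steps:
        raise ValueError(
            f"trace has {trace.n_steps} prediction steps but targets imply "
            f"{values.shape[0] - 1}"
        )
    err = trace.y_mean - values[1:]
    return float(
        np.sum(0.5 * np.log(2.0 * np.pi * trace.variance) + err**2 / (2.0 * trace.variance))
    )


# ---------------------------------------------------------------------------
# batched teacher-forced pass + exact BPTT (used by training and inference)

class PaddedBatch:
    """Variable-length target sequences padded into one (B, T, F) array."""

    def __init__(self, dataset: list[TargetSequence] | list[np.ndarray]):
        arrays = [
            s.targets if isinstance(s, TargetSequence) else np.asarray(s, dtype=float)
            for s in dataset
        ]
        if not arrays:
            raise ValueError("empty dataset")
        self.lengths = np.array([a.shape[0] for a in arrays])
        if self.lengths.min() < 2:
            raise ValueError("every sequence needs length >= 2")
        n_feat = arrays[0].shape[1]
        tmax = int(self.lengths.max())
        self.targets = np.zeros((len(arrays), tmax, n_feat))
        for i, a in enumerate(arrays):
            self.targets[i, : a.shape[0]] = a
        # step k (input = target[k]) is valid when a target at k+1 exists
        steps = np.arange(tmax - 1)
        self.step_mask = steps[None, :] < (self.lengths[:, None] - 1)
        self.n_valid_steps = int(self.step_mask.sum())

    @property
    def n_sequences(self) -> int:
        return self.targets.shape[0]

    @property
    def n_features(self) -> int:
        return self.targets.shape[2]


def _forward_batch(params, config, batch: PaddedBatch, pb_u: np.ndarray,
                   inputs: np.ndarray | None = None):
    """Teacher-forced pass over all sequences at once.

    ``inputs`` (B, T-1, F) overrides the fed-in values (e.g. noise-corrupted
    targets during training); the loss targets stay the clean ones.  Returns
    dict of stacked per-step arrays; padded steps hold values that are
    ignored downstream via ``batch.step_mask``.
    """
    B, T, F = batch.targets.shape
    n_steps = T - 1
    if inputs is None:
        inputs = batch.targets[:, :-1]
    tau = params.tau
    p = np.tanh(pb_u)  # (B, n_pb)
    pb_drive = p @ params.w_pl.T + params.a_l  # constant over time
    u = np.zeros((B, config.n_lower))
    l = np.tanh(u)
    L = np.empty((n_steps, B, config.n_lower))
    U = np.empty_like(L)
    Y = np.empty((n_steps, B, F))
    UV = np.empty_like(Y)
    for k in range(n_steps):
        drive = inputs[:, k] @ params.w_xl.T + l @ params.w_ll.T + pb_drive
        u = drive / tau + (1.0 - 1.0 / tau) * u
        l = np.tanh(u)
        U[k] = u
        L[k] = l
        Y[k] = np.tanh(l @ params.w_ly.T + params.a_y)
        UV[k] = l @ params.w_lv.T + params.a_v
    V = np.exp(UV) + config.variance_floor
    return {"p": p, "U": U, "L": L, "Y": Y, "UV": UV, "V": V}


def batch_nll(fwd: dict, batch: PaddedBatch) -> float:
    err = fwd["Y"] - np.transpose(batch.targets[:, 1:], (1, 0, 2))
    per = 0.5 * np.log(2.0 * np.pi * fwd["V"]) + err**2 / (2.0 * fwd["V"])
    mask = batch.step_mask.T[:, :, None]
    return float(np.sum(per * mask))


def compute_gradients(
    params: NetworkParams,
    config: NetworkConfig,
    pb_u: np.ndarray,
    batch: PaddedBatch,
    pb_only: bool = False,
    inputs: np.ndarray | None = None,
):
    """Exact gradients of the summed NLL by backpropagation through time.

    Returns ``(grads, pb_grad, total_nll, fwd)`` where ``grads`` maps the
    trainable parameter names to arrays (empty when ``pb_only``) and
    ``pb_grad`` is (B, n_pb) over the sequences' PB internal states.
    Lower-level thresholds receive no gradient: they are frozen by
    construction.  ``inputs`` optionally replaces the fed-in values (see
    ``_forward_batch``); the loss is always against the clean targets.
    """
    if inputs is None:
        inputs = batch.targets[:, :-1]
    fwd = _forward_batch(params, config, batch, pb_u, inputs=inputs)
    B, T, F = batch.targets.shape
    n_steps = T - 1
    tau = params.tau
    U, L, Y, V = fwd["U"], fwd["L"], fwd["Y"], fwd["V"]
    p = fwd["p"]
    mask = batch.step_mask.T  # (n_steps, B)

    targets_next = np.transpose(batch.targets[:, 1:], (1, 0, 2))  # (n_steps, B, F)
    err = Y - targets_next
    per = 0.5 * np.log(2.0 * np.pi * V) + err**2 / (2.0 * V)
    total = float(np.sum(per * mask[:, :, None]))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite loss in compute_gradients")

    # output-head deltas, masked
    m3 = mask[:, :, None]
    d_y = (err / V) * m3                      # dL/dy
    delta_m = d_y * (1.0 - Y**2)              # dL/du_mean
    d_v = (0.5 / V - err**2 / (2.0 * V**2)) * m3
    delta_v = d_v * (V - config.variance_floor)  # dv/du = exp(u_v)

    grads = {}
    if not pb_only:
        LT = L.reshape(-1, config.n_lower)
        grads["w_ly"] = delta_m.reshape(-1, F).T @ LT
        grads["a_y"] = delta_m.sum(axis=(0, 1))
        grads["w_lv"] = delta_v.reshape(-1, F).T @ LT
        grads["a_v"] = delta_v.sum(axis=(0, 1))
        g_w_xl = np.zeros_like(params.w_xl)
        g_w_ll = np.zeros_like(params.w_ll)

    # backward through time over the lower level
    delta_u_sum = np.zeros((B, config.n_lower))  # sum over t of dL/du_t (for PB/W_pl)
    delta_u_next = np.zeros((B, config.n_lower))
    l_init = np.zeros((B, config.n_lower))
    for k in range(n_steps - 1, -1, -1):
        dl = delta_m[k] @ params.w_ly + delta_v[k] @ params.w_lv
        dl += (delta_u_next @ params.w_ll) / tau
        delta_u = dl * (1.0 - L[k] ** 2) + (1.0 - 1.0 / tau) * delta_u_next
        if not pb_only:
            g_w_xl += delta_u.T @ inputs[:, k] / tau
            l_prev = L[k - 1] if k > 0 else l_init
            g_w_ll += delta_u.T @ l_prev / tau
        delta_u_sum += delta_u
        delta_u_next = delta_u

    pb_grad = (delta_u_sum / tau) @ params.w_pl * (1.0 - p**2)
    if not pb_only:
        grads["w_xl"] = g_w_xl
        grads["w_ll"] = g_w_ll
        grads["w_pl"] = (delta_u_sum / tau).T @ p
    return grads, pb_grad, total, fwd


# ---------------------------------------------------------------------------
# checkpointing (JSON: Python float repr round-trips binary64 exactly)

def save_checkpoint(
    path: str | Path,
    params: NetworkParams,
    config: NetworkConfig,
    pb_internal: np.ndarray | None = None,
    scaler_json: str | None = None,
    extra: dict | None = None,
) -> None:
    payload = {
        "config": {
            "n_input": config.n_input,
            "n_lower": config.n_lower,
            "n_pb": config.n_pb,
            "K": config.K,
            "tau_lower": config.tau_lower,
            "variance_floor": config.variance_floor,
            "seed": config.seed,
        },
        "params": {
            **{k: getattr(params, k).tolist() for k in TRAINABLE_KEYS},
            "a_l": params.a_l.tolist(),
            "tau": params.tau,
        },
        "pb_internal": None if pb_internal is None else np.asarray(pb_internal).tolist(),
        "scaler": scaler_json,
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path):
    data = json.loads(Path(path).read_text())
    config = NetworkConfig(**data["config"])
    p = data["params"]
    params = NetworkParams(
        **{k: np.asarray(p[k], dtype=float) for k in TRAINABLE_KEYS},
        a_l=np.asarray(p["a_l"], dtype=float),
        tau=float(p["tau"]),
    )
    pb = None if data["pb_internal"] is None else np.asarray(data["pb_internal"], dtype=float)
    return params, config, pb, data.get("scaler"), data.get("extra", {})
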