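"""Bidirectional LSTM classifier trained by CHO instead of gradients.

A single BiLSTM layer reads the feature vector E as a short sequence
(row-wise chunking with zero padding).  One direction's cell follows the
standard gated recurrence

    Q_t = sigma(wQ [h_{t-1}, x_t] + dQ)        (forget gate)
    I_t = sigma(wI [h_{t-1}, x_t] + dI)        (input gate)
    P_t = sigma(wP [h_{t-1}, x_t] + dP)        (output gate)
    Xc  = tanh (wX [h_{t-1}, x_t] + dX)        (candidate)
    c_t = Q_t * c_{t-1} + I_t * Xc
    h_t = P_t * tanh(c_t)

The forward pass reads left to right, the backward pass right to left; the
final representation [h_fwd(T), h_bwd(1)] feeds a single linear score, and
the malignancy probability is its sigmoid.  All weights and biases (both
directions plus the output layer) are flattened into one parameter vector
and optimised directly by CHO with classification accuracy as the fitness —
there is no gradient training anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .cho import Bounds, CHOConfig, optimize

__all__ = [
    "DirectionParams",
    "BiLSTMParams",
    "lstm_cell_step",
    "bilstm_forward",
    "encode_as_sequence",
    "flatten_params",
    "unflatten_params",
    "param_count",
    "fitness_of_candidate",
    "BiLSTMClassifier",
    "train_with_cho",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class DirectionParams:
    """Gate weights (hidden x (hidden + input)) and biases for one direction."""

    wq: np.ndarray
    wi: np.ndarray
    wp: np.ndarray
    wx: np.ndarray
    bq: np.ndarray
    bi: np.ndarray
    bp: np.ndarray
    bx: np.ndarray


@dataclass
class BiLSTMParams:
    forward: DirectionParams
    backward: DirectionParams
    w_out: np.ndarray  # (2 * hidden,)
    b_out: float

    @property
    def hidden_size(self) -> int:
        return self.forward.wq.shape[0]

    @property
    def input_size(self) -> int:
        return self.forward.wq.shape[1] - self.hidden_size


def param_count(hidden_size: int, input_size: int) -> int:
    """Total number of scalars in a BiLSTMParams of the given geometry."""
    per_dir = 4 * (hidden_size * (hidden_size + input_size) + hidden_size)
    return 2 * per_dir + 2 * hidden_size + 1


def flatten_params(params: BiLSTMParams) -> np.ndarray:
    """Fixed layout: fwd [wq wi wp wx bq bi bp bx], bwd likewise, w_out, b_out."""
    parts = []
    for d in (params.forward, params.backward):
        parts.extend([d.wq.ravel(), d.wi.ravel(), d.wp.ravel(), d.wx.ravel(),
                      d.bq, d.bi, d.bp, d.bx])
    parts.append(params.w_out)
    parts.append(np.array([params.b_out]))
    return np.concatenate(parts)


def unflatten_params(vec: np.ndarray, hidden_size: int, input_size: int) -> BiLSTMParams:
    vec = np.asarray(vec, dtype=float).ravel()
    expected = param_count(hidden_size, input_size)
    if vec.size != expected:
        raise ValueError(
            f"length mismatch: parameter vector has {vec.size}, expected {expected}"
        )
    h, m = hidden_size, hidden_size + input_size
    pos = 0

    def take(shape):
        nonlocal pos
        n = int(np.prod(shape))
        out = vec[pos:pos + n].reshape(shape)
        pos += n
        return out

    dirs = []
    for _ in range(2):
        wq, wi, wp, wx = (take((h, m)) for _ in range(4))
        bq, bi, bp, bx = (take((h,)) for _ in range(4))
        dirs.append(DirectionParams(wq, wi, wp, wx, bq, bi, bp, bx))
    w_out = take((2 * h,))
    b_out = float(take((1,))[0])
    return BiLSTMParams(dirs[0], dirs[1], w_out, b_out)


def lstm_cell_step(x_t, h_prev, c_prev, params: DirectionParams):
    """One gated cell update; returns (h_t, c_t).

    ``x_t``/``h_prev``/``c_prev`` may carry a leading batch axis.  Raises
    on non-finite intermediates.
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    hx = np.concatenate([h_prev, x_t], axis=-1)
    q = _sigmoid(hx @ params.wq.T + params.bq)
    i = _sigmoid(hx @ params.wi.T + params.bi)
    p = _sigmoid(hx @ params.wp.T + params.bp)
    cand = np.tanh(hx @ params.wx.T + params.bx)
    c_t = q * c_prev + i * cand
    h_t = p * np.tanh(c_t)
    if not (np.all(np.isfinite(h_t)) and np.all(np.isfinite(c_t))):
        raise FloatingPointError("numerical overflow in LSTM cell")
    return h_t, c_t


def _run_direction(seq: np.ndarray, params: DirectionParams) -> list[np.ndarray]:
    """Hidden states over a (T, ...) or (T, batch, ...) sequence, in scan order."""
    batch_shape = seq.shape[1:-1]
    h = np.zeros(batch_shape + (params.wq.shape[0],))
    c = np.zeros_like(h)
    states = []
    for t in range(seq.shape[0]):
        h, c = lstm_cell_step(seq[t], h, c, params)
        states.append(h)
    return states


def bilstm_forward(sequence, params: BiLSTMParams):
    """Bidirectional pass and linear score.

    ``sequence`` is a (T, step_dim) array or list of step vectors (a batch
    axis (T, n, step_dim) is accepted).  Returns ``(score, trace)`` where
    ``trace`` holds the per-step hidden states of both directions; the
    score is the linear readout of [h_fwd at step T, h_bwd at step 1].
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim == 1:
        seq = seq[None, :]
    if seq.shape[0] == 0:
        raise ValueError("empty sequence")
    fwd = _run_direction(seq, params.forward)
    bwd_rev = _run_direction(seq[::-1], params.backward)
    bwd = bwd_rev[::-1]  # bwd[t] is the backward state at step t
    rep = np.concatenate([fwd[-1], bwd[0]], axis=-1)
    score = rep @ params.w_out + params.b_out
    trace = {"forward": np.stack(fwd), "backward": np.stack(bwd)}
    return score, trace


def encode_as_sequence(E, timesteps: int, step_dim: int | None = None,
                       pad_value: float = 0.0) -> np.ndarray:
    """Row-wise chunking of a flat feature vector into (timesteps, step_dim).

    ``step_dim`` defaults to the smallest width that fits E; the tail is
    padded with ``pad_value``.  Step t holds E[t*step_dim : (t+1)*step_dim].
    """
    E = np.asarray(E, dtype=float).ravel()
    if timesteps < 1:
        raise ValueError("timesteps must be >= 1")
    if step_dim is None:
        step_dim = int(np.ceil(E.size / timesteps))
    total = timesteps * step_dim
    if total < E.size:
        raise ValueError("timesteps * step_dim must cover the feature length")
    padded = np.full(total, pad_value)
    padded[:E.size] = E
    return padded.reshape(timesteps, step_dim)


def fitness_of_candidate(param_vector, val_sequences: np.ndarray,
                         val_labels: np.ndarray, hidden_size: int,
                         step_dim: int) -> float:
    """Classification accuracy of the candidate parameters on a validation set.

    ``val_sequences`` has shape (T, n, step_dim); labels are 0/1 with 1 the
    positive (malignant) class.  This is the objective CHO maximises.
    """
    params = unflatten_params(param_vector, hidden_size, step_dim)
    scores, _ = bilstm_forward(val_sequences, params)
    pred = (_sigmoid(scores) >= 0.5).astype(int)
    return float(np.mean(pred == val_labels))


class BiLSTMClassifier(ClassifierMixin, BaseEstimator):
    """Binary BiLSTM classifier whose weights are found by CHO.

    Parameters
    ----------
    hidden_size : int, default=8
        Hidden state width per direction.
    timesteps : int, default=8
        Number of sequence steps the feature vector is chunked into.
    w_max : float, default=2.0
        Parameters are searched in the box [-w_max, w_max]^P.
    threshold : float, default=0.5
        Decision threshold on the malignancy probability; ties (p ==
        threshold) go to the positive class.
    cho : CHOConfig or None
        Optimizer configuration; a small default (pop 20, 50 iterations)
        is used when None.  Its seed is derived from ``random_state``.
    val_fraction : float, default=0.2
        Stratified fraction of the training data used as the fitness
        validation set.
    random_state : int or None
        Controls the split and the optimizer seed.

    Attributes
    ----------
    classes_ : ndarray of the two class labels (positive class is
        ``classes_[1]``).
    params_ : BiLSTMParams of the best candidate.
    history_ : per-iteration best fitness (non-decreasing).
    best_fitness_ : final fitness (validation accuracy).
    """

    def __init__(self, hidden_size=8, timesteps=8, w_max=2.0, threshold=0.5,
                 cho: CHOConfig | None = None, val_fraction=0.2,
                 random_state=None):
        self.hidden_size = hidden_size
        self.timesteps = timesteps
        self.w_max = w_max
        self.threshold = threshold
        self.cho = cho
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _encode_all(self, X: np.ndarray) -> np.ndarray:
        """(n, features) -> (T, n, step_dim) batched sequence tensor."""
        seqs = np.stack([
            encode_as_sequence(row, self.timesteps, self.step_dim_) for row in X
        ])  # (n, T, step_dim)
        return seqs.transpose(1, 0, 2)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("degenerate labels: need exactly two classes")
        y01 = (y == self.classes_[1]).astype(int)
        self.n_features_in_ = X.shape[1]
        self.step_dim_ = int(np.ceil(X.shape[1] / self.timesteps))

        seed = 0 if self.random_state is None else int(self.random_state)
        idx_tr, idx_val = train_test_split(
            np.arange(X.shape[0]), test_size=self.val_fraction,
            stratify=y01, random_state=seed, shuffle=True,
        )
        val_seq = self._encode_all(X[idx_val])
        val_lab = y01[idx_val]

        cho = self.cho or CHOConfig(pop_size=20, t_max=50)
        from dataclasses import replace
        cho = replace(cho, seed=seed)
        n_params = param_count(self.hidden_size, self.step_dim_)
        bounds = Bounds.cube(-self.w_max, self.w_max, n_params)

        def objective(vec):
            return fitness_of_candidate(
                vec, val_seq, val_lab, self.hidden_size, self.step_dim_
            )

        result = optimize(objective, bounds, cho)
        self.params_ = unflatten_params(result.best_position, self.hidden_size,
                                        self.step_dim_)
        self.param_vector_ = result.best_position
        self.history_ = result.history
        self.best_fitness_ = result.best_fitness
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        scores, _ = bilstm_forward(self._encode_all(X), self.params_)
        return scores

    def predict_proba(self, X):
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= self.threshold, self.classes_[1], self.classes_[0])

    def to_dict(self) -> dict:
        """JSON-serialisable model (versioned schema)."""
        return {
            "schema": "nodulekit-bilstm/1",
            "hidden_size": self.hidden_size,
            "timesteps": self.timesteps,
            "step_dim": self.step_dim_,
            "threshold": self.threshold,
            "classes": [str(c) for c in self.classes_],
            "parameters": self.param_vector_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BiLSTMClassifier":
        if payload.get("schema") != "nodulekit-bilstm/1":
            raise ValueError("unrecognised model schema")
        model = cls(hidden_size=payload["hidden_size"],
                    timesteps=payload["timesteps"],
                    threshold=payload.get("threshold", 0.5))
        model.step_dim_ = payload["step_dim"]
        model.classes_ = np.array(payload["classes"])
        model.param_vector_ = np.array(payload["parameters"], dtype=float)
        model.params_ = unflatten_params(model.param_vector_, model.hidden_size,
                                         model.step_dim_)
        model.n_features_in_ = model.step_dim_ * model.timesteps
        return model


def train_with_cho(X, y, cho_config: CHOConfig | None = None,
                   **model_kwargs) -> BiLSTMClassifier:
    """Convenience wrapper: fit a :class:`BiLSTMClassifier` by CHO."""
    model = BiLSTMClassifier(cho=cho_config, **model_kwargs)
    return model.fit(X, y)
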