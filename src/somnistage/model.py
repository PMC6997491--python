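"""Recurrent sleep-stage classifier: LSTM, weighted loss, batching, training.

The classifier is a single unidirectional LSTM consuming an ``(i*32) x 128``
spectral-sequence matrix row by row (one 900 ms STFT frame per step, 128
frequency-x-channel features).  The final hidden state feeds a dense layer to
five class logits; softmax yields the stage probabilities.  Class imbalance is
handled by a weighted softmax cross-entropy, with weight ``N/(5*n_k)`` for a
class with ``n_k`` of ``N`` training samples (absent classes get weight 0).

Training follows a fixed protocol: Adam (moment decay 0.9/0.999), initial
learning rate 1e-3 divided by 10 every 50 epochs and floored at 1e-6, at most
200 epochs, stopping early after five successive near-identical testing costs
(absolute difference below 1e-5) or five successive testing-cost increases.

Everything here is NumPy; forward and backward passes are hand-derived
backpropagation-through-time with batched BLAS matrix products, which is
entirely adequate for desk-scale experiments on synthetic nights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_CLASSES = 5
N_INPUT_COLUMNS = 128
FRAMES_PER_EPOCH = 32


class DivergenceError(RuntimeError):
    """Raised when the training cost becomes non-finite."""


@dataclass
class ModelConfig:
    """Architecture knobs; defaults follow the reference configuration."""

    n_cells: int = 512
    n_classes: int = N_CLASSES
    n_inputs: int = N_INPUT_COLUMNS
    mode: int = 3
    dropout: float = 0.0  # readout dropout; the LSTM itself uses none

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("cell count must be positive")
        if self.n_classes != N_CLASSES:
            raise ValueError("this classifier is five-class")
        if self.mode not in (1, 2, 3, 4):
            raise ValueError("mode must be in 1..4")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def expected_rows(self) -> int:
        return FRAMES_PER_EPOCH * self.mode


@dataclass
class TrainConfig:
    """Optimization protocol; defaults mirror the full-scale configuration."""

    max_epochs: int = 200
    lr_init: float = 1e-3
    lr_final: float = 1e-6
    lr_decay_every: int = 50
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 1024
    group_size: int = 10  # subjects per mini-batch construction group
    plateau_tol: float = 1e-5
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr_init < self.lr_final:
            raise ValueError("learning-rate schedule must be non-increasing")


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Stepped schedule: ``lr_init * 10^(-floor(epoch/50))``, floored at ``lr_final``."""
    lr = cfg.lr_init * 10.0 ** (-(epoch // cfg.lr_decay_every))
    return max(lr, cfg.lr_final)


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights normalized to mean 1: ``w_k = N / (5 * n_k)``.

    Classes absent from training get weight 0 (and a warning); with equal
    counts every weight is exactly 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} class counts")
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("class counts must be nonnegative with a positive total")
    weights = np.zeros(N_CLASSES)
    present = counts > 0
    weights[present] = counts.sum() / (N_CLASSES * counts[present])
    if not present.all():
        logger.warning("classes %s absent from training; weight set to 0",
                       np.flatnonzero(~present).tolist())
    return weights


def make_minibatches(
    samples_by_subject: dict, batch_size: int, group_size: int, seed: int
) -> list[np.ndarray]:
    """Subject-grouped random mini-batches of exactly ``batch_size`` samples.

    Subjects are randomly permuted and split into groups of ``group_size``;
    within each group the pooled samples are permuted and packed into
    full-size batches, each group leaving a remainder; the remainders are then
    concatenated and packed the same way, with the final short batch
    discarded.  Every emitted batch has exactly ``batch_size`` members and no
    sample appears twice.  ``samples_by_subject`` maps a subject key to an
    array of global sample indices.
    """
    if batch_size < 1:
        raise ValueError("batch size must be >= 1")
    if not samples_by_subject:
        raise ValueError("at least one subject is required")
    rng = np.random.default_rng(seed)
    subjects = list(samples_by_subject)
    order = rng.permutation(len(subjects))
    batches: list[np.ndarray] = []
    remainders: list[np.ndarray] = []
    for g0 in range(0, len(subjects), group_size):
        group = [subjects[i] for i in order[g0 : g0 + group_size]]
        pool = np.concatenate([np.asarray(samples_by_subject[s], dtype=int) for s in group])
        pool = pool[rng.permutation(len(pool))]
        n_full = len(pool) // batch_size
        for b in range(n_full):
            batches.append(pool[b * batch_size : (b + 1) * batch_size])
        if len(pool) % batch_size:
            remainders.append(pool[n_full * batch_size :])
    if remainders:
        pool = np.concatenate(remainders)
        n_full = len(pool) // batch_size
        for b in range(n_full):
            batches.append(pool[b * batch_size : (b + 1) * batch_size])
    return batches


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTMClassifier:
    """Single-layer LSTM with a dense five-class readout on the last step."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, h, c = config.n_inputs, config.n_cells, config.n_classes
        # Table-style initialization: Gaussian weights, zero biases.
        self.Wx = rng.normal(0.0, 1.0 / np.sqrt(d), (d, 4 * h)).astype(np.float32)
        self.Wh = rng.normal(0.0, 1.0 / np.sqrt(h), (h, 4 * h)).astype(np.float32)
        self.b = np.zeros(4 * h, dtype=np.float32)
        self.Wy = rng.normal(0.0, 1.0 / np.sqrt(h), (h, c)).astype(np.float32)
        self.by = np.zeros(c, dtype=np.float32)
        self._adam_state: dict | None = None

    # -- parameter plumbing -------------------------------------------------
    def _params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b, "Wy": self.Wy, "by": self.by}

    def _validate(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        rows = self.config.expected_rows
        if X.ndim != 3 or X.shape[1] != rows or X.shape[2] != self.config.n_inputs:
            raise ValueError(
                f"mode-{self.config.mode} model expects (n, {rows}, {self.config.n_inputs}) "
                f"inputs, got {X.shape}"
            )
        return X

    # -- forward / backward -------------------------------------------------
    def _forward(self, X: np.ndarray, keep_cache: bool):
        B, T, _ = X.shape
        h_dim = self.config.n_cells
        h = np.zeros((B, h_dim), dtype=np.float32)
        c = np.zeros((B, h_dim), dtype=np.float32)
        cache = [] if keep_cache else None
        xz_all = X @ self.Wx + self.b  # (B, T, 4H): input part of every gate
        for t in range(T):
            z = xz_all[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :h_dim])
            f = _sigmoid(z[:, h_dim : 2 * h_dim])
            g = np.tanh(z[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(z[:, 3 * h_dim :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if keep_cache:
                cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        logits = h @ self.Wy + self.by
        return logits, h, cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Per-sample stage probabilities (softmax over the five logits)."""
        X = self._validate(X)
        out = []
        for b0 in range(0, len(X), batch_size):
            logits, _, _ = self._forward(X[b0 : b0 + batch_size], keep_cache=False)
            out.append(softmax(logits.astype(np.float64)))
        return np.concatenate(out) if out else np.empty((0, self.config.n_classes))

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Predicted labels; ties in probability break to the lowest index."""
        return np.argmax(self.predict_proba(X, batch_size), axis=1)

    def cost(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray,
             batch_size: int = 512) -> float:
        """Mean weighted cross-entropy over a sample set."""
        X = self._validate(X)
        y = np.asarray(y, dtype=int)
        total = 0.0
        for b0 in range(0, len(X), batch_size):
            logits, _, _ = self._forward(X[b0 : b0 + batch_size], keep_cache=False)
            p = softmax(logits.astype(np.float64))
            yb = y[b0 : b0 + batch_size]
            nll = -np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None))
            total += float(np.sum(weights[yb] * nll))
        return total / len(X)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray,
                       dropout_rng: np.random.Generator | None = None):
        """Weighted cross-entropy and gradients for one mini-batch (BPTT)."""
        X = self._validate(X)
        y = np.asarray(y, dtype=int)
        B = len(X)
        h_dim = self.config.n_cells
        logits, h_last, cache = self._forward(X, keep_cache=True)

        drop_mask = None
        if self.config.dropout > 0 and dropout_rng is not None:
            keep = 1.0 - self.config.dropout
            drop_mask = (dropout_rng.random(h_last.shape) < keep).astype(np.float32) / keep
            logits = (h_last * drop_mask) @ self.Wy + self.by

        p = softmax(logits.astype(np.float64))
        w = weights[y]
        nll = -np.log(np.clip(p[np.arange(B), y], 1e-12, None))
        loss = float(np.mean(w * nll))
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training cost ({loss}); aborting")

        dlogits = p.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (w / B)[:, None]
        dlogits = dlogits.astype(np.float32)

        h_for_readout = h_last if drop_mask is None else h_last * drop_mask
        grads = {
            "Wy": h_for_readout.T @ dlogits,
            "by": dlogits.sum(axis=0),
            "Wx": np.zeros_like(self.Wx),
            "Wh": np.zeros_like(self.Wh),
            "b": np.zeros_like(self.b),
        }
        dh = dlogits @ self.Wy.T
        if drop_mask is not None:
            dh *= drop_mask
        dc = np.zeros((B, h_dim), dtype=np.float32)
        dXz = np.empty((B, X.shape[1], 4 * h_dim), dtype=np.float32)
        for t in range(X.shape[1] - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dXz[:, t] = dz
            grads["Wh"] += h_prev.T @ dz
            dh = dz @ self.Wh.T
            dc = dc * f
        # input-side weight gradients batched over all steps
        grads["Wx"] += np.tensordot(X, dXz, axes=([0, 1], [0, 1]))
        grads["b"] += dXz.sum(axis=(0, 1))
        return loss, grads

    def adam_step(self, grads: dict, lr: float, cfg: TrainConfig) -> None:
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self._params().items()},
                "v": {k: np.zeros_like(v) for k, v in self._params().items()},
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        for k, param in self._params().items():
            g = grads[k]
            st["m"][k] = b1 * st["m"][k] + (1 - b1) * g
            st["v"][k] = b2 * st["v"][k] + (1 - b2) * g * g
            m_hat = st["m"][k] / (1 - b1 ** st["t"])
            v_hat = st["v"][k] / (1 - b2 ** st["t"])
            param -= (lr * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)).astype(param.dtype)

    # -- persistence ---------------------------------------------------------
    def save(self, path, trace: dict | None = None) -> None:
        """Checkpoint: config + weights (+ optional training trace) as NPZ."""
        meta = {"config": asdict(self.config)}
        if trace is not None:
            meta["trace"] = trace
        np.savez_compressed(path, meta=json.dumps(meta), **self._params())

    @classmethod
    def load(cls, path) -> "LSTMClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            model = cls(ModelConfig(**meta["config"]))
            for k in model._params():
                getattr(model, k)[...] = z[k]
        return model


def build_model(config: ModelConfig, seed: int = 0) -> LSTMClassifier:
    """Construct a classifier with Gaussian weights and zero biases."""
    return LSTMClassifier(config, seed=seed)


class EarlyStopper:
    """Plateau and rise rules on the testing-cost trace.

    Stops after ``patience`` successive epoch-to-epoch differences with
    absolute value below ``tol`` (plateau), or ``patience`` successive
    increases (rise).
    """

    def __init__(self, tol: float = 1e-5, patience: int = 5):
        self.tol = tol
        self.patience = patience
        self.prev: float | None = None
        self.plateau_run = 0
        self.rise_run = 0
        self.reason: str | None = None

    def update(self, cost: float) -> bool:
        if self.prev is not None:
            delta = cost - self.prev
            self.plateau_run = self.plateau_run + 1 if abs(delta) < self.tol else 0
            self.rise_run = self.rise_run + 1 if delta > 0 else 0
        self.prev = cost
        if self.plateau_run >= self.patience:
            self.reason = "plateau"
        elif self.rise_run >= self.patience:
            self.reason = "rise"
        return self.reason is not None


@dataclass
class TrainingTrace:
    """Per-epoch record of the optimization."""

    train_costs: list[float] = field(default_factory=list)
    eval_costs: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    stop_reason: str = "max-epochs"

    def to_dict(self) -> dict:
        return asdict(self)


def train(
    model: LSTMClassifier,
    X: np.ndarray,
    y: np.ndarray,
    batches: list[np.ndarray],
    eval_X: np.ndarray,
    eval_y: np.ndarray,
    config: TrainConfig,
    weights: np.ndarray | None = None,
) -> TrainingTrace:
    """Run the full training protocol; returns the cost trace.

    ``batches`` index into ``X``/``y`` (see :func:`make_minibatches`); the
    testing cost driving the stopping rules is evaluated on
    ``eval_X``/``eval_y`` after every epoch, with the same class weights.
    """
    if not batches:
        raise ValueError("at least one mini-batch is required")
    y = np.asarray(y, dtype=int)
    if weights is None:
        weights = class_weights(np.bincount(y, minlength=N_CLASSES))
    X = np.asarray(X, dtype=np.float32)
    eval_X = np.asarray(eval_X, dtype=np.float32)
    rng = np.random.default_rng(config.seed)
    stopper = EarlyStopper(config.plateau_tol, config.patience)
    trace = TrainingTrace()
    for epoch in range(config.max_epochs):
        lr = learning_rate(epoch, config)
        epoch_cost = 0.0
        for batch in batches:
            loss, grads = model.loss_and_grads(X[batch], y[batch], weights, dropout_rng=rng)
            model.adam_step(grads, lr, config)
            epoch_cost += loss
        epoch_cost /= len(batches)
        eval_cost = model.cost(eval_X, eval_y, weights)
        trace.train_costs.append(epoch_cost)
        trace.eval_costs.append(eval_cost)
        trace.learning_rates.append(lr)
        logger.info("epoch %d: lr %.2e train cost %.5f test cost %.5f",
                    epoch, lr, epoch_cost, eval_cost)
        if stopper.update(eval_cost):
            trace.stop_reason = stopper.reason
            break
    return trace
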