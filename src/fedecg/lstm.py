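"""Client-side sequence classifier: a stacked LSTM over the 9 fiducial
features, implemented directly on numpy.

The nine features of a record are fed as a length-9 sequence of scalars in
canonical feature order — the classifier treats the feature vector as a
(9 time steps, 1 feature) sequence.  The default architecture stacks three
LSTM layers (64 -> 32 -> 16 units; the first two return per-step sequences,
the third returns its final state), applies ReLU to each layer's output and
a dropout of 0.2 after each, and ends in a dense softmax head with 3 units.

The cells are standard single-bias LSTM cells (sigmoid gates, tanh cell
activations); ReLU acts on the hidden-state sequence passed to the next
layer, not inside the recurrence.  Gradients are computed by full
backpropagation through time; a finite-difference check in the test suite
pins the implementation.

Everything stochastic (initialisation, dropout, mini-batch shuffling) draws
from a single seeded generator, so training is bit-reproducible on a fixed
BLAS backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .features import N_CLASSES, N_FEATURES, FeatureMatrix

__all__ = [
    "NetworkSpec", "TrainingConfig", "ModelParameters", "LSTMClassifier",
    "build_network", "count_trainable_parameters", "local_train",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description; the parameter registry is a pure function
    of this spec."""

    input_len: int = N_FEATURES
    lstm_units: tuple[int, ...] = (64, 32, 16)
    dropout_rate: float = 0.2
    n_classes: int = N_CLASSES

    def validate(self) -> None:
        if not self.lstm_units or any(u <= 0 for u in self.lstm_units):
            raise ValueError("lstm_units must be non-empty positive integers")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.input_len < 1:
            raise ValueError("input_len must be >= 1")


@dataclass
class TrainingConfig:
    """Local-training hyperparameters: mini-batch size B, local epochs E,
    learning rate eta, optimizer, and the seed for shuffling/dropout."""

    batch_size: int = 32
    local_epochs: int = 15
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


class ModelParameters:
    """Ordered named-tensor registry with an exact flatten/unflatten bijection.

    This is the unit federated averaging operates on: layer-wise averaging of
    registries and elementwise averaging of their flattened vectors coincide.
    """

    def __init__(self, entries: Sequence[tuple[str, np.ndarray]]):
        self._names = [name for name, _ in entries]
        self._arrays = {name: np.asarray(a, dtype=float) for name, a in entries}

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self._arrays[name]

    def __iter__(self):
        return ((n, self._arrays[n]) for n in self._names)

    def shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        return [(n, self._arrays[n].shape) for n in self._names]

    @property
    def size(self) -> int:
        return sum(a.size for a in self._arrays.values())

    def flatten(self) -> np.ndarray:
        return np.concatenate([self._arrays[n].ravel() for n in self._names])

    def unflatten(self, vector: np.ndarray) -> "ModelParameters":
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}")
        out, ofs = [], 0
        for n in self._names:
            a = self._arrays[n]
            out.append((n, vector[ofs:ofs + a.size].reshape(a.shape).copy()))
            ofs += a.size
        return ModelParameters(out)

    def copy(self) -> "ModelParameters":
        return ModelParameters([(n, a.copy()) for n, a in self])

    def same_registry(self, other: "ModelParameters") -> bool:
        return self.shapes() == other.shapes()

    def save(self, path) -> None:
        np.savez(path, **{n: a for n, a in self})

    @classmethod
    def load(cls, path) -> "ModelParameters":
        with np.load(path) as z:
            return cls([(n, z[n]) for n in z.files])


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def initialize_parameters(spec: NetworkSpec, seed: int = 0) -> ModelParameters:
    """Glorot-uniform kernels, zero biases with the forget-gate slice set to
    one (the usual LSTM bias trick)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, np.ndarray]] = []
    d_in = 1
    for layer, h in enumerate(spec.lstm_units):
        W = _glorot(rng, (d_in, 4 * h))
        U = _glorot(rng, (h, 4 * h))
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget gate
        entries += [(f"lstm{layer}.W", W), (f"lstm{layer}.U", U), (f"lstm{layer}.b", b)]
        d_in = h
    entries += [
        ("dense.W", _glorot(rng, (d_in, spec.n_classes))),
        ("dense.b", np.zeros(spec.n_classes)),
    ]
    return ModelParameters(entries)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _lstm_forward(X: np.ndarray, W, U, b, return_sequences: bool, cache: bool):
    """One LSTM layer over X of shape (B, T, D). Returns (output, cache).

    Output is relu(h_t) per step (or relu(h_T) only); the recurrence itself
    uses the raw hidden state h_t.
    """
    B, T, D = X.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    caches = [] if cache else None
    # input-to-hidden projections for all timesteps at once
    XW = (X.reshape(B * T, D) @ W).reshape(B, T, 4 * H) + b
    for t in range(T):
        z = XW[:, t, :] + h @ U
        gates = expit(z[:, : 2 * H])        # i, f share one contiguous slice
        i = gates[:, :H]
        f = gates[:, H:]
        g = np.tanh(z[:, 2 * H:3 * H])
        o = expit(z[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        hs[:, t, :] = h
        if cache:
            caches.append((X[:, t, :], h_prev, c_prev, i, f, g, o, tc))
    out = np.maximum(hs, 0.0) if return_sequences else np.maximum(hs[:, -1, :], 0.0)
    return out, (caches, hs)


def _lstm_backward(dOut, layer_cache, W, U, return_sequences: bool):
    """BPTT through one layer. dOut matches the layer's forward output shape
    (already multiplied by downstream dropout/ReLU-independent factors).

    Returns (dX, dW, dU, db).
    """
    caches, hs = layer_cache
    T = len(caches)
    B, H = caches[0][3].shape
    D = caches[0][0].shape[1]
    relu_mask = hs > 0
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H)
    dX = np.empty((B, T, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    dz = np.empty((B, 4 * H))
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, tc = caches[t]
        if return_sequences:
            dh = dOut[:, t, :] * relu_mask[:, t, :] + dh_next
        else:
            dh = dh_next.copy()
            if t == T - 1:
                dh += dOut * relu_mask[:, t, :]
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        dz[:, :H] = dc * g * i * (1 - i)
        dz[:, H:2 * H] = dc * c_prev * f * (1 - f)
        dz[:, 2 * H:3 * H] = dc * i * (1 - g * g)
        dz[:, 3 * H:] = do * o * (1 - o)
        dW += x_t.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t, :] = dz @ W.T
        dh_next = dz @ U.T
        dc_next = dc * f
    return dX, dW, dU, db


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: ModelParameters, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, p in params:
            g = grads[name]
            m = self.m.setdefault(name, np.zeros_like(p))
            v = self.v.setdefault(name, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, lr):
        self.lr = lr

    def step(self, params: ModelParameters, grads: dict[str, np.ndarray]) -> None:
        for name, p in params:
            p -= self.lr * grads[name]


class LSTMClassifier:
    """Stacked-LSTM multi-class classifier with a scikit-learn estimator API.

    ``fit(X, y)`` expects an ``(n, 9)`` matrix of (already standardised)
    fiducial features and integer class codes; each row is consumed as a
    length-9 scalar sequence in canonical feature order.  ``fit`` accepts an
    optional ``init_params`` registry so federated clients can resume from
    broadcast global parameters.
    """

    def __init__(
        self,
        lstm_units: tuple[int, ...] = (64, 32, 16),
        dropout_rate: float = 0.2,
        n_classes: int = N_CLASSES,
        batch_size: int = 32,
        epochs: int = 15,
        learning_rate: float = 1e-3,
        optimizer: str = "adam",
        random_state: int = 0,
    ):
        self.lstm_units = tuple(lstm_units)
        self.dropout_rate = dropout_rate
        self.n_classes = n_classes
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "lstm_units": self.lstm_units, "dropout_rate": self.dropout_rate,
            "n_classes": self.n_classes, "batch_size": self.batch_size,
            "epochs": self.epochs, "learning_rate": self.learning_rate,
            "optimizer": self.optimizer, "random_state": self.random_state,
        }

    def set_params(self, **kw) -> "LSTMClassifier":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def spec(self) -> NetworkSpec:
        return NetworkSpec(
            lstm_units=self.lstm_units,
            dropout_rate=self.dropout_rate,
            n_classes=self.n_classes,
        )

    # -- core -------------------------------------------------------------
    def initialize(self, seed: int | None = None) -> "LSTMClassifier":
        """Create the parameter registry without training (round-0 model)."""
        self.params_ = initialize_parameters(
            self.spec, self.random_state if seed is None else seed
        )
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = N_FEATURES
        return self

    def get_weights(self) -> ModelParameters:
        return self.params_.copy()

    def set_weights(self, params: ModelParameters) -> "LSTMClassifier":
        if hasattr(self, "params_") and not self.params_.same_registry(params):
            raise ValueError("parameter registry mismatch")
        self.params_ = params.copy()
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = N_FEATURES
        return self

    def _validate_X(self, X) -> np.ndarray:
        X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(
                f"expected (n, {N_FEATURES}) feature matrix in canonical order, "
                f"got shape {X.shape}"
            )
        return X

    def _forward(self, X: np.ndarray, params: ModelParameters, *,
                 training: bool, rng: np.random.Generator | None = None):
        """Full forward pass. Returns (probs, caches) where caches hold what
        backward needs (None entries at inference)."""
        B = X.shape[0]
        seq = X.reshape(B, N_FEATURES, 1)
        layer_out = seq
        layer_caches = []
        drop = self.dropout_rate
        n_layers = len(self.lstm_units)
        for layer in range(n_layers):
            W = params[f"lstm{layer}.W"]
            U = params[f"lstm{layer}.U"]
            b = params[f"lstm{layer}.b"]
            ret_seq = layer < n_layers - 1
            out, cache = _lstm_forward(layer_out, W, U, b, ret_seq, cache=training)
            if training and drop > 0:
                mask = (rng.random(out.shape) >= drop) / (1.0 - drop)
                out = out * mask
            else:
                mask = None
            layer_caches.append((cache, mask, layer_out))
            layer_out = out
        logits = layer_out @ params["dense.W"] + params["dense.b"]
        probs = _softmax(logits)
        return probs, (layer_caches, layer_out)

    def _loss_and_grads(self, X, y, params, rng):
        probs, (layer_caches, dense_in) = self._forward(
            X, params, training=True, rng=rng
        )
        B = X.shape[0]
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(B), y] + eps))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {
            "dense.W": dense_in.T @ dlogits,
            "dense.b": dlogits.sum(axis=0),
        }
        dOut = dlogits @ params["dense.W"].T
        n_layers = len(self.lstm_units)
        for layer in range(n_layers - 1, -1, -1):
            cache, mask, _ = layer_caches[layer]
            if mask is not None:
                dOut = dOut * mask
            dX, dW, dU, db = _lstm_backward(
                dOut, cache, params[f"lstm{layer}.W"], params[f"lstm{layer}.U"],
                return_sequences=(layer < n_layers - 1),
            )
            grads[f"lstm{layer}.W"] = dW
            grads[f"lstm{layer}.U"] = dU
            grads[f"lstm{layer}.b"] = db
            dOut = dX
        return loss, grads

    def fit(self, X, y, init_params: ModelParameters | None = None,
            config: TrainingConfig | None = None) -> "LSTMClassifier":
        """Mini-batch training with sparse categorical cross-entropy.

        ``config`` overrides the estimator's batch/epoch/rate/optimizer/seed
        settings (used by the federated loop); ``init_params`` warm-starts
        from broadcast global parameters instead of a fresh initialisation.
        """
        X = self._validate_X(X)
        y = np.asarray(y, dtype=int).reshape(-1)
        if X.shape[0] == 0:
            raise ValueError("cannot fit on an empty dataset")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if y.min(initial=0) < 0 or y.max(initial=0) >= self.n_classes:
            raise ValueError("labels out of range")
        cfg = config or TrainingConfig(
            batch_size=self.batch_size, local_epochs=self.epochs,
            learning_rate=self.learning_rate, optimizer=self.optimizer,
            seed=self.random_state,
        )
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        params = (init_params.copy() if init_params is not None
                  else initialize_parameters(self.spec, cfg.seed))
        opt = (_Adam(cfg.learning_rate) if cfg.optimizer == "adam"
               else _SGD(cfg.learning_rate))

        n = X.shape[0]
        self.loss_history_ = []
        for _epoch in range(cfg.local_epochs):
            order = rng.permutation(n)
            losses, weights = [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads = self._loss_and_grads(X[idx], y[idx], params, rng)
                opt.step(params, grads)
                losses.append(loss)
                weights.append(len(idx))
            self.loss_history_.append(float(np.average(losses, weights=weights)))

        self.params_ = params
        self.final_loss_ = self.loss_history_[-1] if self.loss_history_ else None
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = N_FEATURES
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability matrix (n, n_classes); rows sum to 1."""
        X = self._validate_X(X)
        if not hasattr(self, "params_"):
            raise ValueError("estimator is not fitted")
        out = np.empty((X.shape[0], self.n_classes))
        chunk = 8192
        for start in range(0, X.shape[0], chunk):
            probs, _ = self._forward(
                X[start:start + chunk], self.params_, training=False
            )
            out[start:start + chunk] = probs
        return out

    def predict(self, X) -> np.ndarray:
        """Hard labels; ties broken toward the lowest class code."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def log_loss(self, X, y) -> float:
        """Mean sparse categorical cross-entropy on (X, y)."""
        p = self.predict_proba(X)
        y = np.asarray(y, dtype=int)
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-12)))


def build_network(
    spec: NetworkSpec | None = None, seed: int = 0
) -> tuple[LSTMClassifier, ModelParameters]:
    """Construct a classifier for ``spec`` with seeded initial parameters."""
    spec = spec or NetworkSpec()
    spec.validate()
    clf = LSTMClassifier(
        lstm_units=spec.lstm_units, dropout_rate=spec.dropout_rate,
        n_classes=spec.n_classes, random_state=seed,
    ).initialize(seed)
    return clf, clf.get_weights()


def count_trainable_parameters(model: LSTMClassifier | ModelParameters) -> int:
    """Exact count of trainable scalars."""
    params = model if isinstance(model, ModelParameters) else model.params_
    return params.size


def local_train(model: LSTMClassifier, shard, config: TrainingConfig):
    """Run one client's local training from the model's current parameters.

    ``shard`` is a ClientShard or an ``(X, y)`` pair; features must already
    be standardised.  Returns the updated :class:`ModelParameters` and the
    mean training loss of the final epoch (None when ``local_epochs == 0``).
    """
    if hasattr(shard, "data"):
        X, y = shard.data.values, shard.data.labels
    else:
        X, y = shard
    if len(X) == 0:
        raise ValueError("empty shard")
    start = model.get_weights()
    if config.local_epochs == 0:
        return start, None
    model.fit(X, y, init_params=start, config=config)
    return model.get_weights(), model.final_loss_
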