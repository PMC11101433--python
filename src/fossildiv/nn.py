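"""Sequence-to-sequence regressor: fossil features -> log-diversity.

A bidirectional LSTM stack reads the t x f feature matrix in both time
directions, an optional fully connected head mixes the per-bin states, and
a SoftPlus output keeps predicted log(x+1) diversity positive.  Training
minimises mean squared error on log(x+1)-transformed diversity with Adam
and early stopping on a validation split.  A dropout layer ahead of the
output stays active at inference (Monte Carlo dropout) to produce a
predictive ensemble; draws from several trained models can be pooled.

The network, its gradients and the optimiser are implemented directly in
NumPy; the backward pass is verified against finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "TrainingLog",
    "PredictionEnsemble",
    "LSTMRegressor",
    "build_model",
    "train",
    "predict_with_dropout",
    "save_checkpoint",
    "load_checkpoint",
]

_ALLOWED_LSTM_NODES = (32, 128)
_ALLOWED_DENSE_NODES = (32, 64)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class ModelConfig:
    """Architecture menu: LSTM stack depth/width, optional dense head,
    Monte Carlo dropout fraction."""

    n_lstm_layers: int = 1
    lstm_nodes: int = 32
    dense_nodes: tuple[int, ...] = ()
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.dense_nodes = tuple(self.dense_nodes)
        if self.n_lstm_layers not in (1, 2, 3, 4):
            raise ValueError("n_lstm_layers must be between 1 and 4")
        if self.lstm_nodes not in _ALLOWED_LSTM_NODES:
            raise ValueError(f"lstm_nodes must be one of {_ALLOWED_LSTM_NODES}")
        if len(self.dense_nodes) > 2 or any(
            n not in _ALLOWED_DENSE_NODES for n in self.dense_nodes
        ):
            raise ValueError(
                f"dense head: at most 2 hidden layers with nodes in {_ALLOWED_DENSE_NODES}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_lstm_layers": self.n_lstm_layers,
            "lstm_nodes": self.lstm_nodes,
            "dense_nodes": list(self.dense_nodes),
            "dropout": self.dropout,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            n_lstm_layers=d["n_lstm_layers"],
            lstm_nodes=d["lstm_nodes"],
            dense_nodes=tuple(d["dense_nodes"]),
            dropout=d["dropout"],
            seed=d["seed"],
        )


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 100
    validation_fraction: float = 0.2
    patience: int = 50
    max_epochs: int = 1000
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


class LSTMRegressor:
    """Bidirectional LSTM stack + dense head + SoftPlus output."""

    def __init__(self, config: ModelConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(config.seed)
        H = config.lstm_nodes
        d_in = n_features
        for layer in range(config.n_lstm_layers):
            for dr in ("f", "b"):
                self.params[f"W{layer}{dr}"] = self._glorot(rng, d_in, 4 * H)
                self.params[f"U{layer}{dr}"] = self._glorot(rng, H, 4 * H)
                bias = np.zeros(4 * H)
                bias[H:2 * H] = 1.0  # forget-gate bias init
                self.params[f"b{layer}{dr}"] = bias
            d_in = 2 * H
        for i, n in enumerate(config.dense_nodes):
            self.params[f"Wd{i}"] = self._glorot(rng, d_in, n)
            self.params[f"bd{i}"] = np.zeros(n)
            d_in = n
        self.params["Wo"] = self._glorot(rng, d_in, 1)
        self.params["bo"] = np.zeros(1)

    @staticmethod
    def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # ---- forward -----------------------------------------------------

    def _lstm_dir(self, x: np.ndarray, layer: int, dr: str):
        """One LSTM direction over the full sequence; returns outputs and
        the per-step cache needed for backprop."""
        B, T, _ = x.shape
        H = self.config.lstm_nodes
        W = self.params[f"W{layer}{dr}"]
        U = self.params[f"U{layer}{dr}"]
        b = self.params[f"b{layer}{dr}"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = x[:, t] @ W + h @ U + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        return hs, cache

    def _lstm_dir_backward(self, x: np.ndarray, dh_out: np.ndarray, cache,
                           layer: int, dr: str, grads: dict) -> np.ndarray:
        B, T, _ = x.shape
        H = self.config.lstm_nodes
        W = self.params[f"W{layer}{dr}"]
        U = self.params[f"U{layer}{dr}"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * H)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dh_out[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ W.T
            dh_next = dz @ U.T
        grads[f"W{layer}{dr}"] = dW
        grads[f"U{layer}{dr}"] = dU
        grads[f"b{layer}{dr}"] = db
        return dx

    def forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Full forward pass.  ``dropout_rng`` enables (inverted) dropout;
        pass None for a deterministic pass.  Returns (y, cache)."""
        x = np.asarray(x, float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.shape[2] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[2]}"
            )
        B, T, _ = x.shape
        layer_in = x
        lstm_caches = []
        for layer in range(self.config.n_lstm_layers):
            hf, cf = self._lstm_dir(layer_in, layer, "f")
            hb_rev, cb = self._lstm_dir(layer_in[:, ::-1], layer, "b")
            out = np.concatenate([hf, hb_rev[:, ::-1]], axis=2)
            lstm_caches.append((layer_in, cf, cb))
            layer_in = out

        flat = layer_in.reshape(B * T, -1)
        dense_cache = []
        for i_l in range(len(self.config.dense_nodes)):
            z = flat @ self.params[f"Wd{i_l}"] + self.params[f"bd{i_l}"]
            a = np.maximum(z, 0.0)
            dense_cache.append((flat, z))
            flat = a

        if dropout_rng is not None and self.config.dropout > 0.0:
            keep = 1.0 - self.config.dropout
            mask = (dropout_rng.random(flat.shape) < keep) / keep
        else:
            mask = None
        dropped = flat * mask if mask is not None else flat
        zo = dropped @ self.params["Wo"] + self.params["bo"]
        y = _softplus(zo).reshape(B, T)
        cache = (x, lstm_caches, dense_cache, dropped, mask, zo, B, T)
        return (y[0] if squeeze else y), cache

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given dL/dy."""
        x, lstm_caches, dense_cache, dropped, mask, zo, B, T = cache
        grads: dict[str, np.ndarray] = {}
        dzo = (np.asarray(dy).reshape(B * T, 1)) * _sigmoid(zo)
        grads["Wo"] = dropped.T @ dzo
        grads["bo"] = dzo.sum(axis=0)
        dflat = dzo @ self.params["Wo"].T
        if mask is not None:
            dflat = dflat * mask
        for i_l in range(len(self.config.dense_nodes) - 1, -1, -1):
            inp, z = dense_cache[i_l]
            dz = dflat * (z > 0.0)
            grads[f"Wd{i_l}"] = inp.T @ dz
            grads[f"bd{i_l}"] = dz.sum(axis=0)
            dflat = dz @ self.params[f"Wd{i_l}"].T

        H = self.config.lstm_nodes
        dlayer = dflat.reshape(B, T, -1)
        for layer in range(self.config.n_lstm_layers - 1, -1, -1):
            layer_in, cf, cb = lstm_caches[layer]
            dhf = dlayer[:, :, :H]
            dhb = dlayer[:, :, H:]
            dx_f = self._lstm_dir_backward(layer_in, dhf, cf, layer, "f", grads)
            dx_b = self._lstm_dir_backward(
                layer_in[:, ::-1], dhb[:, ::-1], cb, layer, "b", grads
            )
            dlayer = dx_f + dx_b[:, ::-1]
        return grads

    def predict(self, x: np.ndarray,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        y, _ = self.forward(x, dropout_rng=dropout_rng)
        return y

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()


def build_model(config: ModelConfig, n_features: int) -> LSTMRegressor:
    """Construct an untrained model (the t dimension is free: the network
    is applied per time step and recurrently, so any sequence length works)."""
    return LSTMRegressor(config, n_features)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if norm > max_norm:
        scale = max_norm / norm
        for k in grads:
            grads[k] *= scale


def train(model: LSTMRegressor, X: np.ndarray, y: np.ndarray,
          tcfg: TrainingConfig, rng: np.random.Generator) -> TrainingLog:
    """Fit on (N, T, F) normalized features and (N, T) log(x+1) diversity.

    A random validation split is held out; training stops once the
    validation MSE has not improved for ``patience`` epochs and the weights
    of the best validation epoch are restored.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 3 or X.shape[2] != model.n_features:
        raise ValueError("X must be (N, T, F) matching the model's feature count")
    if y.shape != X.shape[:2]:
        raise ValueError("y must be (N, T) matching X")
    N = X.shape[0]
    n_val = max(1, int(round(N * tcfg.validation_fraction)))
    perm = rng.permutation(N)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("validation split leaves no training data")
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    opt = _Adam(model.params, tcfg.learning_rate)
    log = TrainingLog()
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(tr_idx.size)
        ep_loss = 0.0
        for start in range(0, order.size, tcfg.batch_size):
            bi = order[start:start + tcfg.batch_size]
            xb, yb = Xtr[bi], ytr[bi]
            pred, cache = model.forward(xb, dropout_rng=rng)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            grads = model.backward(cache, 2.0 * err / err.size)
            _clip_grads(grads, tcfg.grad_clip)
            opt.step(model.params, grads)
            ep_loss += loss * bi.size
        log.train_loss.append(ep_loss / order.size)

        val_pred = model.predict(Xval)
        val_loss = float(np.mean((val_pred - yval) ** 2))
        log.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            log.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tcfg.patience:
                break
    model.set_weights(best_weights)
    return log


@dataclass
class PredictionEnsemble:
    """Pooled Monte Carlo-dropout draws with natural-scale summaries."""

    draws_log: np.ndarray  # (n_draws_total, T), log(x+1) scale

    def __post_init__(self) -> None:
        self.draws_log = np.atleast_2d(np.asarray(self.draws_log, float))

    @property
    def draws(self) -> np.ndarray:
        return np.expm1(self.draws_log)

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def lower(self) -> np.ndarray:
        return np.quantile(self.draws, 0.025, axis=0)

    @property
    def upper(self) -> np.ndarray:
        return np.quantile(self.draws, 0.975, axis=0)


def predict_with_dropout(models, features: np.ndarray, n_draws: int,
                         rng: np.random.Generator) -> PredictionEnsemble:
    """``n_draws`` stochastic forward passes per model, pooled.

    ``features`` is a normalized (T, F) matrix.  Raises when no model has
    an active dropout layer (there would be no uncertainty source).
    """
    if not isinstance(models, (list, tuple)):
        models = [models]
    if all(m.config.dropout == 0.0 for m in models) and (
        len(models) * n_draws > 1
    ):
        raise ValueError("dropout disabled in all models: no uncertainty source")
    draws = []
    for m in models:
        for _ in range(n_draws):
            draws.append(
                m.predict(features, dropout_rng=rng if m.config.dropout > 0 else None)
            )
    return PredictionEnsemble(np.asarray(draws))


def save_checkpoint(path, model: LSTMRegressor, scaler=None,
                    bin_edges: np.ndarray | None = None) -> None:
    """Single-file .npz bundle: weights + config + normalization metadata."""
    meta = {
        "config": model.config.to_dict(),
        "n_features": model.n_features,
        "scaler": scaler.to_dict() if scaler is not None else None,
        "bin_edges": list(map(float, bin_edges)) if bin_edges is not None else None,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_checkpoint(path):
    """Returns (model, scaler_or_None, bin_edges_or_None)."""
    from .features import FeatureScaler

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = LSTMRegressor(ModelConfig.from_dict(meta["config"]),
                              meta["n_features"])
        model.set_weights({k: data[k] for k in model.params})
    scaler = (FeatureScaler.from_dict(meta["scaler"])
              if meta.get("scaler") else None)
    edges = (np.asarray(meta["bin_edges"], float)
             if meta.get("bin_edges") else None)
    return model, scaler, edges
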