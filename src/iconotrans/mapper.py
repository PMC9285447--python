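"""Many-to-one recurrent mappings from phone-feature sequences to vectors.

A single masked LSTM layer reads the padded ``(15, F)`` feature matrix of a
word (padded positions carry the state forward unchanged, so predictions
depend only on the unmasked prefix) and a dense head maps the final hidden
state to the output space:

* regression head (visual/semantic targets): ReLU or linear activation,
  trained by maximizing mean cosine similarity with Adam;
* classification head (word classes): softmax activation, trained with
  categorical cross-entropy.

The whole model is implemented directly in NumPy: parameter count and batch
sizes in this pipeline are small, the implementation is self-contained and
bitwise reproducible from a seed, and the analytic backward pass is checked
against finite-difference gradients in the test suite.  Dropout follows the
variational convention: one input mask and one recurrent mask per sample,
shared across timesteps, active only during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MapperConfig",
    "MappingModel",
    "train_regressor",
    "train_classifier",
    "predict",
]

_EPS = 1e-7  # norm clamp in the cosine objective


@dataclass(frozen=True)
class MapperConfig:
    """Hyperparameters of one mapping model.

    Reference defaults for the three experiments: 500 hidden units for the
    visual mapping, 50 for the semantic one, 25 for the word-class
    classifier; dropout and recurrent dropout 0.2; Adam at learning rate
    0.01; one training epoch.
    """

    hidden_units: int = 500
    dropout: float = 0.2
    recurrent_dropout: float = 0.2
    learning_rate: float = 0.01
    epochs: int = 1
    batch_size: int = 32
    output_dim: int = 1
    output_activation: str = "relu"  # relu | linear | softmax
    loss: str = "negative_cosine"  # negative_cosine | categorical_cross_entropy
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_units < 1 or self.output_dim < 1:
            raise ValueError("hidden_units and output_dim must be positive")
        if not (0.0 <= self.dropout < 1.0 and 0.0 <= self.recurrent_dropout < 1.0):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.output_activation not in ("relu", "linear", "softmax"):
            raise ValueError(f"unknown activation {self.output_activation!r}")
        if self.loss == "categorical_cross_entropy":
            if self.output_activation != "softmax":
                raise ValueError("cross-entropy loss requires softmax activation")
        elif self.loss == "negative_cosine":
            if self.output_activation not in ("relu", "linear"):
                raise ValueError("cosine loss requires relu or linear activation")
        else:
            raise ValueError(f"unknown loss {self.loss!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


@dataclass
class MappingModel:
    """Trained LSTM + dense head; apply with :func:`predict`."""

    config: MapperConfig
    input_shape: tuple[int, int]
    params: dict[str, np.ndarray]
    history: list[dict[str, float]] = field(default_factory=list)
    final_train_metric: float | None = None

    def save(self, path) -> None:
        """Persist weights and config to an ``.npz`` checkpoint."""
        import json

        meta = json.dumps(
            {"config": self.config.__dict__, "input_shape": list(self.input_shape)}
        )
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "MappingModel":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            params = {k: data[k] for k in data.files if k != "_meta"}
        return cls(
            config=MapperConfig(**meta["config"]),
            input_shape=tuple(meta["input_shape"]),
            params=params,
        )


def _init_params(cfg: MapperConfig, F: int, rng: np.random.Generator):
    H, O = cfg.hidden_units, cfg.output_dim
    limit = np.sqrt(6.0 / (F + 4 * H))
    Wx = rng.uniform(-limit, limit, size=(F, 4 * H))
    Wh = np.concatenate([_orthogonal(rng, H) for _ in range(4)], axis=1)
    b = np.zeros(4 * H)
    b[H : 2 * H] = 1.0  # forget-gate bias
    lim_out = np.sqrt(6.0 / (H + O))
    Wy = rng.uniform(-lim_out, lim_out, size=(H, O))
    by = np.zeros(O)
    return {"Wx": Wx, "Wh": Wh, "b": b, "Wy": Wy, "by": by}


def _stack(pairs):
    X = np.stack([p[0].matrix for p in pairs])
    mask = np.stack([p[0].mask for p in pairs]).astype(float)
    Y = np.stack([np.asarray(p[1], dtype=float) for p in pairs])
    return X, mask, Y


def _forward(params, X, mask, drop_x=None, drop_h=None, cache=False):
    """Masked LSTM forward pass over the batch.

    ``X``: (B, T, F); ``mask``: (B, T) in {0,1}.  Masked positions leave the
    hidden and cell state untouched.  Returns the final hidden state (and,
    with ``cache=True``, the stored intermediates for BPTT).
    """
    B, T, F = X.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = [] if cache else None
    for t in range(T):
        xt = X[:, t, :]
        if drop_x is not None:
            xt = xt * drop_x
        hd = h * drop_h if drop_h is not None else h
        z = xt @ params["Wx"] + hd @ params["Wh"] + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_raw = f * c + i * g
        tanh_c = np.tanh(c_raw)
        h_raw = o * tanh_c
        m = mask[:, t][:, None]
        if cache:
            steps.append((xt, hd, i, f, g, o, c, c_raw, tanh_c, m))
        c = m * c_raw + (1.0 - m) * c
        h = m * h_raw + (1.0 - m) * h
    return (h, steps) if cache else h


def _backward(params, steps, dh_final, drop_h=None):
    """BPTT through the masked LSTM; returns parameter gradients."""
    H = params["Wh"].shape[0]
    grads = {
        "Wx": np.zeros_like(params["Wx"]),
        "Wh": np.zeros_like(params["Wh"]),
        "b": np.zeros_like(params["b"]),
    }
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for xt, hd, i, f, g, o, c_prev, c_raw, tanh_c, m in reversed(steps):
        dh_raw = dh * m
        dc_raw = dc * m
        dh_skip = dh * (1.0 - m)
        dc_skip = dc * (1.0 - m)
        do = dh_raw * tanh_c
        dc_raw = dc_raw + dh_raw * o * (1.0 - tanh_c**2)
        di = dc_raw * g
        df = dc_raw * c_prev
        dg = dc_raw * i
        dc = dc_raw * f + dc_skip
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        grads["Wx"] += xt.T @ dz
        grads["Wh"] += hd.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh_prev = dz @ params["Wh"].T
        if drop_h is not None:
            dh_prev = dh_prev * drop_h
        dh = dh_prev + dh_skip
    return grads


def _head(params, h, activation):
    z = h @ params["Wy"] + params["by"]
    if activation == "relu":
        return np.maximum(z, 0.0), z
    if activation == "softmax":
        return _softmax(z), z
    return z, z


def _cosine_loss_and_grad(y, targets):
    """Negative mean cosine similarity and its gradient w.r.t. ``y``."""
    ny = np.maximum(np.linalg.norm(y, axis=1), _EPS)
    nt = np.maximum(np.linalg.norm(targets, axis=1), _EPS)
    dots = (y * targets).sum(axis=1)
    cos = dots / (ny * nt)
    B = y.shape[0]
    dy = -(targets / (ny * nt)[:, None] - (cos / ny**2)[:, None] * y) / B
    return -cos.mean(), dy, cos


def _ce_loss_and_grad(probs, targets):
    B = probs.shape[0]
    eps = 1e-12
    loss = -(targets * np.log(probs + eps)).sum() / B
    dz = (probs - targets) / B  # gradient w.r.t. pre-softmax logits
    return loss, dz


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _train(pairs, cfg: MapperConfig) -> MappingModel:
    cfg.validate()
    if not pairs:
        raise ValueError("empty training set")
    X, mask, Y = _stack(pairs)
    n, T, F = X.shape
    if Y.shape[1] != cfg.output_dim:
        raise ValueError(
            f"targets have dimension {Y.shape[1]}, config says {cfg.output_dim}"
        )
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, F, rng)
    opt = _Adam(params, cfg.learning_rate)
    H = cfg.hidden_units
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss, total_metric, seen = 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, mb, yb = X[idx], mask[idx], Y[idx]
            B = len(idx)
            drop_x = drop_h = None
            if cfg.dropout > 0:
                drop_x = (rng.random((B, F)) >= cfg.dropout) / (1 - cfg.dropout)
            if cfg.recurrent_dropout > 0:
                drop_h = (rng.random((B, H)) >= cfg.recurrent_dropout) / (
                    1 - cfg.recurrent_dropout
                )
            h, steps = _forward(params, xb, mb, drop_x, drop_h, cache=True)
            out, z = _head(params, h, cfg.output_activation)
            if cfg.loss == "negative_cosine":
                loss, dy, cos = _cosine_loss_and_grad(out, yb)
                dz = dy * (z > 0) if cfg.output_activation == "relu" else dy
                metric = cos.mean()
            else:
                loss, dz = _ce_loss_and_grad(out, yb)
                metric = float(
                    (out.argmax(axis=1) == yb.argmax(axis=1)).mean()
                )
            grads = {"Wy": h.T @ dz, "by": dz.sum(axis=0)}
            dh = dz @ params["Wy"].T
            grads.update(_backward(params, steps, dh, drop_h))
            opt.step(params, grads)
            total_loss += loss * B
            total_metric += metric * B
            seen += B
        history.append(
            {"epoch": epoch, "loss": total_loss / seen, "metric": total_metric / seen}
        )
    model = MappingModel(
        config=cfg, input_shape=(T, F), params=params, history=history
    )
    # Final-parameter training metric, evaluated without dropout, so the
    # reported number matches an external recomputation from predictions.
    h = _forward(params, X, mask)
    out, _ = _head(params, h, cfg.output_activation)
    if cfg.loss == "negative_cosine":
        _, _, cos = _cosine_loss_and_grad(out, Y)
        model.final_train_metric = float(cos.mean())
    else:
        model.final_train_metric = float(
            (out.argmax(axis=1) == Y.argmax(axis=1)).mean()
        )
    return model


def train_regressor(pairs, cfg: MapperConfig) -> MappingModel:
    """Train a sequence-to-vector regressor with the cosine objective."""
    if cfg.loss != "negative_cosine":
        raise ValueError("train_regressor requires loss='negative_cosine'")
    return _train(pairs, cfg)


def train_classifier(pairs, cfg: MapperConfig) -> MappingModel:
    """Train a sequence-to-class softmax classifier with cross-entropy."""
    if cfg.loss != "categorical_cross_entropy":
        raise ValueError(
            "train_classifier requires loss='categorical_cross_entropy'"
        )
    return _train(pairs, cfg)


def predict(model: MappingModel, encoded_words, batch_size: int = 256) -> list[np.ndarray]:
    """Apply a trained model to encoded words (deterministic; no dropout)."""
    words = list(encoded_words)
    if not words:
        return []
    for w in words:
        if w.matrix.shape != model.input_shape:
            raise ValueError(
                f"input shape {w.matrix.shape} does not match model "
                f"{model.input_shape}"
            )
    out: list[np.ndarray] = []
    for start in range(0, len(words), batch_size):
        chunk = words[start : start + batch_size]
        X = np.stack([w.matrix for w in chunk])
        mask = np.stack([w.mask for w in chunk]).astype(float)
        h = _forward(model.params, X, mask)
        y, _ = _head(model.params, h, model.config.output_activation)
        out.extend(y)
    return out
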