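"""Convolutional binary classifier over 31-element pair feature vectors.

The network is five sequential convolutional blocks (conv width 3, 'same'
padding → ReLU → max pool width 2 stride 2, the pool skipped once the
spatial length reaches 1) with channel counts 512/1024/512/1024/1024,
followed by a fully connected output neuron producing a contact
probability.  Spatial lengths therefore run 31 → 15 → 7 → 3 → 1 → 1.

Implemented directly on NumPy (float32 training, float64 inference) with a
class-weighted binary cross-entropy loss and an Adam optimizer; all
randomness is drawn from the seed in :class:`ModelConfig`, so training is
bit-reproducible for a fixed input order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ContractError, TrainingError

DEFAULT_CHANNELS = (512, 1024, 512, 1024, 1024)
INPUT_SIZE = 31


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    channels: tuple[int, ...] = DEFAULT_CHANNELS
    kernel: int = 3
    pool: int = 2
    threshold: float = 0.5
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 5
    batch_size: int = 256
    class_weight_cap: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.channels):
            raise ConfigurationError("channel counts must be positive")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("decision threshold must lie in (0, 1)")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.kernel != 3:
            raise ConfigurationError("only kernel width 3 is supported")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class Metrics:
    acc: float
    precision: float
    recall: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int
    undefined: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Conv1d:
    """'Same'-padded width-3 convolution via an unfolded matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = (rng.standard_normal((c_out, c_in * kernel)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kernel = kernel
        self._cols: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def _unfold(self, x: np.ndarray) -> np.ndarray:
        n, c, L = x.shape
        pad = self.kernel // 2
        xp = np.zeros((n, c, L + 2 * pad), dtype=x.dtype)
        xp[:, :, pad : pad + L] = x
        # (n, L, c * kernel), windows along the spatial axis
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n, L, -1)

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        cols = self._unfold(x)
        self._cols = cols if keep else None
        self._in_shape = x.shape
        out = cols @ self.w.T.astype(x.dtype) + self.b.astype(x.dtype)
        return out.transpose(0, 2, 1)  # (n, c_out, L)

    def backward(self, dout: np.ndarray):
        n, c_out, L = dout.shape
        d = dout.transpose(0, 2, 1).reshape(n * L, c_out)
        cols = self._cols.reshape(n * L, -1)
        dw = d.T @ cols
        db = d.sum(axis=0)
        dcols = (d @ self.w).reshape(n, L, self._in_shape[1], self.kernel)
        pad = self.kernel // 2
        dxp = np.zeros(
            (n, self._in_shape[1], self._in_shape[2] + 2 * pad), dtype=dout.dtype
        )
        for t in range(self.kernel):
            dxp[:, :, t : t + L] += dcols[:, :, :, t].transpose(0, 2, 1)
        dx = dxp[:, :, pad : pad + self._in_shape[2]]
        return dx, [dw, db]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        mask = x > 0
        self._mask = mask if keep else None
        return x * mask

    def backward(self, dout: np.ndarray):
        return dout * self._mask, []


class _MaxPool:
    """Width-2 stride-2 max pool; a trailing odd element is dropped."""

    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n, c, L = x.shape
        half = L // 2
        trimmed = x[:, :, : 2 * half].reshape(n, c, half, 2)
        arg = trimmed.argmax(axis=3)
        if keep:
            self._arg = arg
            self._in_shape = (n, c, L)
        return np.take_along_axis(trimmed, arg[..., None], axis=3)[..., 0]

    def backward(self, dout: np.ndarray):
        n, c, L = self._in_shape
        half = L // 2
        dtr = np.zeros((n, c, half, 2), dtype=dout.dtype)
        np.put_along_axis(dtr, self._arg[..., None], dout[..., None], axis=3)
        dx = np.zeros((n, c, L), dtype=dout.dtype)
        dx[:, :, : 2 * half] = dtr.reshape(n, c, 2 * half)
        return dx, []


class _Flatten:
    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray):
        return dout.reshape(self._shape), []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_out, d_in)) * scale).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        self._x = x if keep else None
        return x @ self.w.T.astype(x.dtype) + self.b.astype(x.dtype)

    def backward(self, dout: np.ndarray):
        dw = dout.T @ self._x
        db = dout.sum(axis=0)
        return dout @ self.w, [dw, db]


class ContactCNN:
    """The convolutional network; holds layers and exposes forward/backward."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list = []
        c_in, length = 1, INPUT_SIZE
        for c_out in config.channels:
            layers.append(_Conv1d(c_in, c_out, config.kernel, rng))
            layers.append(_ReLU())
            if length >= config.pool:
                layers.append(_MaxPool())
                length //= config.pool
            c_in = c_out
        layers.append(_Flatten())
        layers.append(_Dense(c_in * length, 1, rng))
        self.layers = layers
        self.out_features = c_in * length

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        """x: (n, 31) → logits (n,)."""
        if x.ndim != 2 or x.shape[1] != INPUT_SIZE:
            raise ContractError(
                f"model accepts (n, {INPUT_SIZE}) inputs, got {x.shape}"
            )
        h = x[:, None, :]
        for layer in self.layers:
            h = layer.forward(h, keep=keep)
        return h[:, 0]

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        d = dlogits[:, None]
        for layer in reversed(self.layers):
            d, layer_grads = layer.backward(d)
            grads = layer_grads + grads
        return grads


@dataclasses.dataclass
class TrainedModel:
    config: ModelConfig
    network: ContactCNN
    training_log: list[dict]


def build_model(config: ModelConfig = ModelConfig()) -> ContactCNN:
    """Untrained network; same seed ⇒ identical initial parameters."""
    return ContactCNN(config)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float32) for p in params]

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g.astype(np.float32)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= lr_t * m / (np.sqrt(v) + eps)


class _SGD:
    def __init__(self, params, lr: float):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g.astype(np.float32)


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        x = vectors.astype(np.float32, copy=False)
    else:
        x = np.asarray([np.asarray(getattr(v, "values", v)) for v in vectors], np.float32)
    if x.ndim != 2 or x.shape[1] != INPUT_SIZE:
        raise ContractError(f"expected (n, {INPUT_SIZE}) feature matrix, got {x.shape}")
    return x


def train(
    vectors,
    labels: Sequence[int] | np.ndarray,
    config: ModelConfig = ModelConfig(),
    network: ContactCNN | None = None,
) -> TrainedModel:
    """Minimise class-weighted binary cross-entropy with Adam.

    The positive class is up-weighted by N_neg/N_pos (capped at
    ``class_weight_cap``) to counter the heavy negative imbalance of
    interhelical pair datasets.
    """
    x = _as_matrix(vectors)
    y = np.asarray(labels, dtype=np.float32)
    if y.shape != (x.shape[0],):
        raise ContractError("labels length does not match vectors")
    if x.shape[0] == 0:
        raise TrainingError("empty training set")
    n_pos = float((y == 1).sum())
    n_neg = float((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingError("training set must contain both classes")
    w_pos = min(config.class_weight_cap, n_neg / n_pos)

    net = network or ContactCNN(config)
    params = net.parameters()
    opt_cls = {"adam": _Adam, "sgd": _SGD}[config.optimizer]
    opt = opt_cls(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    log: list[dict] = []
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_loss, total_weight, correct = 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            logits = net.forward(xb)
            # numerically stable weighted BCE-with-logits
            wb = np.where(yb == 1, np.float32(w_pos), np.float32(1.0))
            zmax = np.maximum(logits, 0)
            loss_vec = zmax - logits * yb + np.log1p(np.exp(-np.abs(logits)))
            batch_w = wb.sum()
            total_loss += float((wb * loss_vec).sum())
            total_weight += float(batch_w)
            prob = 1.0 / (1.0 + np.exp(-logits))
            correct += int(((prob >= config.threshold) == (yb == 1)).sum())
            dlogits = (wb * (prob - yb) / batch_w).astype(np.float32)
            grads = net.backward(dlogits)
            opt.step(params, grads)
        log.append(
            {
                "epoch": epoch + 1,
                "loss": total_loss / total_weight,
                "train_acc": correct / n,
            }
        )
    return TrainedModel(config=config, network=net, training_log=log)


def predict(
    model: TrainedModel, vectors, threshold: float | None = None
) -> list[tuple[float, int]]:
    """(probability, label) per input vector; order preserved.

    Inference runs in float64 full-batch equivalents so the result is
    independent of batching.
    """
    x = _as_matrix(vectors).astype(np.float64)
    if x.shape[0] == 0:
        return []
    thr = model.config.threshold if threshold is None else threshold
    probs: list[float] = []
    for start in range(0, x.shape[0], 4096):
        logits = model.network.forward(x[start : start + 4096], keep=False)
        probs.extend(1.0 / (1.0 + np.exp(-logits)))
    return [(float(p), int(p >= thr)) for p in probs]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(
    predicted: Sequence[int] | np.ndarray, true: Sequence[int] | np.ndarray
) -> Metrics:
    """ACC / Precision / Recall / MCC from the confusion matrix.

    Any ratio with a zero denominator is reported as 0 and flagged in
    ``Metrics.undefined``.
    """
    yp = np.asarray(predicted, dtype=int)
    yt = np.asarray(true, dtype=int)
    if yp.shape != yt.shape or yp.ndim != 1 or yp.size == 0:
        raise ContractError("predicted and true label vectors must match and be non-empty")
    if not (np.isin(yp, (0, 1)).all() and np.isin(yt, (0, 1)).all()):
        raise ContractError("labels must be binary")
    tp = int(((yp == 1) & (yt == 1)).sum())
    fp = int(((yp == 1) & (yt == 0)).sum())
    tn = int(((yp == 0) & (yt == 0)).sum())
    fn = int(((yp == 0) & (yt == 1)).sum())
    undefined: list[str] = []
    acc = (tp + tn) / (tp + fp + tn + fn)
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    else:
        mcc, undefined = 0.0, undefined + ["mcc"]
    return Metrics(
        acc=float(acc),
        precision=float(precision),
        recall=float(recall),
        mcc=float(mcc),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        undefined=tuple(undefined),
    )


def kfold_split(
    protein_ids: Sequence[str], k: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Protein-level folds: seeded shuffle, sizes differing by at most 1."""
    unique = sorted(set(protein_ids))
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    if k > len(unique):
        raise ConfigurationError(f"k={k} exceeds the {len(unique)} proteins available")
    order = list(np.random.default_rng(seed).permutation(unique))
    folds = [list(f) for f in np.array_split(order, k)]
    return [
        (sorted(p for f in folds[:h] + folds[h + 1 :] for p in f), sorted(folds[h]))
        for h in range(k)
    ]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path: str | Path, model: TrainedModel) -> None:
    """Persist weights (npz) with the config and training log embedded."""
    arrays = {f"p{k}": p for k, p in enumerate(model.network.parameters())}
    np.savez(
        path,
        __config__=json.dumps(model.config.to_dict()),
        __log__=json.dumps(model.training_log),
        **arrays,
    )


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        log = json.loads(str(data["__log__"]))
        net = ContactCNN(config)
        for k, p in enumerate(net.parameters()):
            stored = data[f"p{k}"]
            if stored.shape != p.shape:
                raise ContractError("checkpoint incompatible with config")
            p[...] = stored
    return TrainedModel(config=config, network=net, training_log=log)


def write_training_log(path: str | Path, model: TrainedModel) -> None:
    with Path(path).open("w") as fh:
        fh.write("epoch\tloss\ttrain_acc\n")
        for rec in model.training_log:
            fh.write(f"{rec['epoch']}\t{rec['loss']:.6f}\t{rec['train_acc']:.6f}\n")
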