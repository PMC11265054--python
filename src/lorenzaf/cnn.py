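"""Compact convolutional classifier for 32x32 scattergram images.

The network is the smallest conventional stack with three convolution
stages: 3 x (3x3 same-padding convolution -> ReLU -> 2x2 max pooling),
flatten, one fully connected ReLU layer, and a single sigmoid output (AF
probability).  It is implemented directly on NumPy — im2col convolutions
lowered to BLAS matrix multiplies, hand-derived backward passes, Adam with
binary cross-entropy — which keeps the package dependency-light and makes
training bit-reproducible for a given seed on a given platform.

All tensors are float32 with layout (batch, channels, height, width).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .scattergram import LSImage, RasterSpec, images_to_array

__all__ = [
    "ModelConfig",
    "TrainingHistory",
    "CNNModel",
    "build_model",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
]

ImagesLike = Union[Sequence[LSImage], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Exactly three convolution stages; defaults are 16/32/64 filters with
    3x3 kernels and 2x2 max pooling, a 64-unit dense layer, Adam at
    learning rate 1e-3, batches of 128, 20 epochs (no early stopping: the
    epoch budget is fixed).
    """

    conv_filters: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: int = 64
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 20
    seed: int = 0
    balance_classes: bool = False

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("exactly three convolution stages are required")
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("conv_filters must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        if self.batch_size < 1 or self.dense_units < 1 or self.pool_size < 2:
            raise ValueError("invalid batch_size/dense_units/pool_size")
        object.__setattr__(self, "conv_filters", tuple(int(f) for f in self.conv_filters))


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy curves (length == epochs)."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# layer primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,C,H,W) -> (B*H*W, C*k*k) patch matrix with same padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (B,C,H,W,k,k) -> (B,H,W,C,k,k) -> (B*H*W, C*k*k)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(b * h * w, c * k * k)


def _conv_forward(x: np.ndarray, W: np.ndarray, bias: np.ndarray, k: int):
    b, c, h, w = x.shape
    cols = _im2col(x, k)
    out = cols @ W.T + bias
    return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2), cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, W: np.ndarray,
                   x_shape: tuple, k: int):
    b, c, h, w = x_shape
    dmat = dout.transpose(0, 2, 3, 1).reshape(b * h * w, -1)
    dW = dmat.T @ cols
    db = dmat.sum(axis=0)
    dcols = dmat @ W                              # (B*H*W, C*k*k)
    dcols = dcols.reshape(b, h, w, c, k, k)
    p = k // 2
    dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
    for dy in range(k):
        for dx in range(k):
            dxp[:, :, dy:dy + h, dx:dx + w] += dcols[:, :, :, :, dy, dx].transpose(0, 3, 1, 2)
    return dxp[:, :, p:p + h, p:p + w], dW, db


def _pool_forward(x: np.ndarray, s: int):
    b, c, h, w = x.shape
    h2, w2 = h // s, w // s
    xr = x[:, :, :h2 * s, :w2 * s].reshape(b, c, h2, s, w2, s)
    xr = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 3, 5)).reshape(b, c, h2, w2, s * s)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, x_shape: tuple, s: int):
    b, c, h, w = x_shape
    h2, w2 = h // s, w // s
    dxr = np.zeros((b, c, h2, w2, s * s), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(b, c, h2, w2, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2 * s, w2 * s)
    if h2 * s != h or w2 * s != w:
        dx = np.pad(dx, ((0, 0), (0, 0), (0, h - h2 * s), (0, w - w2 * s)))
    return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class CNNModel:
    """Model handle: parameters + config + the raster geometry it expects."""

    def __init__(self, cfg: ModelConfig, raster_spec: Optional[RasterSpec] = None,
                 grid_size: Optional[int] = None):
        self.cfg = cfg
        self.raster_spec = raster_spec if raster_spec is not None else RasterSpec()
        g = grid_size if grid_size is not None else self.raster_spec.grid_size
        s, k = cfg.pool_size, cfg.kernel_size
        g1, g2, g3 = g // s, g // s // s, g // s // s // s
        if g3 < 1:
            raise ValueError(f"grid size {g} too small for three {s}x{s} poolings")
        f1, f2, f3 = cfg.conv_filters
        self.grid_size = g
        self.flat_dim = f3 * g3 * g3
        rng = np.random.default_rng(cfg.seed)

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

        self.params: dict[str, np.ndarray] = {
            "W1": he((f1, 1 * k * k), 1 * k * k), "b1": np.zeros(f1, np.float32),
            "W2": he((f2, f1 * k * k), f1 * k * k), "b2": np.zeros(f2, np.float32),
            "W3": he((f3, f2 * k * k), f2 * k * k), "b3": np.zeros(f3, np.float32),
            "W4": he((cfg.dense_units, self.flat_dim), self.flat_dim),
            "b4": np.zeros(cfg.dense_units, np.float32),
            "W5": he((1, cfg.dense_units), cfg.dense_units), "b5": np.zeros(1, np.float32),
        }
        self._adam_m = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_v = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward ---------------------------------------------------------
    def _forward(self, x: np.ndarray, want_cache: bool = False):
        cfg, P = self.cfg, self.params
        k, s = cfg.kernel_size, cfg.pool_size
        cache: dict = {"x": x}
        a = x
        for layer in (1, 2, 3):
            z, cols = _conv_forward(a, P[f"W{layer}"], P[f"b{layer}"], k)
            r = np.maximum(z, 0.0)
            p_out, idx = _pool_forward(r, s)
            if want_cache:
                cache[f"cols{layer}"] = cols
                cache[f"z{layer}"] = z
                cache[f"r_shape{layer}"] = r.shape
                cache[f"idx{layer}"] = idx
                cache[f"in_shape{layer}"] = a.shape
            a = p_out
        flat = a.reshape(a.shape[0], -1)
        h = flat @ P["W4"].T + P["b4"]
        hr = np.maximum(h, 0.0)
        logits = (hr @ P["W5"].T + P["b5"])[:, 0]
        if want_cache:
            cache.update(flat=flat, h=h, hr=hr, pooled_shape=a.shape)
            return logits, cache
        return logits

    # -- backward --------------------------------------------------------
    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg, P = self.cfg, self.params
        k, s = cfg.kernel_size, cfg.pool_size
        grads: dict[str, np.ndarray] = {}
        dlog = dlogits[:, None].astype(np.float32)
        grads["W5"] = dlog.T @ cache["hr"]
        grads["b5"] = dlog.sum(axis=0)
        dhr = dlog @ P["W5"]
        dh = dhr * (cache["h"] > 0)
        grads["W4"] = dh.T @ cache["flat"]
        grads["b4"] = dh.sum(axis=0)
        dflat = dh @ P["W4"]
        da = dflat.reshape(cache["pooled_shape"])
        for layer in (3, 2, 1):
            dr = _pool_backward(da, cache[f"idx{layer}"], cache[f"r_shape{layer}"], s)
            dz = dr * (cache[f"z{layer}"] > 0)
            da, dW, db = _conv_backward(dz, cache[f"cols{layer}"], P[f"W{layer}"],
                                        cache[f"in_shape{layer}"], k)
            grads[f"W{layer}"] = dW
            grads[f"b{layer}"] = db
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        lr_t = cfg.learning_rate * np.sqrt(1 - b2 ** self._adam_t) / (1 - b1 ** self._adam_t)
        for n, g in grads.items():
            g = g.astype(np.float32)
            m = self._adam_m[n] = b1 * self._adam_m[n] + (1 - b1) * g
            v = self._adam_v[n] = b2 * self._adam_v[n] + (1 - b2) * g * g
            self.params[n] -= np.float32(lr_t) * m / (np.sqrt(v) + eps)


def build_model(cfg: ModelConfig, raster_spec: Optional[RasterSpec] = None) -> CNNModel:
    """Construct an untrained model with seeded (He) initialization."""
    return CNNModel(cfg, raster_spec)


def _coerce_xy(images: ImagesLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(images, tuple) and len(images) == 2 and isinstance(images[0], np.ndarray):
        X, y = images
        return X.astype(np.float32), y.astype(np.float32)
    return images_to_array(images)


def _bce(logits: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None) -> float:
    # log(1+e^-|z|) form, numerically stable
    per = np.logaddexp(0.0, -np.abs(logits)) + np.maximum(logits, 0.0) - logits * y
    if w is not None:
        return float(np.average(per, weights=w))
    return float(per.mean())


def train(model: CNNModel, train_images: ImagesLike, val_images: ImagesLike,
          cfg: Optional[ModelConfig] = None) -> tuple[CNNModel, TrainingHistory]:
    """Train in place for exactly ``cfg.epochs`` epochs.

    Both classes must be present in the training set.  The history holds
    one entry per epoch: mean minibatch training loss/accuracy and full
    validation loss/accuracy.
    """
    cfg = cfg if cfg is not None else model.cfg
    Xtr, ytr = _coerce_xy(train_images)
    Xva, yva = _coerce_xy(val_images)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("train and validation sets must be non-empty")
    if len(np.unique(ytr)) < 2:
        raise ValueError("training set contains a single class; need both AF and non-AF")

    weights = None
    if cfg.balance_classes:
        pos = float(ytr.mean())
        w_pos, w_neg = 0.5 / max(pos, 1e-9), 0.5 / max(1 - pos, 1e-9)
        weights = np.where(ytr == 1.0, w_pos, w_neg).astype(np.float32)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7261696E]))
    history = TrainingHistory()
    n = len(Xtr)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, accs, counts = [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            logits, cache = model._forward(xb, want_cache=True)
            p = _sigmoid(logits)
            if weights is None:
                dlogits = (p - yb) / len(yb)
            else:
                wb = weights[idx]
                dlogits = wb * (p - yb) / wb.sum()
            grads = model._backward(dlogits, cache)
            model._adam_step(grads)
            losses.append(_bce(logits, yb, None if weights is None else weights[idx]))
            accs.append(float(((p >= 0.5) == (yb == 1.0)).mean()))
            counts.append(len(yb))
        w = np.asarray(counts, dtype=float)
        history.train_loss.append(float(np.average(losses, weights=w)))
        history.train_accuracy.append(float(np.average(accs, weights=w)))
        val_logits = _predict_logits(model, Xva)
        history.val_loss.append(_bce(val_logits, yva))
        history.val_accuracy.append(float(((val_logits >= 0.0) == (yva == 1.0)).mean()))
        if not np.isfinite(history.train_loss[-1]):
            raise FloatingPointError("training loss diverged to non-finite value")
    return model, history


def _predict_logits(model: CNNModel, X: np.ndarray, chunk: int = 512) -> np.ndarray:
    outs = [model._forward(X[s:s + chunk]) for s in range(0, len(X), chunk)]
    return np.concatenate(outs) if outs else np.zeros(0, dtype=np.float32)


def predict_proba(model: CNNModel, images: ImagesLike) -> np.ndarray:
    """AF probability in [0, 1] for each image (empty input -> empty)."""
    if isinstance(images, tuple):
        X = images[0].astype(np.float32)
    elif isinstance(images, np.ndarray):
        X = images.astype(np.float32)
        if X.ndim == 3:
            X = X[:, None]
    else:
        X, _ = images_to_array(images)
    if len(X) == 0:
        return np.zeros(0, dtype=np.float32)
    return _sigmoid(_predict_logits(model, X))


def save_model(model: CNNModel, path: str | Path) -> None:
    """Persist parameters plus ModelConfig and RasterSpec (self-describing)."""
    path = Path(path)
    meta = {
        "model_config": asdict(model.cfg),
        "raster_spec": asdict(model.raster_spec),
        "grid_size": model.grid_size,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_model(path: str | Path) -> CNNModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        alt = path.with_suffix(path.suffix + ".npz")
        if alt.exists():
            path = alt
        else:
            raise FileNotFoundError(f"no model file at {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        mc = meta["model_config"]
        mc["conv_filters"] = tuple(mc["conv_filters"])
        cfg = ModelConfig(**mc)
        spec = RasterSpec(**meta["raster_spec"])
        model = CNNModel(cfg, spec, grid_size=meta["grid_size"])
        for name in model.params:
            model.params[name] = data[name].astype(np.float32)
    return model
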