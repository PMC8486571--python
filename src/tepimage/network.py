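"""A small deterministic convolutional binary classifier, in pure numpy.

Architecture (10 layers, 8 hidden): two valid-mode 2-D convolutions with
four 3x3 filters each and tanh activation, a flatten layer, four dense
relu layers with strictly decreasing widths, dropout after the first two
dense layers, and a single sigmoid output unit.  Training minimizes
class-weighted binary cross-entropy with the adadelta update rule
(accumulated squared gradients and squared updates with decay ``rho``),
reshuffling the training order each epoch from a seeded stream.

Everything — initialization, dropout masks, shuffling — is driven by
explicit seeds, so two runs with the same configuration are bit-identical
on the same platform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "ConvNet",
    "class_weights",
    "build_network",
    "train",
    "predict_scores",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    The layer counts are fixed by the design (2 conv, 4 dense, 2 dropout);
    only widths, dropout rates and the seed vary.
    """

    conv_filters: int = 4
    kernel_size: int = 3
    dense_units: tuple[int, ...] = (256, 64, 16, 4)
    dropout_rates: tuple[float, float] = (0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dense_units) != 4:
            raise ValueError("exactly 4 dense hidden layers are required")
        if any(u <= 0 for u in self.dense_units):
            raise ValueError("dense_units must be positive")
        if not all(a > b for a, b in zip(self.dense_units, self.dense_units[1:])):
            raise ValueError("dense_units must be strictly decreasing")
        if len(self.dropout_rates) != 2:
            raise ValueError("exactly 2 dropout layers are required")
        if not all(0 <= r < 1 for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1.0
    rho: float = 0.95
    epsilon: float = 1e-6
    positive_class_scale: float = 1.0
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.positive_class_scale <= 0:
            raise ValueError("positive_class_scale must be > 0")


def class_weights(labels, positive_class_scale: float = 1.0) -> dict[int, float]:
    """Frequency-proportional class weights ``w_c = N / (2 n_c)``.

    The positive-class weight is additionally multiplied by
    ``positive_class_scale`` (1.06 reproduces the ovarian-cancer setting).
    """
    if positive_class_scale <= 0:
        raise ValueError("positive_class_scale must be > 0")
    y = np.asarray(labels).astype(int)
    n = len(y)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    return {
        0: n / (2.0 * n_neg),
        1: n / (2.0 * n_pos) * positive_class_scale,
    }


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N, H-k+1, W-k+1, C*k*k) patch matrix."""
    sw = sliding_window_view(x, (k, k), axis=(1, 2))  # (N,OH,OW,C,k,k)
    n, oh, ow = sw.shape[:3]
    return np.ascontiguousarray(sw).reshape(n, oh, ow, -1)


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Scatter-add patch gradients back to the (N,H,W,C) input."""
    n, h, w, c = shape
    oh, ow = h - k + 1, w - k + 1
    d = dcols.reshape(n, oh, ow, c, k, k)
    dx = np.zeros(shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, i : i + oh, j : j + ow, :] += d[:, :, :, :, i, j]
    return dx


class ConvNet:
    """The classifier: parameters, forward pass, gradients, adadelta state."""

    def __init__(self, input_height: int, input_width: int, spec: NetworkSpec):
        k, f = spec.kernel_size, spec.conv_filters
        oh1, ow1 = input_height - k + 1, input_width - k + 1
        oh2, ow2 = oh1 - k + 1, ow1 - k + 1
        if min(oh1, ow1, oh2, ow2) < 1:
            raise ValueError(
                f"input {input_height}x{input_width} is too small for two "
                f"valid-mode {k}x{k} convolutions"
            )
        self.spec = spec
        self.input_shape = (input_height, input_width)
        self._conv_out = (oh2, ow2)
        flat = oh2 * ow2 * f

        rng = np.random.default_rng(spec.seed)

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        self.params: dict[str, np.ndarray] = {}
        self.params["K1"] = glorot((k * k * 1, f), k * k * 1, k * k * f)
        self.params["bK1"] = np.zeros(f)
        self.params["K2"] = glorot((k * k * f, f), k * k * f, k * k * f)
        self.params["bK2"] = np.zeros(f)
        widths = [flat, *spec.dense_units, 1]
        for i, (din, dout) in enumerate(zip(widths, widths[1:]), start=1):
            self.params[f"W{i}"] = glorot((din, dout), din, dout)
            self.params[f"b{i}"] = np.zeros(dout)
        self._opt_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- introspection ------------------------------------------------------

    @property
    def layer_names(self) -> list[str]:
        """Layer sequence, input to output (flatten included)."""
        return [
            "conv2d", "conv2d", "flatten",
            "dense", "dropout", "dense", "dropout", "dense", "dense",
            "dense_output",
        ]

    @property
    def hidden_layer_names(self) -> list[str]:
        return [
            n for n in self.layer_names if n in ("conv2d", "dense", "dropout")
        ]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool = False, rng=None):
        """Forward pass; returns scores and, in training mode, a cache."""
        spec = self.spec
        k = spec.kernel_size
        x = x[..., None] if x.ndim == 3 else x  # (N,H,W,1)
        cache: dict = {"x": x}

        cols1 = _im2col(x, k)
        z1 = cols1 @ self.params["K1"] + self.params["bK1"]
        a1 = np.tanh(z1)
        cols2 = _im2col(a1, k)
        z2 = cols2 @ self.params["K2"] + self.params["bK2"]
        a2 = np.tanh(z2)
        h = a2.reshape(len(x), -1)
        cache.update(cols1=cols1, a1=a1, cols2=cols2, a2=a2, flat=h)

        drop_after = {1: spec.dropout_rates[0], 2: spec.dropout_rates[1]}
        for i in range(1, 5):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            a = np.maximum(z, 0.0)
            cache[f"z{i}"] = z
            cache[f"in{i}"] = h
            if i in drop_after and train and drop_after[i] > 0:
                rate = drop_after[i]
                mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
                a = a * mask
                cache[f"mask{i}"] = mask
            h = a
        z_out = h @ self.params["W5"] + self.params["b5"]
        cache["in5"] = h
        p = _sigmoid(z_out)[:, 0]
        return p, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-sample scores in [0, 1]; dropout inactive."""
        x = np.asarray(x, dtype=float)
        if x.shape[1:3] != self.input_shape:
            raise ValueError(
                f"image shape {x.shape[1:3]} does not match model input "
                f"{self.input_shape}"
            )
        p, _ = self._forward(x, train=False)
        return p

    def loss(self, x, y, sample_weights) -> float:
        """Mean class-weighted binary cross-entropy of current predictions."""
        p = self.predict(np.asarray(x, dtype=float))
        return _weighted_bce(p, np.asarray(y, float), np.asarray(sample_weights))

    def loss_and_grads(self, x, y, sample_weights, train=False, rng=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.asarray(sample_weights, dtype=float)
        n = len(x)
        p, cache = self._forward(x, train=train, rng=rng)
        loss = _weighted_bce(p, y, w)
        grads: dict[str, np.ndarray] = {}

        dz = (w * (p - y) / n)[:, None]  # d loss / d z_out
        grads["W5"] = cache["in5"].T @ dz
        grads["b5"] = dz.sum(axis=0)
        dh = dz @ self.params["W5"].T
        for i in range(4, 0, -1):
            mask = cache.get(f"mask{i}")
            if mask is not None:
                dh = dh * mask
            dzi = dh * (cache[f"z{i}"] > 0)
            grads[f"W{i}"] = cache[f"in{i}"].T @ dzi
            grads[f"b{i}"] = dzi.sum(axis=0)
            dh = dzi @ self.params[f"W{i}"].T

        k = self.spec.kernel_size
        oh2, ow2 = self._conv_out
        dz2 = dh.reshape(len(x), oh2, ow2, -1) * (1.0 - cache["a2"] ** 2)
        grads["K2"] = np.tensordot(cache["cols2"], dz2, axes=([0, 1, 2], [0, 1, 2]))
        grads["bK2"] = dz2.sum(axis=(0, 1, 2))
        dcols2 = dz2 @ self.params["K2"].T
        da1 = _col2im(dcols2, cache["a1"].shape, k)
        dz1 = da1 * (1.0 - cache["a1"] ** 2)
        grads["K1"] = np.tensordot(cache["cols1"], dz1, axes=([0, 1, 2], [0, 1, 2]))
        grads["bK1"] = dz1.sum(axis=(0, 1, 2))
        return loss, grads

    # -- adadelta -----------------------------------------------------------

    def apply_adadelta(self, grads, cfg: TrainConfig) -> None:
        rho, eps, lr = cfg.rho, cfg.epsilon, cfg.learning_rate
        for name, g in grads.items():
            if name not in self._opt_state:
                self._opt_state[name] = (np.zeros_like(g), np.zeros_like(g))
            eg, edx = self._opt_state[name]
            eg = rho * eg + (1 - rho) * g**2
            dx = -np.sqrt(edx + eps) / np.sqrt(eg + eps) * g
            edx = rho * edx + (1 - rho) * dx**2
            self._opt_state[name] = (eg, edx)
            self.params[name] += lr * dx


def _weighted_bce(p, y, w) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.mean(-w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def build_network(
    input_height: int, input_width: int, spec: NetworkSpec | None = None
) -> ConvNet:
    """Construct the classifier for a given image size; seeded initialization."""
    spec = spec or NetworkSpec()
    if min(input_height, input_width) < spec.kernel_size:
        raise ValueError(
            f"input {input_height}x{input_width} is smaller than the "
            f"{spec.kernel_size}x{spec.kernel_size} kernel"
        )
    model = ConvNet(input_height, input_width, spec)
    logger.info(
        "build_network: %dx%d input, %d trainable parameters",
        input_height, input_width, model.n_params,
    )
    return model


def _reinitialize(model: ConvNet, attempt: int) -> None:
    """Reset weights and optimizer state from a deterministically offset seed."""
    spec = model.spec
    new_seed = int((spec.seed + 0x5EED + attempt) % (2**31))
    fresh = ConvNet(
        *model.input_shape,
        NetworkSpec(
            conv_filters=spec.conv_filters,
            kernel_size=spec.kernel_size,
            dense_units=spec.dense_units,
            dropout_rates=spec.dropout_rates,
            seed=new_seed,
        ),
    )
    model.params = fresh.params
    model._opt_state = {}


def train(
    model: ConvNet,
    images: np.ndarray,
    labels,
    weights: dict[int, float],
    cfg: TrainConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    max_restarts: int = 2,
) -> dict[str, list[float]]:
    """Fit the model; returns a per-epoch history (loss, optional val_loss).

    Each sample's loss term is multiplied by its class weight; the training
    order is reshuffled every epoch from the seeded stream.

    The narrow 4-unit bottleneck can die entirely (all ReLUs off), leaving a
    constant output that gradient descent cannot escape.  When the trained
    model's predictions are constant to within 1e-6, training restarts from
    a deterministically reseeded initialization (at most ``max_restarts``
    times); the restart count is recorded in the history.
    """
    x = np.asarray(images, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one sample per class")
    w = np.where(y == 1, weights[1], weights[0])

    val_w = None
    if validation is not None:
        xv = np.asarray(validation[0], dtype=float)
        yv = np.asarray(validation[1], dtype=float)
        val_w = np.where(yv == 1, weights[1], weights[0])

    n = len(x)
    for attempt in range(max_restarts + 1):
        ss = np.random.SeedSequence((cfg.seed, attempt))
        shuffle_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        history: dict = {"loss": []}
        if validation is not None:
            history["val_loss"] = []
        order = np.arange(n)
        for epoch in range(cfg.epochs):
            if cfg.shuffle_each_epoch:
                order = shuffle_rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads = model.loss_and_grads(
                    x[idx], y[idx], w[idx], train=True, rng=drop_rng
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"batch starting at {start} (loss={loss})"
                    )
                model.apply_adadelta(grads, cfg)
                epoch_losses.append(loss)
            history["loss"].append(float(np.mean(epoch_losses)))
            if validation is not None:
                history["val_loss"].append(
                    _weighted_bce(model.predict(xv), yv, val_w)
                )
        history["restarts"] = attempt
        p = model.predict(x)
        if p.max() - p.min() >= 1e-6 or attempt == max_restarts:
            if attempt:
                logger.warning(
                    "train: recovered from constant-output collapse after "
                    "%d restart(s)", attempt,
                )
            return history
        logger.warning(
            "train: constant-output collapse detected (all predictions "
            "%.6f); reinitializing", float(p[0]),
        )
        _reinitialize(model, attempt)
    raise AssertionError("unreachable")


def predict_scores(model: ConvNet, images: np.ndarray) -> np.ndarray:
    """Scores in [0, 1], one per sample; independent of batch composition."""
    return model.predict(np.asarray(images, dtype=float))


def save_model(model: ConvNet, path) -> None:
    """Persist weights (npz) plus a JSON sidecar of the architecture."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    sidecar = {
        "input_shape": list(model.input_shape),
        "spec": asdict(model.spec),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> ConvNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    sd = sidecar["spec"]
    sd["dense_units"] = tuple(sd["dense_units"])
    sd["dropout_rates"] = tuple(sd["dropout_rates"])
    spec = NetworkSpec(**sd)
    model = ConvNet(*sidecar["input_shape"], spec)
    with np.load(path.with_suffix(".npz")) as data:
        for name in model.params:
            model.params[name] = data[name]
    return model
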