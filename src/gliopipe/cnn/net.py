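"""Trainable network instantiated from an :class:`ArchitectureSpec`.

A small, self-contained numpy engine sufficient for the compact 30x30
grayscale models: valid stride-1 convolution via im2col, 2x2 ceiling
max-pooling, inverted dropout, dense layers with ReLU, a softmax
cross-entropy head, and Adam.  Gradients are exact (verified against
numerical differentiation in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .arch import ArchitectureSpec

__all__ = ["TrainConfig", "Network", "train", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 100
    epochs: int = 8
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    loss: str = "categorical_crossentropy"
    #: fraction of the training set held out for per-epoch validation
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.loss != "categorical_crossentropy":
            raise ValueError("only categorical cross-entropy is supported")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, OH, OW, k*k*C) patches in (k, k, C) order."""
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # N, OH, OW, C, k, k
    win = win.transpose(0, 1, 2, 4, 5, 3)  # N, OH, OW, k, k, C
    n, oh, ow = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, oh, ow, -1)


class Network:
    """Forward/backward implementation of one architecture spec."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        # parameter shapes follow the spec's shape chain
        shape = spec.layers[0].output_shape
        for layer in spec.layers:
            if layer.kind == "conv":
                k, f = layer.config["kernel"], layer.config["filters"]
                cin = shape[2]
                std = np.sqrt(2.0 / (k * k * cin))
                self.params[f"{layer.name}/W"] = rng.normal(0, std, (k, k, cin, f))
                self.params[f"{layer.name}/b"] = np.zeros(f)
            elif layer.kind == "dense":
                units = layer.config["units"]
                std = np.sqrt(2.0 / shape[0])
                self.params[f"{layer.name}/W"] = rng.normal(0, std, (shape[0], units))
                self.params[f"{layer.name}/b"] = np.zeros(units)
            shape = layer.output_shape

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Return logits and the per-layer caches needed for backprop."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        expected = self.spec.layers[0].output_shape
        if x.shape[1:] != expected:
            raise ValueError(f"input shape {x.shape[1:]} does not match {expected}")
        caches = []
        out = x
        last = len(self.spec.layers) - 1
        for li, layer in enumerate(self.spec.layers):
            if layer.kind == "input":
                caches.append(None)
            elif layer.kind == "conv":
                k = layer.config["kernel"]
                W = self.params[f"{layer.name}/W"]
                b = self.params[f"{layer.name}/b"]
                col = _im2col(out, k)
                pre = col @ W.reshape(-1, W.shape[-1]) + b
                post = np.maximum(pre, 0.0)
                caches.append((col, out.shape, pre > 0))
                out = post
            elif layer.kind == "maxpool":
                p = layer.config["pool"]
                n, h, w, c = out.shape
                ph, pw = (-h) % p, (-w) % p
                xp = np.pad(
                    out, ((0, 0), (0, ph), (0, pw), (0, 0)),
                    constant_values=-np.inf,
                )
                oh, ow = xp.shape[1] // p, xp.shape[2] // p
                win = xp.reshape(n, oh, p, ow, p, c).transpose(0, 1, 3, 5, 2, 4)
                win = win.reshape(n, oh, ow, c, p * p)
                idx = np.argmax(win, axis=-1)
                out_new = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
                caches.append((idx, (n, h, w, c), p))
                out = out_new.transpose(0, 1, 2, 3)
            elif layer.kind == "dropout":
                rate = layer.config["rate"]
                if train and rate > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an RNG for dropout")
                    keep = rng.random(out.shape) >= rate
                    out = out * keep / (1.0 - rate)
                    caches.append(keep)
                else:
                    caches.append(None)
            elif layer.kind == "flatten":
                caches.append(out.shape)
                out = out.reshape(out.shape[0], -1)
            elif layer.kind == "dense":
                W = self.params[f"{layer.name}/W"]
                b = self.params[f"{layer.name}/b"]
                pre = out @ W + b
                if li == last:  # softmax head: keep logits
                    caches.append((out, None))
                    out = pre
                else:
                    caches.append((out, pre > 0))
                    out = np.maximum(pre, 0.0)
        return out, caches

    # -- backward --------------------------------------------------------

    def backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        d = dlogits
        last = len(self.spec.layers) - 1
        for li in range(last, -1, -1):
            layer = self.spec.layers[li]
            cache = caches[li]
            if layer.kind == "input":
                continue
            if layer.kind == "dense":
                x_in, relu_mask = cache
                if relu_mask is not None:
                    d = d * relu_mask
                W = self.params[f"{layer.name}/W"]
                grads[f"{layer.name}/W"] = x_in.T @ d
                grads[f"{layer.name}/b"] = d.sum(axis=0)
                d = d @ W.T
            elif layer.kind == "flatten":
                d = d.reshape(cache)
            elif layer.kind == "dropout":
                if cache is not None:
                    d = d * cache / (1.0 - layer.config["rate"])
            elif layer.kind == "maxpool":
                idx, in_shape, p = cache
                n, h, w, c = in_shape
                oh, ow = idx.shape[1], idx.shape[2]
                dwin = np.zeros((n, oh, ow, c, p * p))
                np.put_along_axis(dwin, idx[..., None], d[..., None], axis=-1)
                dwin = dwin.reshape(n, oh, ow, c, p, p).transpose(0, 1, 4, 2, 5, 3)
                dxp = dwin.reshape(n, oh * p, ow * p, c)
                d = dxp[:, :h, :w, :]
            elif layer.kind == "conv":
                col, in_shape, relu_mask = cache
                d = d * relu_mask
                k = layer.config["kernel"]
                W = self.params[f"{layer.name}/W"]
                f = W.shape[-1]
                n, oh, ow = d.shape[:3]
                dflat = d.reshape(-1, f)
                colflat = col.reshape(-1, col.shape[-1])
                grads[f"{layer.name}/W"] = (colflat.T @ dflat).reshape(W.shape)
                grads[f"{layer.name}/b"] = dflat.sum(axis=0)
                # dx = full correlation of d with the spatially flipped kernel
                dpad = np.pad(d, ((0, 0), (k - 1, k - 1), (k - 1, k - 1), (0, 0)))
                Wrot = W[::-1, ::-1].transpose(0, 1, 3, 2)  # k, k, F, Cin
                dcol = _im2col(dpad, k)
                d = dcol @ Wrot.reshape(-1, Wrot.shape[-1])
                assert d.shape[1:3] == in_shape[1:3]
        return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _accuracy(net: Network, x: np.ndarray, y: np.ndarray, batch: int = 512) -> float:
    preds = []
    for i in range(0, len(x), batch):
        logits, _ = net.forward(x[i : i + batch], train=False)
        preds.append(np.argmax(logits, axis=1))
    return float(np.mean(np.concatenate(preds) == y))


def train(
    spec: ArchitectureSpec,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[Network, list[dict]]:
    """Train a network from scratch on integer-labelled inputs.

    Returns the trained network and a per-epoch history of mean training
    loss and train/validation accuracy.  ``epochs=0`` returns the freshly
    initialized network with an empty history.  Raises on a single-class
    dataset.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes present")
    if y.max() >= spec.num_classes:
        raise ValueError("label outside the model's class range")
    rng = np.random.default_rng(config.seed)
    net = Network(spec, seed=config.seed)
    if net.num_parameters() != spec.total_params:
        raise AssertionError("instantiated parameter count disagrees with the spec")

    n = len(x)
    perm = rng.permutation(n)
    n_val = int(round(config.val_fraction * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    xtr, ytr = x[tr_idx], y[tr_idx]
    xval, yval = x[val_idx], y[val_idx]

    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    t = 0
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(xtr))
        losses = []
        for start in range(0, len(xtr), config.batch_size):
            bidx = order[start : start + config.batch_size]
            xb, yb = xtr[bidx], ytr[bidx]
            logits, caches = net.forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            eps = 1e-12
            losses.append(-np.mean(np.log(probs[np.arange(len(yb)), yb] + eps)))
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = net.backward(dlogits, caches)
            t += 1
            for key, g in grads.items():
                m[key] = config.beta1 * m[key] + (1 - config.beta1) * g
                v[key] = config.beta2 * v[key] + (1 - config.beta2) * g * g
                mhat = m[key] / (1 - config.beta1**t)
                vhat = v[key] / (1 - config.beta2**t)
                net.params[key] -= config.learning_rate * mhat / (np.sqrt(vhat) + config.eps)
        entry = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": _accuracy(net, xtr, ytr),
        }
        if len(xval):
            entry["val_accuracy"] = _accuracy(net, xval, yval)
        history.append(entry)
    return net, history


def predict(model: Network, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probabilities for a batch of inputs."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[..., None]
    probs_all = []
    for i in range(0, len(x), 512):
        logits, _ = model.forward(x[i : i + 512], train=False)
        probs_all.append(_softmax(logits))
    probs = np.concatenate(probs_all) if probs_all else np.empty((0, model.spec.num_classes))
    return np.argmax(probs, axis=1), probs
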