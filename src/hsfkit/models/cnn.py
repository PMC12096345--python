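"""Convolutional classifier over 66x66x1 fingerprints, in pure NumPy.

Three conv(ReLU)+maxpool stages, a flatten, ReLU dense layers and a
softmax output, trained with Adam on cross-entropy. Implemented with
im2col/col2im so a CPU-only environment can train the full library in
minutes; deterministic for a given seed under single-threaded BLAS.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

INPUT_SHAPE = (66, 66, 1)
N_CONV_STAGES = 3


@dataclass(frozen=True)
class CNNSpec:
    """Architecture + optimizer settings.

    ``conv_stages`` is exactly three ``(filters, kernel, pool)`` triples;
    every conv uses ReLU and is followed by max pooling.
    """

    n_classes: int
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    conv_stages: tuple[tuple[int, int, int], ...] = ((16, 3, 2), (32, 3, 2), (64, 3, 2))
    dense_widths: tuple[int, ...] = (128,)
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.conv_stages) != N_CONV_STAGES:
            raise ValueError(f"exactly {N_CONV_STAGES} conv stages required")
        if not self.dense_widths:
            raise ValueError("at least one dense layer required")
        object.__setattr__(self, "conv_stages",
                           tuple(tuple(int(v) for v in s) for s in self.conv_stages))
        object.__setattr__(self, "dense_widths", tuple(int(w) for w in self.dense_widths))
        object.__setattr__(self, "input_shape", tuple(int(v) for v in self.input_shape))

    @property
    def output_width(self) -> int:
        return self.n_classes


def build_cnn(n_classes: int, **overrides) -> CNNSpec:
    """Spec with 3 conv/pool stages, dense ReLU layers, softmax of width n_classes."""
    return CNNSpec(n_classes=n_classes, **overrides)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x (N,H,W,C) -> (N,Ho,Wo,k*k*C); valid convolution, stride 1
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    n, ho, wo, c, _, _ = v.shape
    return np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(n, ho, wo, k * k * c)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    n, h, w, c = x_shape
    ho, wo = h - k + 1, w - k + 1
    d = dcols.reshape(n, ho, wo, k, k, c)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, i:i + ho, j:j + wo, :] += d[:, :, :, i, j, :]
    return dx


def _maxpool(x: np.ndarray, p: int):
    n, h, w, c = x.shape
    ho, wo = h // p, w // p
    xc = x[:, :ho * p, :wo * p, :].reshape(n, ho, p, wo, p, c)
    out = xc.max(axis=(2, 4))
    mask = xc == out[:, :, None, :, None, :]
    return out, mask


def _maxpool_backward(dout: np.ndarray, mask: np.ndarray, x_shape: tuple, p: int) -> np.ndarray:
    n, h, w, c = x_shape
    ho, wo = h // p, w // p
    # split gradient evenly across ties within a window
    counts = mask.sum(axis=(2, 4), keepdims=True)
    d = mask * (dout[:, :, None, :, None, :] / counts)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :ho * p, :wo * p, :] = d.reshape(n, ho * p, wo * p, c)
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNClassifier:
    """Trainable CNN; exposes fit / predict_proba / predict / params_hash."""

    def __init__(self, spec: CNNSpec):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}
        self.loss_trace_: list[float] = []
        self._init_params()

    # -- parameter bookkeeping -------------------------------------------
    def _init_params(self) -> None:
        rng = np.random.default_rng(self.spec.seed)
        h, w, c = self.spec.input_shape
        params = {}
        for s, (f, k, p) in enumerate(self.spec.conv_stages):
            fan_in = k * k * c
            params[f"convW{s}"] = (rng.standard_normal((fan_in, f))
                                   * np.sqrt(2.0 / fan_in)).astype(np.float32)
            params[f"convb{s}"] = np.zeros(f, dtype=np.float32)
            h, w, c = (h - k + 1) // p, (w - k + 1) // p, f
        width = h * w * c
        dims = [width, *self.spec.dense_widths, self.spec.n_classes]
        for s, (din, dout) in enumerate(zip(dims, dims[1:])):
            params[f"denseW{s}"] = (rng.standard_normal((din, dout))
                                    * np.sqrt(2.0 / din)).astype(np.float32)
            params[f"denseb{s}"] = np.zeros(dout, dtype=np.float32)
        self.params = params
        self._flat_width = width

    def params_hash(self) -> str:
        digest = hashlib.sha256()
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(np.ascontiguousarray(self.params[name]).tobytes())
        return digest.hexdigest()

    # -- forward / backward ----------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec {self.spec.input_shape}")
        return x

    def _forward(self, x: np.ndarray, cache: list | None = None):
        a = x
        for s, (f, k, p) in enumerate(self.spec.conv_stages):
            cols = _im2col(a, k)
            z = cols @ self.params[f"convW{s}"] + self.params[f"convb{s}"]
            r = np.maximum(z, 0.0)
            pooled, mask = _maxpool(r, p)
            if cache is not None:
                cache.append(("conv", s, a.shape, cols, z, r.shape, mask, p, k))
            a = pooled
        flat = a.reshape(a.shape[0], -1)
        if cache is not None:
            cache.append(("flatten", a.shape))
        a = flat
        n_dense = len(self.spec.dense_widths) + 1
        for s in range(n_dense):
            z = a @ self.params[f"denseW{s}"] + self.params[f"denseb{s}"]
            last = s == n_dense - 1
            out = z if last else np.maximum(z, 0.0)
            if cache is not None:
                cache.append(("dense", s, a, z, last))
            a = out
        return a  # logits

    def _backward(self, cache: list, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        d = dlogits
        for item in reversed(cache):
            kind = item[0]
            if kind == "dense":
                _, s, a_in, z, last = item
                if not last:
                    d = d * (z > 0)
                grads[f"denseW{s}"] = a_in.T @ d
                grads[f"denseb{s}"] = d.sum(axis=0)
                d = d @ self.params[f"denseW{s}"].T
            elif kind == "flatten":
                _, pooled_shape = item
                d = d.reshape(pooled_shape)
            else:  # conv
                _, s, a_shape, cols, z, r_shape, mask, p, k = item
                d = _maxpool_backward(d, mask, r_shape, p)
                d = d * (z > 0)
                n, ho, wo, f = d.shape
                dflat = d.reshape(-1, f)
                grads[f"convW{s}"] = cols.reshape(-1, cols.shape[-1]).T @ dflat
                grads[f"convb{s}"] = dflat.sum(axis=0)
                dcols = d @ self.params[f"convW{s}"].T
                d = _col2im(dcols, a_shape, k)
        return grads

    # -- training ---------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray) -> "CNNClassifier":
        x = self._check_input(x)
        y = np.asarray(y, dtype=np.int64)
        if len(x) == 0:
            raise ValueError("training set is empty")
        if len(x) != len(y):
            raise ValueError("X/y length mismatch")
        if y.min() < 0 or y.max() >= self.spec.n_classes:
            raise ValueError("labels outside [0, n_classes)")
        rng = np.random.default_rng(self.spec.seed + 1)
        m = {k: np.zeros_like(v, dtype=np.float64) for k, v in self.params.items()}
        v = {k: np.zeros_like(val, dtype=np.float64) for k, val in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_trace_ = []
        n = len(x)
        bs = min(self.spec.batch_size, n)
        for _epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, bs):
                idx = order[lo:lo + bs]
                xb, yb = x[idx], y[idx]
                cache: list = []
                logits = self._forward(xb, cache)
                probs = _softmax(logits.astype(np.float64))
                loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
                losses.append(float(loss))
                dlogits = probs
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits = (dlogits / len(yb)).astype(np.float32)
                grads = self._backward(cache, dlogits)
                step += 1
                for name, g in grads.items():
                    g = g.astype(np.float64)
                    m[name] = beta1 * m[name] + (1 - beta1) * g
                    v[name] = beta2 * v[name] + (1 - beta2) * g * g
                    mhat = m[name] / (1 - beta1 ** step)
                    vhat = v[name] / (1 - beta2 ** step)
                    self.params[name] = (self.params[name]
                                         - self.spec.learning_rate * mhat
                                         / (np.sqrt(vhat) + eps)).astype(np.float32)
            self.loss_trace_.append(float(np.mean(losses)))
        return self

    # -- inference --------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = self._check_input(x)
        out = []
        for lo in range(0, len(x), 256):
            logits = self._forward(x[lo:lo + 256])
            out.append(_softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        import json
        from pathlib import Path

        spec = {
            "n_classes": self.spec.n_classes,
            "input_shape": list(self.spec.input_shape),
            "conv_stages": [list(s) for s in self.spec.conv_stages],
            "dense_widths": list(self.spec.dense_widths),
            "learning_rate": self.spec.learning_rate,
            "epochs": self.spec.epochs,
            "batch_size": self.spec.batch_size,
            "seed": self.spec.seed,
        }
        np.savez(Path(path), spec=json.dumps(spec),
                 **{k: v for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "CNNClassifier":
        import json

        data = np.load(path, allow_pickle=False)
        raw = json.loads(str(data["spec"]))
        spec = CNNSpec(
            n_classes=raw["n_classes"],
            input_shape=tuple(raw["input_shape"]),
            conv_stages=tuple(tuple(s) for s in raw["conv_stages"]),
            dense_widths=tuple(raw["dense_widths"]),
            learning_rate=raw["learning_rate"],
            epochs=raw["epochs"],
            batch_size=raw["batch_size"],
            seed=raw["seed"],
        )
        model = cls(spec)
        model.params = {k: data[k] for k in data.files if k != "spec"}
        return model


def train_cnn(spec: CNNSpec, x: np.ndarray, y: np.ndarray,
              seed: int | None = None) -> tuple[CNNClassifier, list[float]]:
    """Train a CNN; returns the model and its per-epoch loss trace."""
    if seed is not None and seed != spec.seed:
        from dataclasses import replace

        spec = replace(spec, seed=seed)
    model = CNNClassifier(spec).fit(x, y)
    return model, model.loss_trace_
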