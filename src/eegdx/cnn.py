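"""A small 2-D convolutional network for epoch-level EEG classification.

Architecture (fixed, following the study protocol): two convolutional
blocks — conv(16, (3,5)) -> ReLU -> batch norm -> max-pool(2,2) ->
dropout(0.4), then conv(32, (3,5)) with identical subsequent layers —
followed by flatten and a single sigmoid output unit. Trained with Adam
(learning rate 0.001), batch size 32, binary cross-entropy.

Implemented directly on NumPy (forward and backward passes, Adam) so the
package has no deep-learning-framework dependency; convolutions are
"valid" (no padding), pooling is non-overlapping 2x2 max with floor
semantics, and batch normalization keeps running statistics for
inference. All randomness (initialization, shuffling, dropout) flows
from a single seed, so training is reproducible on a fixed thread count.

The activation-then-batch-norm order is deliberate (it matches the
narrated block order); ``bn_before_activation=True`` swaps to the more
conventional order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CNNSpec", "CNNModel", "build_cnn", "CNNError"]


class CNNError(ValueError):
    pass


@dataclass(frozen=True)
class CNNSpec:
    """Architecture and training hyperparameters."""

    filters: tuple[int, int] = (16, 32)
    kernel: tuple[int, int] = (3, 5)
    pool: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.4
    learning_rate: float = 0.001
    batch_size: int = 32
    max_train_epochs: int = 50
    early_stop: str = "internal_val"  # internal_val | paper_faithful_test_monitor | none
    patience: int = 5
    val_subject_fraction: float = 0.15
    bn_before_activation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise CNNError("dropout_rate must be in [0, 1)")
        if self.early_stop not in ("internal_val", "paper_faithful_test_monitor", "none"):
            raise CNNError(f"unknown early_stop mode {self.early_stop!r}")


# ---------------------------------------------------------------------------
# layers (channels-last: inputs are (N, H, W, C))


class _Conv2D:
    kind = "conv2d"

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = kh * kw * c_in
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (kh * kw * c_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kh, self.kw = kh, kw
        self.params = {"w": self.w, "b": self.b}
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, H, W, C) -> (N, OH, OW, kh*kw*C), valid windows
        win = np.lib.stride_tricks.sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        # win: (N, OH, OW, C, kh, kw) -> (N, OH, OW, kh, kw, C)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        n, oh, ow = win.shape[:3]
        return np.ascontiguousarray(win).reshape(n, oh, ow, -1)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.x_shape = x.shape
        col = self._im2col(x)
        self.col = col if train else None
        return col @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, oh, ow, c_out = grad.shape
        g2 = grad.reshape(-1, c_out)
        self.grads["w"][...] = self.col.reshape(-1, self.w.shape[0]).T @ g2
        self.grads["b"][...] = g2.sum(axis=0)
        dcol = (g2 @ self.w.T).reshape(n, oh, ow, self.kh, self.kw, -1)
        dx = np.zeros(self.x_shape, dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + oh, j : j + ow, :] += dcol[:, :, :, i, j, :]
        self.col = None
        return dx

    def describe(self) -> dict:
        return {
            "kind": self.kind,
            "filters": self.w.shape[1],
            "kernel": (self.kh, self.kw),
            "padding": "valid",
        }


class _ReLU:
    kind = "relu"
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train):
        self.mask = x > 0
        return np.where(self.mask, x, 0.0)

    def backward(self, grad):
        return grad * self.mask

    def describe(self):
        return {"kind": self.kind}


class _BatchNorm:
    kind = "batch_norm"

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": self.gamma, "beta": self.beta}
        self.grads = {"gamma": np.zeros(c, np.float32), "beta": np.zeros(c, np.float32)}

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.x_hat = (x - mean) * self.inv_std
        out = self.gamma * self.x_hat + self.beta
        if not train:
            self.x_hat = None
        return out

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        n = grad.size / grad.shape[-1]
        self.grads["gamma"][...] = (grad * self.x_hat).sum(axis=axes)
        self.grads["beta"][...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - self.x_hat * (dxhat * self.x_hat).sum(axis=axes) / n
        ) * self.inv_std
        self.x_hat = None
        return dx.astype(np.float32)

    def describe(self):
        return {"kind": self.kind, "momentum": self.momentum, "eps": self.eps}


class _MaxPool:
    kind = "max_pool"
    params: dict = {}
    grads: dict = {}

    def __init__(self, ph: int = 2, pw: int = 2):
        self.ph, self.pw = ph, pw

    def forward(self, x, train):
        n, h, w, c = x.shape
        oh, ow = h // self.ph, w // self.pw
        self.in_shape = x.shape
        xr = x[:, : oh * self.ph, : ow * self.pw, :].reshape(
            n, oh, self.ph, ow, self.pw, c
        )
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, self.ph * self.pw)
        self.argmax = flat.argmax(axis=-1)
        return np.take_along_axis(flat, self.argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, oh, ow, c = grad.shape
        flat = np.zeros((n, oh, ow, c, self.ph * self.pw), dtype=np.float32)
        np.put_along_axis(flat, self.argmax[..., None], grad[..., None], axis=-1)
        xr = flat.reshape(n, oh, ow, c, self.ph, self.pw).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self.in_shape, dtype=np.float32)
        dx[:, : oh * self.ph, : ow * self.pw, :] = xr.reshape(
            n, oh * self.ph, ow * self.pw, c
        )
        return dx

    def describe(self):
        return {"kind": self.kind, "pool": (self.ph, self.pw)}


class _Dropout:
    kind = "dropout"
    params: dict = {}
    grads: dict = {}

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.uniform(size=x.shape) < keep).astype(np.float32) / keep
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask

    def describe(self):
        return {"kind": self.kind, "rate": self.rate}


class _Flatten:
    kind = "flatten"
    params: dict = {}
    grads: dict = {}

    def forward(self, x, train):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.in_shape)

    def describe(self):
        return {"kind": self.kind}


class _Dense:
    kind = "dense"

    def __init__(self, n_in: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (n_in + 1))
        self.w = rng.uniform(-lim, lim, (n_in, 1)).astype(np.float32)
        self.b = np.zeros(1, dtype=np.float32)
        self.params = {"w": self.w, "b": self.b}
        self.grads = {"w": np.zeros_like(self.w), "b": np.zeros_like(self.b)}

    def forward(self, x, train):
        self.x = x if train else None
        return (x @ self.w + self.b)[:, 0]

    def backward(self, grad):
        g = grad[:, None]
        self.grads["w"][...] = self.x.T @ g
        self.grads["b"][...] = g.sum(axis=0)
        dx = g @ self.w.T
        self.x = None
        return dx

    def describe(self):
        return {"kind": self.kind, "units": 1, "activation": "sigmoid"}


# ---------------------------------------------------------------------------


def _conv_out(h: int, w: int, kernel: tuple[int, int]) -> tuple[int, int]:
    return h - kernel[0] + 1, w - kernel[1] + 1


def _min_input_dims(spec: CNNSpec) -> tuple[int, int]:
    """Smallest (H, W) for which both conv blocks produce non-empty maps."""
    kh, kw = spec.kernel
    ph, pw = spec.pool
    # work backwards: pool2 output >= 1 => conv2 input >= kernel + pool - 1
    h = ph * (kh + ph - 1) + kh - 1
    w = pw * (kw + pw - 1) + kw - 1
    return h, w


def build_cnn(input_dims: tuple[int, int, int], spec: CNNSpec = CNNSpec()) -> "CNNModel":
    """Construct an untrained model for (n_freqs, n_times, n_channels)
    input. Raises with the computed minimum dimensions if the input is
    too small for the kernels and poolings."""
    return CNNModel(input_dims, spec)


class CNNModel:
    def __init__(self, input_dims: tuple[int, int, int], spec: CNNSpec):
        h, w, c = input_dims
        if min(input_dims) < 1:
            raise CNNError("input dimensions must be positive")
        min_h, min_w = _min_input_dims(spec)
        if h < min_h or w < min_w:
            raise CNNError(
                f"input ({h}, {w}) too small for two conv({spec.kernel})/"
                f"pool({spec.pool}) blocks; minimum is ({min_h}, {min_w})"
            )
        self.spec = spec
        self.input_dims = tuple(input_dims)
        self.rng = np.random.default_rng(spec.seed)
        self.layers: list = []
        shape = (h, w, c)
        for f in spec.filters:
            conv = _Conv2D(*spec.kernel, shape[2], f, self.rng)
            block = [conv]
            act_bn = [_ReLU(), _BatchNorm(f)]
            if spec.bn_before_activation:
                act_bn = act_bn[::-1]
            block += act_bn
            block += [_MaxPool(*spec.pool), _Dropout(spec.dropout_rate, self.rng)]
            self.layers += block
            ch, cw = _conv_out(shape[0], shape[1], spec.kernel)
            shape = (ch // spec.pool[0], cw // spec.pool[1], f)
        self.layers.append(_Flatten())
        n_flat = int(np.prod(shape))
        self.layers.append(_Dense(n_flat, self.rng))
        self._init_adam()
        self.fitted = False
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": []}

    # -- introspection ------------------------------------------------------

    def architecture_report(self) -> list[dict]:
        """Ordered layer descriptors with output shapes (per epoch)."""
        report = []
        shape: tuple = self.input_dims
        for layer in self.layers:
            d = layer.describe()
            if layer.kind == "conv2d":
                ch, cw = _conv_out(shape[0], shape[1], d["kernel"])
                shape = (ch, cw, d["filters"])
            elif layer.kind == "max_pool":
                shape = (shape[0] // d["pool"][0], shape[1] // d["pool"][1], shape[2])
            elif layer.kind == "flatten":
                shape = (int(np.prod(shape)),)
            elif layer.kind == "dense":
                shape = (1,)
            d["output_shape"] = shape
            report.append(d)
        return report

    # -- optimization -------------------------------------------------------

    def _init_adam(self):
        self._adam_m, self._adam_v = [], []
        for layer in self.layers:
            self._adam_m.append({k: np.zeros_like(v) for k, v in layer.params.items()})
            self._adam_v.append({k: np.zeros_like(v) for k, v in layer.params.items()})
        self._adam_t = 0

    def _adam_step(self):
        lr, b1, b2, eps = self.spec.learning_rate, 0.9, 0.999, 1e-7
        self._adam_t += 1
        t = self._adam_t
        for layer, m, v in zip(self.layers, self._adam_m, self._adam_v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k][...] = b1 * m[k] + (1 - b1) * g
                v[k][...] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**t)
                vhat = v[k] / (1 - b2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x  # logits

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # -- weights ------------------------------------------------------------

    def get_weights(self) -> list[dict]:
        out = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.params.items()}
            if layer.kind == "batch_norm":
                d["running_mean"] = layer.running_mean.copy()
                d["running_var"] = layer.running_var.copy()
            out.append(d)
        return out

    def set_weights(self, weights: list[dict]) -> None:
        for layer, d in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = d[k]
            if layer.kind == "batch_norm":
                layer.running_mean[...] = d["running_mean"]
                layer.running_var[...] = d["running_var"]

    # -- training -----------------------------------------------------------

    @staticmethod
    def _bce_from_logits(z: np.ndarray, y: np.ndarray) -> float:
        # numerically stable binary cross-entropy
        return float(np.mean(np.logaddexp(0.0, z) - y * z))

    def _eval_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        z = self._forward(x.astype(np.float32), train=False)
        return self._bce_from_logits(z, y)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        subject_ids: np.ndarray | None = None,
        monitor: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> dict[str, list[float]]:
        """Train with Adam/BCE. Early stopping per ``spec.early_stop``:

        - ``internal_val``: hold out a subject-stratified validation split
          carved from the *training* subjects (requires ``subject_ids``),
          stop when its loss fails to improve for ``patience`` passes,
          restore the best weights.
        - ``paper_faithful_test_monitor``: monitor loss on the provided
          ``monitor`` set (the held-out fold). This reproduces a protocol
          that leaks test information into the stopping decision; it is
          provided for comparability only.
        - ``none``: run all ``max_train_epochs`` passes.
        """
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        classes = np.unique(y)
        if classes.size < 2:
            raise CNNError("training labels contain a single class")
        spec = self.spec
        val: tuple[np.ndarray, np.ndarray] | None = None
        if spec.early_stop == "internal_val":
            if subject_ids is None:
                raise CNNError("internal_val early stopping needs subject_ids")
            tr_idx, va_idx = _subject_validation_split(
                np.asarray(subject_ids), y, spec.val_subject_fraction, self.rng
            )
            val = (x[va_idx], y[va_idx])
            x, y = x[tr_idx], y[tr_idx]
        elif spec.early_stop == "paper_faithful_test_monitor":
            if monitor is None:
                raise CNNError("paper_faithful_test_monitor needs a monitor set")
            val = (np.asarray(monitor[0], np.float32), np.asarray(monitor[1], np.float32))
        n = x.shape[0]
        best_loss, best_weights, since_best = np.inf, None, 0
        for _ in range(spec.max_train_epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                xb, yb = x[idx], y[idx]
                z = self._forward(xb, train=True)
                loss = self._bce_from_logits(z, yb)
                if not np.isfinite(loss):
                    raise CNNError("non-finite training loss")
                p = 1.0 / (1.0 + np.exp(-z))
                self._backward(((p - yb) / yb.size).astype(np.float32))
                self._adam_step()
                losses.append(loss)
            self.history["loss"].append(float(np.mean(losses)))
            if val is not None:
                vloss = self._eval_loss(*val)
                self.history["val_loss"].append(vloss)
                if vloss < best_loss - 1e-6:
                    best_loss, since_best = vloss, 0
                    best_weights = self.get_weights()
                else:
                    since_best += 1
                    if since_best >= spec.patience:
                        break
        if val is not None and best_weights is not None:
            self.set_weights(best_weights)
        self.fitted = True
        return self.history

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-epoch class-1 probability; deterministic (dropout off,
        batch norm in inference mode)."""
        if not self.fitted:
            raise CNNError("model is not fitted")
        x = np.asarray(x, dtype=np.float32)
        if x.shape[1:] != self.input_dims:
            raise CNNError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{self.input_dims}"
            )
        z = self._forward(x, train=False)
        return 1.0 / (1.0 + np.exp(-z))


def _subject_validation_split(
    subject_ids: np.ndarray,
    y: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick validation subjects (>= 1) so that both classes remain in the
    training portion; epochs of a subject never straddle the split."""
    subjects = np.array(sorted(set(subject_ids.tolist())))
    n_val = max(1, int(round(fraction * subjects.size)))
    if subjects.size - n_val < 2:
        n_val = max(1, subjects.size - 2)
    subj_label = {s: y[subject_ids == s][0] for s in subjects}
    for _ in range(100):
        val_subjects = rng.choice(subjects, size=n_val, replace=False)
        tr_subjects = [s for s in subjects if s not in set(val_subjects.tolist())]
        if len({subj_label[s] for s in tr_subjects}) == 2:
            val_mask = np.isin(subject_ids, val_subjects)
            return np.where(~val_mask)[0], np.where(val_mask)[0]
    raise CNNError("could not build a two-class training split")
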