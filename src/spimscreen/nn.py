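"""A compact VGG-style convolutional network in plain numpy.

Designed for small single-channel morphology patches: stacks of 3×3
convolution + ReLU + 2×2 max-pool blocks followed by one hidden dense
layer and a softmax head, trained with Adam on cross-entropy.  Everything
is seeded and single-process, so training is reproducible.

The implementation favours clarity and CPU throughput at desk scale
(thousands of 32×32 patches): convolutions are evaluated as nine shifted
tensor contractions, which keeps all heavy lifting inside BLAS.
"""

from __future__ import annotations

import numpy as np


class _Conv3x3:
    """Same-padded 3×3 convolution via im2col + one GEMM per direction."""

    def __init__(self, c_in, c_out, rng, is_input_layer=False):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0, scale, (c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.is_input_layer = is_input_layer

    def forward(self, x):
        from numpy.lib.stride_tricks import sliding_window_view

        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)
        f = self.W.shape[0]
        out = cols @ self.W.reshape(f, c * 9).T + self.b
        self._cols = cols
        self._shape = (n, c, h, w)
        return out.reshape(n, h, w, f).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w = self._shape
        f = self.W.shape[0]
        dout2 = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, f)
        self.dW = (dout2.T @ self._cols).reshape(f, c, 3, 3)
        self.db = dout2.sum(axis=0)
        self._cols = None
        if self.is_input_layer:
            return None  # nothing upstream needs this gradient
        dcols = (dout2 @ self.W.reshape(f, c * 9)).reshape(n, h, w, c, 3, 3)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for dy in range(3):
            for dx in range(3):
                dxp[:, :, dy:dy + h, dx:dx + w] += dcols[:, :, :, :, dy, dx].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]

    def params(self):
        return [("W", self.W, lambda: self.dW), ("b", self.b, lambda: self.db)]


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        self._r = r
        self._out = out
        return out

    def backward(self, dout):
        r = self._r
        mask = r == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)  # ties share the gradient
        g = mask * (dout[:, :, :, None, :, None] / counts)
        n, c, h2, _, w2, _ = r.shape
        return g.reshape(n, c, h2 * 2, w2 * 2)

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [("W", self.W, lambda: self.dW), ("b", self.b, lambda: self.db)]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def augment_batch(x, rng):
    """Random 90° rotations and flips (the symmetries of a nucleus patch)."""
    k = rng.integers(0, 4, len(x))
    fl = rng.integers(0, 2, len(x))
    out = x.copy()
    for kk in (1, 2, 3):
        m = k == kk
        if m.any():
            out[m] = np.rot90(out[m], kk, axes=(-2, -1))
    m = fl == 1
    if m.any():
        out[m] = out[m][..., ::-1]
    return out


class TinyVGG:
    """3 conv blocks (16→32→64 channels) + dense(128) + softmax head."""

    def __init__(self, input_size=32, n_classes=4, channels=(16, 32, 64),
                 hidden=128, seed=0):
        rng = np.random.default_rng(seed)
        self.input_size = int(input_size)
        self.n_classes = int(n_classes)
        self.channels = tuple(channels)
        self.hidden = int(hidden)
        layers = []
        c_prev = 1
        size = self.input_size
        for i, c in enumerate(channels):
            layers += [_Conv3x3(c_prev, c, rng, is_input_layer=(i == 0)),
                       _ReLU(), _MaxPool2()]
            c_prev = c
            size //= 2
        layers += [_Flatten(), _Dense(size * size * c_prev, hidden, rng), _ReLU(),
                   _Dense(hidden, n_classes, rng)]
        self.layers = layers
        self._adam_state = {}

    # ---------------------------------------------------------------

    def _forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, patches, batch_size=256):
        """Softmax class probabilities for (N, H, W) patches in [0, 1]."""
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        out = []
        for i in range(0, len(x), batch_size):
            out.append(_softmax(self._forward(x[i:i + batch_size])))
        return np.vstack(out) if out else np.zeros((0, self.n_classes))

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t = getattr(self, "_t", 0) + 1
        for li, layer in enumerate(self.layers):
            for name, param, grad_fn in layer.params():
                g = grad_fn()
                key = (li, name)
                m, v = self._adam_state.get(key, (np.zeros_like(param), np.zeros_like(param)))
                m = beta1 * m + (1 - beta1) * g
                v = beta2 * v + (1 - beta2) * g * g
                self._adam_state[key] = (m, v)
                mhat = m / (1 - beta1**self._t)
                vhat = v / (1 - beta2**self._t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, patches, labels, epochs=8, batch_size=128, lr=1e-3,
            seed=0, augment=True, verbose=False, lr_decay=True):
        """Train on (N, H, W) patches with integer class labels.

        With ``lr_decay`` the learning rate steps down to 1/4 and 1/10 of
        ``lr`` over the last 40% / 15% of epochs, which settles the late
        epochs onto a stable optimum.
        """
        x = np.asarray(patches, dtype=np.float32)
        y = np.asarray(labels, dtype=np.int64)
        if x.ndim == 3:
            x = x[:, None]
        rng = np.random.default_rng(seed)
        n = len(x)
        base_lr = lr
        for epoch in range(epochs):
            if lr_decay:
                if epoch >= int(0.85 * epochs):
                    lr = base_lr / 10.0
                elif epoch >= int(0.6 * epochs):
                    lr = base_lr / 4.0
                else:
                    lr = base_lr
            order = rng.permutation(n)
            total = 0.0
            for i in range(0, n, batch_size):
                sel = order[i:i + batch_size]
                xb = x[sel]
                if augment:
                    xb = augment_batch(xb, rng)
                yb = y[sel]
                logits = self._forward(xb)
                p = _softmax(logits)
                loss = -np.log(np.clip(p[np.arange(len(yb)), yb], 1e-12, None)).mean()
                total += loss * len(yb)
                dlogits = p
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grad = dlogits.astype(np.float32)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                self._adam_step(lr)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs} loss {total / n:.4f}")
        return self

    # --- serialization -------------------------------------------------

    def state_dict(self):
        d = {"input_size": self.input_size, "n_classes": self.n_classes,
             "channels": self.channels, "hidden": self.hidden}
        arrays = {}
        for li, layer in enumerate(self.layers):
            for name, param, _ in layer.params():
                arrays[f"{li}.{name}"] = param
        return d, arrays

    @classmethod
    def from_state(cls, meta, arrays):
        net = cls(meta["input_size"], meta["n_classes"], tuple(meta["channels"]),
                  meta["hidden"])
        for li, layer in enumerate(net.layers):
            for name, param, _ in layer.params():
                param[...] = arrays[f"{li}.{name}"]
        return net
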