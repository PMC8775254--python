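"""A compact numpy neural-network engine for small sequence classifiers.

Implements exactly the layers the gesture models need — 2-D convolution
(im2col), batch normalization, ReLU, ceil-mode max-pooling, dense, dropout, a
single-layer LSTM, and channel concatenation for the fusion block — each with
a hand-written backward pass, plus SGD with momentum and decoupled L2 weight
decay.  Gradients are verified against finite differences in the test suite.

Layers follow one protocol: ``forward(x, train)`` caches what backward needs,
``backward(gy)`` returns the gradient w.r.t. the input and fills
``layer.grads``.  Shapes are channel-last: conv maps are ``(B, H, W, C)``,
sequences are ``(B, T, D)``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    name = "layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _pad_amounts(L, k, stride):
    n_out = -(-L // stride)
    total = max((n_out - 1) * stride + k - L, 0)
    return n_out, total // 2, total - total // 2


class Conv2D(Layer):
    """Same- or valid-padded 2-D convolution, channel-last, via im2col."""

    def __init__(self, c_in, filters, kernel=3, stride=1, padding="same",
                 bias=True, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.k, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.filters = c_in, filters
        fan_in = kernel * kernel * c_in
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(fan_in, filters))
        if bias:
            self.params["b"] = np.zeros(filters)
        self.name = f"conv{filters}k{kernel}" + (f"s{stride}" if stride != 1 else "")

    def _im2col(self, xp, out_h, out_w):
        B, _, _, C = xp.shape
        k, s = self.k, self.stride
        cols = np.empty((B, out_h, out_w, k, k, C), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[:, i : i + out_h * s : s,
                                            j : j + out_w * s : s, :]
        return cols.reshape(B, out_h, out_w, k * k * C)

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        k, s = self.k, self.stride
        if self.padding == "same":
            out_h, ph0, ph1 = _pad_amounts(H, k, s)
            out_w, pw0, pw1 = _pad_amounts(W, k, s)
        else:
            if H < k or W < k:
                raise ValueError(f"spatial extent ({H},{W}) smaller than kernel {k}")
            out_h, out_w = (H - k) // s + 1, (W - k) // s + 1
            ph0 = ph1 = pw0 = pw1 = 0
        xp = np.pad(x, ((0, 0), (ph0, ph1), (pw0, pw1), (0, 0)))
        self._cache = (x.shape, xp.shape, (ph0, pw0), out_h, out_w)
        self._cols = self._im2col(xp, out_h, out_w)
        y = self._cols @ self.params["W"]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, gy):
        (xshape, xpshape, (ph0, pw0), out_h, out_w) = self._cache
        B = xshape[0]
        k, s, C = self.k, self.stride, self.c_in
        flat_cols = self._cols.reshape(-1, k * k * C)
        flat_gy = gy.reshape(-1, self.filters)
        self.grads["W"] = flat_cols.T @ flat_gy
        if "b" in self.params:
            self.grads["b"] = flat_gy.sum(axis=0)
        gcols = (flat_gy @ self.params["W"].T).reshape(B, out_h, out_w, k, k, C)
        gxp = np.zeros(xpshape)
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + out_h * s : s, j : j + out_w * s : s, :] += \
                    gcols[:, :, :, i, j, :]
        H, W = xshape[1], xshape[2]
        return gxp[:, ph0 : ph0 + H, pw0 : pw0 + W, :]


class BatchNorm(Layer):
    """Batch normalization over all but the last (channel) axis."""

    name = "batchnorm"

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes])
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._train = train
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, gy):
        axes = self._axes
        self.grads["gamma"] = (gy * self._xhat).sum(axis=axes)
        self.grads["beta"] = gy.sum(axis=axes)
        gxhat = gy * self.params["gamma"]
        if not self._train:
            return gxhat / self._std
        m = self._m
        return (gxhat - gxhat.mean(axis=axes)
                - self._xhat * (gxhat * self._xhat).sum(axis=axes) / m) / self._std


class ReLU(Layer):
    name = "relu"

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class MaxPool2D(Layer):
    """2x2 stride-2 max pool in ceil mode: odd extents keep a truncated final
    window, so the output is always ``ceil(L/2)`` per axis (matching the
    same-padded stride-2 conv branch of the fusion block)."""

    name = "maxpool2"

    def __init__(self, size=2):
        super().__init__()
        self.size = size

    def forward(self, x, train=False):
        B, H, W, C = x.shape
        s = self.size
        H2, W2 = -(-H // s), -(-W // s)
        xp = np.full((B, H2 * s, W2 * s, C), -np.inf)
        xp[:, :H, :W, :] = x
        xr = xp.reshape(B, H2, s, W2, s, C)
        y = xr.max(axis=(2, 4))
        mask = xr == y[:, :, None, :, None, :]
        # split gradient among ties to keep backward well-defined
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._shape = (B, H, W, C, H2, W2)
        return y

    def backward(self, gy):
        B, H, W, C, H2, W2 = self._shape
        s = self.size
        g = self._mask * gy[:, :, None, :, None, :]
        return g.reshape(B, H2 * s, W2 * s, C)[:, :H, :W, :]


class Flatten(Layer):
    name = "flatten"

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in, d_out, bias=True, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        if bias:
            self.params["b"] = np.zeros(d_out)
        self.name = f"dense{d_out}"

    def forward(self, x, train=False):
        self._x = x
        y = x @ self.params["W"]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, gy):
        self.grads["W"] = self._x.T @ gy
        if "b" in self.params:
            self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = np.random.default_rng(rng)
        self.name = f"dropout{rate:g}"

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """Single-layer LSTM over ``(B, T, D)`` returning the last hidden state.

    Gate order i, f, g, o; Glorot-uniform input/recurrent weights, forget-gate
    bias initialized to 1 (standard practice for trainability).
    """

    def __init__(self, d_in, units, rng=None):
        super().__init__()
        rng = np.random.default_rng(rng)
        lim_x = np.sqrt(6.0 / (d_in + 4 * units))
        lim_h = np.sqrt(6.0 / (units + 4 * units))
        self.params["Wx"] = rng.uniform(-lim_x, lim_x, size=(d_in, 4 * units))
        self.params["Wh"] = rng.uniform(-lim_h, lim_h, size=(units, 4 * units))
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0
        self.params["b"] = b
        self.units = units
        self.name = f"lstm{units}"

    def forward(self, x, train=False):
        B, T, D = x.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        self._x = x
        self._steps = []
        for t in range(T):
            z = x[:, t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U : 2 * U])
            g = np.tanh(z[:, 2 * U : 3 * U])
            o = _sigmoid(z[:, 3 * U :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            self._steps.append((h.copy(), c_prev, i, f, g, o, tc))
            h = o * tc
        return h

    def backward(self, gh_last):
        x = self._x
        B, T, D = x.shape
        U = self.units
        gWx = np.zeros_like(self.params["Wx"])
        gWh = np.zeros_like(self.params["Wh"])
        gb = np.zeros_like(self.params["b"])
        gx = np.zeros_like(x)
        gh = gh_last
        gc = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._steps[t]
            go = gh * tc
            gc = gc + gh * o * (1 - tc**2)
            gi = gc * g
            gf = gc * c_prev
            gg = gc * i
            gz = np.concatenate(
                [gi * i * (1 - i), gf * f * (1 - f),
                 gg * (1 - g**2), go * o * (1 - o)], axis=1)
            gWx += x[:, t].T @ gz
            gWh += h_prev.T @ gz
            gb += gz.sum(axis=0)
            gx[:, t] = gz @ self.params["Wx"].T
            gh = gz @ self.params["Wh"].T
            gc = gc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = gWx, gWh, gb
        return gx


class CFFBlock2D(Layer):
    """Trainable fusion block: max-pool and stride-2 conv applied to the same
    map in parallel, channel-concatenated with the parameter-free pool branch
    first.  Output channels = input channels + conv filters."""

    def __init__(self, c_in, filters, kernel=3, rng=None, bias=True):
        super().__init__()
        self.pool = MaxPool2D()
        self.conv = Conv2D(c_in, filters, kernel=kernel, stride=2,
                           padding="same", bias=bias, rng=rng)
        self.c_in = c_in
        self.name = f"cff[maxpool2||conv{filters}k{kernel}s2]"

    @property
    def params(self):
        return self.conv.params

    @params.setter
    def params(self, value):  # Layer.__init__ assigns {}; delegate to conv
        pass

    @property
    def grads(self):
        return self.conv.grads

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x, train=False):
        p = self.pool.forward(x, train)
        c = self.conv.forward(x, train)
        if p.shape[:3] != c.shape[:3]:
            raise ValueError(
                f"branch shape mismatch: pool {p.shape} vs conv {c.shape}")
        self._split = p.shape[-1]
        return np.concatenate([p, c], axis=-1)

    def backward(self, gy):
        gp = self.pool.backward(gy[..., : self._split])
        gc = self.conv.backward(gy[..., self._split :])
        return gp + gc


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs, y_onehot, kind="bernoulli", eps=1e-7):
    """Mean-per-sample loss and its gradient w.r.t. the logits.

    ``kind='bernoulli'`` is the elementwise form
    ``-[y log p + (1-y) log(1-p)]`` summed over classes (the binary
    cross-entropy idiom applied to a softmax output); ``kind='categorical'``
    is ``-sum_i y_i log p_i``.  Both return ``(loss, dL/dlogits)``.
    """
    p = np.clip(probs, eps, 1 - eps)
    B = p.shape[0]
    if kind == "categorical":
        loss = -(y_onehot * np.log(p)).sum() / B
        gz = (probs - y_onehot) / B
    elif kind == "bernoulli":
        loss = -(y_onehot * np.log(p) + (1 - y_onehot) * np.log(1 - p)).sum() / B
        gp = (-(y_onehot / p) + (1 - y_onehot) / (1 - p)) / B
        # back through softmax: dL/dz = p * (g - <g, p>)
        gz = probs * (gp - (gp * probs).sum(axis=-1, keepdims=True))
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    return loss, gz


class SGDM:
    """SGD with momentum and L2 weight decay: v <- m v - lr (g + wd p)."""

    def __init__(self, lr=0.002, momentum=0.95, weight_decay=0.0005):
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers):
        for layer in layers:
            if not layer.params:
                continue
            v = self._v.setdefault(id(layer), {
                k: np.zeros_like(p) for k, p in layer.params.items()})
            for k, p in layer.params.items():
                g = layer.grads[k] + self.weight_decay * p
                v[k] = self.momentum * v[k] - self.lr * g
                p += v[k]


class SequenceClassifier:
    """Time-distributed CNN + LSTM + softmax head over ``(B, T, W, H, C)``.

    ``frame_layers`` are applied to each frame independently (the batch and
    time axes are merged), the per-frame feature vectors form the LSTM input
    sequence, and the head maps the final hidden state to class logits.
    """

    def __init__(self, frame_layers, lstm, dropout, head):
        self.frame_layers = list(frame_layers)
        self.lstm = lstm
        self.dropout = dropout
        self.head = head

    @property
    def layers(self):
        return [*self.frame_layers, self.lstm, self.dropout, self.head]

    def layer_names(self):
        names = [l.name for l in self.frame_layers]
        names += [self.lstm.name, self.head.name, "softmax"]
        return names

    def forward(self, X, train=False):
        B, T = X.shape[:2]
        h = X.reshape(B * T, *X.shape[2:])
        for layer in self.frame_layers:
            h = layer.forward(h, train)
        h = h.reshape(B, T, -1)
        h = self.lstm.forward(h, train)
        h = self.dropout.forward(h, train)
        return self.head.forward(h, train)  # logits

    def backward(self, gz):
        g = self.head.backward(gz)
        g = self.dropout.backward(g)
        g = self.lstm.backward(g)  # (B, T, D_feat)
        B, T = g.shape[:2]
        g = g.reshape((B * T,) + self._frame_out_shape)
        for layer in reversed(self.frame_layers):
            g = layer.backward(g)
        return g

    def forward_backward(self, X, y_onehot, loss_kind="bernoulli"):
        """One full pass; returns (loss, probs) and fills layer grads."""
        B, T = X.shape[:2]
        h = X.reshape(B * T, *X.shape[2:])
        for layer in self.frame_layers:
            h = layer.forward(h, True)
        self._frame_out_shape = h.shape[1:]
        seq = h.reshape(B, T, -1)
        hT = self.lstm.forward(seq, True)
        hd = self.dropout.forward(hT, True)
        z = self.head.forward(hd, True)
        probs = softmax(z)
        loss, gz = cross_entropy(probs, y_onehot, kind=loss_kind)
        self.backward(gz)
        return loss, probs

    def predict_proba(self, X, batch_size=64):
        out = []
        for i in range(0, X.shape[0], batch_size):
            z = self.forward(X[i : i + batch_size], train=False)
            out.append(softmax(z))
        return np.concatenate(out)
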