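"""Seeded numpy neural-network backend.

Implements exactly the layer vocabulary the workload classifiers need:
2-D convolution (stride 1, 'same' padding), 2x2 max pooling, LSTM with
ReLU state activation, dense layers, dropout, flatten/reshape, a
softmax head with categorical cross-entropy, and Adam. Weights use
Glorot-uniform initialization from a seeded generator, so builds and
training runs are reproducible bit-for-bit on one machine.

Shapes follow the channels-last convention: images are (batch, H, W, C)
and sequences are (batch, T, D).
"""

from __future__ import annotations

import numpy as np

from cogload.errors import InvalidArgumentError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


class Layer:
    """Base layer: build() fixes shapes and weights; forward/backward cache."""

    def __init__(self) -> None:
        self.weights: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def build(self, input_shape: tuple[int, ...], rng: np.random.Generator,
              dtype) -> tuple[int, ...]:
        return input_shape

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights.values())


class Dense(Layer):
    def __init__(self, units: int, activation: str | None = "relu") -> None:
        super().__init__()
        if activation not in (None, "relu", "softmax"):
            raise InvalidArgumentError(f"unsupported activation {activation!r}")
        self.units = units
        self.activation = activation

    def build(self, input_shape, rng, dtype):
        (d,) = input_shape
        self.weights = {
            "W": _glorot(rng, (d, self.units), d, self.units, dtype),
            "b": np.zeros(self.units, dtype=dtype),
        }
        return (self.units,)

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.weights["W"] + self.weights["b"]
        if self.activation == "relu":
            self._out = _relu(z)
        elif self.activation == "softmax":
            z = z - z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            self._out = e / e.sum(axis=-1, keepdims=True)
        else:
            self._out = z
        return self._out

    def backward(self, grad):
        # softmax head is paired with cross-entropy: grad arrives w.r.t. logits
        if self.activation == "relu":
            grad = grad * (self._out > 0)
        self.grads = {"W": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.weights["W"].T


class Conv2D(Layer):
    """2-D convolution, stride 1, 'same' padding, ReLU activation."""

    def __init__(self, filters: int, kernel_size: tuple[int, int] | int) -> None:
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        self.filters = filters
        self.kh, self.kw = kernel_size

    def build(self, input_shape, rng, dtype):
        h, w, c = input_shape
        self._in_shape = (h, w, c)
        fan_in = self.kh * self.kw * c
        self.weights = {
            "W": _glorot(rng, (fan_in, self.filters), fan_in, self.filters, dtype),
            "b": np.zeros(self.filters, dtype=dtype),
        }
        return (h, w, self.filters)

    def _im2col(self, x):
        B, H, W, C = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (ph, self.kh - 1 - ph),
                        (pw, self.kw - 1 - pw), (0, 0)))
        cols = np.empty((B, H, W, self.kh, self.kw, C), dtype=x.dtype)
        for a in range(self.kh):
            for b in range(self.kw):
                cols[:, :, :, a, b, :] = xp[:, a : a + H, b : b + W, :]
        return cols.reshape(B * H * W, self.kh * self.kw * C)

    def forward(self, x, training=False, rng=None):
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        z = self._cols @ self.weights["W"] + self.weights["b"]
        self._out = _relu(z)
        B, H, W, _ = x.shape
        return self._out.reshape(B, H, W, self.filters)

    def backward(self, grad):
        B, H, W, C = self._x_shape
        g = grad.reshape(B * H * W, self.filters) * (self._out > 0)
        self.grads = {"W": self._cols.T @ g, "b": g.sum(axis=0)}
        dcols = (g @ self.weights["W"].T).reshape(B, H, W, self.kh, self.kw, C)
        ph, pw = self.kh // 2, self.kw // 2
        dxp = np.zeros((B, H + self.kh - 1, W + self.kw - 1, C), dtype=grad.dtype)
        for a in range(self.kh):
            for b in range(self.kw):
                dxp[:, a : a + H, b : b + W, :] += dcols[:, :, :, a, b, :]
        return dxp[:, ph : ph + H, pw : pw + W, :]


class MaxPool2D(Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def build(self, input_shape, rng, dtype):
        h, w, c = input_shape
        if h % self.pool or w % self.pool:
            raise InvalidArgumentError("spatial dims must divide the pool size")
        return (h // self.pool, w // self.pool, c)

    def forward(self, x, training=False, rng=None):
        p = self.pool
        B, H, W, C = x.shape
        self._x_shape = x.shape
        xr = x.reshape(B, H // p, p, W // p, p, C)
        flat = xr.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // p, W // p, p * p, C)
        self._argmax = flat.argmax(axis=3)
        return np.take_along_axis(flat, self._argmax[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, grad):
        p = self.pool
        B, H, W, C = self._x_shape
        dflat = np.zeros((B, H // p, W // p, p * p, C), dtype=grad.dtype)
        np.put_along_axis(dflat, self._argmax[:, :, :, None, :],
                          grad[:, :, :, None, :], axis=3)
        dx = dflat.reshape(B, H // p, W // p, p, p, C).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(B, H, W, C)


class Flatten(Layer):
    def build(self, input_shape, rng, dtype):
        self._in = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...]) -> None:
        super().__init__()
        self.target = tuple(target)

    def build(self, input_shape, rng, dtype):
        if int(np.prod(input_shape)) != int(np.prod(self.target)):
            raise InvalidArgumentError(
                f"cannot reshape {input_shape} to {self.target}: element counts differ"
            )
        return self.target

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise InvalidArgumentError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise InvalidArgumentError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class LSTM(Layer):
    """LSTM with ReLU candidate/state activation (sigmoid gates).

    return_sequences=True emits (B, T, units); otherwise the final
    hidden state (B, units).
    """

    def __init__(self, units: int, return_sequences: bool = False) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences

    def build(self, input_shape, rng, dtype):
        t, d = input_shape
        u = self.units
        self.weights = {
            "Wx": _glorot(rng, (d, 4 * u), d, u, dtype),
            "Wh": _glorot(rng, (u, 4 * u), u, u, dtype),
            "b": np.zeros(4 * u, dtype=dtype),
        }
        return (t, u) if self.return_sequences else (u,)

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    def forward(self, x, training=False, rng=None):
        B, T, _ = x.shape
        u = self.units
        Wx, Wh, b = self.weights["Wx"], self.weights["Wh"], self.weights["b"]
        h = np.zeros((B, u), dtype=x.dtype)
        c = np.zeros((B, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        hs = np.empty((B, T, u), dtype=x.dtype)
        for t in range(T):
            z = x[:, t, :] @ Wx + h @ Wh + b
            i = self._sigmoid(z[:, :u])
            f = self._sigmoid(z[:, u : 2 * u])
            g = _relu(z[:, 2 * u : 3 * u])
            o = self._sigmoid(z[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            ac = _relu(c)
            h = o * ac
            hs[:, t, :] = h
            self._cache.append((h_prev, c_prev, i, f, g, o, c, ac))
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, grad):
        x = self._x
        B, T, D = x.shape
        u = self.units
        Wx, Wh = self.weights["Wx"], self.weights["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.weights["b"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, u), dtype=x.dtype)
        dc_next = np.zeros((B, u), dtype=x.dtype)
        if self.return_sequences:
            dhs = grad
        else:
            dhs = np.zeros((B, T, u), dtype=grad.dtype)
            dhs[:, -1, :] = grad
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c, ac = self._cache[t]
            dh = dhs[:, t, :] + dh_next
            do = dh * ac
            dc = dh * o * (c > 0) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (g > 0),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


class Network:
    """A feed-forward stack of layers with a softmax/cross-entropy head."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...],
                 seed: int = 0, dtype=np.float32) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng, dtype)
        self.output_shape = shape
        # separate stream for dropout so weight init is independent of training
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0]
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=self.dropout_rng)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def loss_and_grads(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        """Categorical cross-entropy; fills every layer's grads (mean over batch)."""
        probs = self.forward(x, training=True)
        B = probs.shape[0]
        eps = 1e-12
        loss = float(-np.sum(y_onehot * np.log(probs + eps)) / B)
        grad = (probs - y_onehot.astype(probs.dtype)) / B
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for layer in self.layers for w in layer.weights.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for name in layer.weights:
                layer.weights[name] = next(it).astype(self.dtype).copy()

    def iter_params(self):
        for layer in self.layers:
            for name in layer.weights:
                yield layer, name


class Adam:
    """Adam optimizer with a mutable learning rate (for schedulers)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, network: Network) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, (layer, name) in enumerate(network.iter_params()):
            g = layer.grads[name]
            if k not in self._m:
                self._m[k] = np.zeros_like(g)
                self._v[k] = np.zeros_like(g)
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            m_hat = self._m[k] / (1 - b1 ** self._t)
            v_hat = self._v[k] / (1 - b2 ** self._t)
            layer.weights[name] -= (
                self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            ).astype(layer.weights[name].dtype)
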