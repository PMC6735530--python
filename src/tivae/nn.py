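"""Minimal NumPy neural-network core with manual backpropagation.

Implements exactly the primitives the embedding and classification stages
need — dense, 1-D convolution, LSTM, batch normalization, dropout, softmax
cross-entropy and Adam — with explicit ``forward``/``backward`` passes so
every gradient can be verified against numerical differentiation (see the
test suite). All randomness (initialization, dropout masks) flows through a
``numpy.random.Generator`` supplied at construction, so training is
deterministic given a seed.

Shapes: dense layers take ``(batch, features)``; convolutions
``(batch, channels, length)``; LSTMs ``(batch, time, features)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "ReLU",
    "Sigmoid",
    "Tanh",
    "Dropout",
    "Flatten",
    "ToChannels",
    "ToSequence",
    "Conv1D",
    "BatchNorm",
    "LSTM",
    "Sequential",
    "SoftmaxCrossEntropy",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate!r}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class ToChannels(Layer):
    """(batch, length) -> (batch, 1, length) for convolution stacks."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x[:, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, 0, :]


class ToSequence(Layer):
    """(batch, features) -> (batch, time, chunk), zero-padded to a full chunk."""

    def __init__(self, chunk: int):
        if chunk <= 0:
            raise ValueError("chunk must be positive")
        self.chunk = chunk

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._n_features = x.shape[1]
        t = -(-self._n_features // self.chunk)
        padded = np.zeros((x.shape[0], t * self.chunk))
        padded[:, : self._n_features] = x
        return padded.reshape(x.shape[0], t, self.chunk)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        flat = grad.reshape(grad.shape[0], -1)
        return flat[:, : self._n_features]


class Conv1D(Layer):
    """Valid 1-D convolution with stride; input (batch, channels, length)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
    ):
        fan_in = in_channels * kernel
        self.W = Param(glorot(rng, (out_channels, in_channels, kernel), fan_in, out_channels))
        self.b = Param(np.zeros(out_channels))
        self.kernel = kernel
        self.stride = stride

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _window_index(self, length: int) -> np.ndarray:
        n_out = (length - self.kernel) // self.stride + 1
        if n_out < 1:
            raise ValueError(
                f"input length {length} shorter than kernel {self.kernel}"
            )
        starts = np.arange(n_out) * self.stride
        return starts[:, None] + np.arange(self.kernel)[None, :]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        self._idx = self._window_index(x.shape[2])
        self._windows = x[:, :, self._idx]  # (B, C, Lo, K)
        return (
            np.einsum("bclk,ock->bol", self._windows, self.W.value)
            + self.b.value[None, :, None]
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += np.einsum("bclk,bol->ock", self._windows, grad)
        self.b.grad += grad.sum(axis=(0, 2))
        dwindows = np.einsum("bol,ock->bclk", grad, self.W.value)
        dx = np.zeros(self._x_shape)
        np.add.at(dx, (slice(None), slice(None), self._idx), dwindows)
        return dx


class BatchNorm(Layer):
    """Normalize the trailing feature axis over all leading axes.

    Keeps running statistics (momentum 0.9) for evaluation-time use; works on
    both (batch, features) and (batch, time, features) inputs.
    """

    def __init__(self, n_features: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        flat = x.reshape(-1, x.shape[-1])
        if train:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (flat - mean) * self._inv_std
        self._train = train
        out = self.gamma.value * self._xhat + self.beta.value
        return out.reshape(self._shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad.reshape(-1, grad.shape[-1])
        self.gamma.grad += (g * self._xhat).sum(axis=0)
        self.beta.grad += g.sum(axis=0)
        gx = g * self.gamma.value
        if self._train:
            n = g.shape[0]
            dx = (
                self._inv_std
                / n
                * (n * gx - gx.sum(axis=0) - self._xhat * (gx * self._xhat).sum(axis=0))
            )
        else:
            dx = gx * self._inv_std
        return dx.reshape(self._shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Single LSTM layer, batch-first input (batch, time, features).

    ``return_sequences`` yields the full hidden sequence (for stacking);
    otherwise the final hidden state. Backpropagation-through-time is exact
    over the whole sequence.
    """

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ):
        h = n_hidden
        self.Wx = Param(glorot(rng, (n_in, 4 * h), n_in, 4 * h))
        self.Wh = Param(glorot(rng, (h, 4 * h), h, 4 * h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias 1: remember by default
        self.b = Param(b)
        self.n_hidden = h
        self.return_sequences = return_sequences

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        h = self.n_hidden
        self._x = x
        self._cache = []
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        outputs = np.zeros((B, T, h))
        for t in range(T):
            z = x[:, t, :] @ self.Wx.value + h_t @ self.Wh.value + self.b.value
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h : 2 * h])
            o = sigmoid(z[:, 2 * h : 3 * h])
            g = np.tanh(z[:, 3 * h :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tanh_c = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tanh_c
            outputs[:, t, :] = h_t
            self._cache.append((i, f, o, g, c_prev, tanh_c, h_prev))
        return outputs if self.return_sequences else h_t

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, T, _ = self._x.shape
        h = self.n_hidden
        if self.return_sequences:
            dout = grad
        else:
            dout = np.zeros((B, T, h))
            dout[:, -1, :] = grad
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            i, f, o, g, c_prev, tanh_c, h_prev = self._cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g**2),
                ],
                axis=1,
            )
            self.Wx.grad += self._x[:, t, :].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class SoftmaxCrossEntropy:
    """Mean softmax cross-entropy over the batch; targets are class indices."""

    def forward(self, logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        shifted = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(shifted)
        probs = exp / exp.sum(axis=1, keepdims=True)
        n = logits.shape[0]
        loss = -np.log(probs[np.arange(n), targets] + 1e-300).mean()
        grad = probs.copy()
        grad[np.arange(n), targets] -= 1.0
        return float(loss), grad / n

    @staticmethod
    def probabilities(logits: np.ndarray) -> np.ndarray:
        shifted = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(shifted)
        return exp / exp.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def numerical_gradient(fn, param: Param, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``fn()`` w.r.t. ``param`` (test helper)."""
    grad = np.zeros_like(param.value)
    flat = param.value.reshape(-1)
    gflat = grad.reshape(-1)
    for k in range(flat.size):
        orig = flat[k]
        flat[k] = orig + eps
        hi = fn()
        flat[k] = orig - eps
        lo = fn()
        flat[k] = orig
        gflat[k] = (hi - lo) / (2 * eps)
    return grad
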