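"""Minimal trainable neural-network layers on numpy arrays.

Every layer is a :class:`Module` with an explicit ``forward``/``backward``
pair; ``backward`` receives the gradient of the loss with respect to the
layer's output, accumulates parameter gradients in-place, and returns the
gradient with respect to its input.  Temporal tensors are laid out as
``(batch, time, channels)``.

The set of layers is exactly what the 1-D regression architectures here
require: dense, (dilated/strided/causal) 1-D convolution, batch
normalization, ReLU, max/global-average pooling, LSTM (with a reversal
wrapper and a concatenation container for bidirectionality), and the
structural containers Sequential / Residual.

Weights use Glorot uniform initialization; LSTM forget-gate biases start at
one.  All randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Dense",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Flatten",
    "LastStep",
    "Sequential",
    "ResidualBlock",
    "LSTM",
    "Reverse",
    "BiConcat",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Dense(Module):
    """Affine map on the last axis; applied per timestep on 3-D input."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Param(glorot(rng, (in_features, out_features), in_features, out_features))
        self.b = Param(np.zeros(out_features)) if bias else None

    def parameters(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        self._x = x
        out = x @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, grad):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.grad += x2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        return grad @ self.W.value.T


class Conv1d(Module):
    """1-D convolution with stride, dilation, and same/causal/valid padding.

    ``same`` pads symmetrically so the output length is ``ceil(T / stride)``;
    ``causal`` pads only on the left by ``(kernel-1) * dilation`` so output
    ``t`` never sees inputs later than ``t`` (output length preserved at
    stride 1).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, dilation: int = 1,
                 padding: str = "same", bias: bool = True):
        if padding not in ("same", "causal", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.cin, self.cout = in_channels, out_channels
        self.k, self.stride, self.dilation = kernel_size, stride, dilation
        self.padding = padding
        fan_in = kernel_size * in_channels
        self.W = Param(
            glorot(rng, (kernel_size * in_channels, out_channels), fan_in, out_channels)
        )
        self.b = Param(np.zeros(out_channels)) if bias else None

    def parameters(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _padding_for(self, T: int) -> tuple[int, int, int]:
        span = (self.k - 1) * self.dilation  # receptive span minus one
        if self.padding == "valid":
            t_out = (T - span - 1) // self.stride + 1
            return 0, 0, t_out
        t_out = -(-T // self.stride)  # ceil
        total = max((t_out - 1) * self.stride + span + 1 - T, 0)
        if self.padding == "causal":
            left = span
            right = max(total - left, 0)
        else:  # same
            left = total // 2
            right = total - left
        return left, right, t_out

    def forward(self, x, training=False):
        N, T, C = x.shape
        left, right, t_out = self._padding_for(T)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        idx = (
            np.arange(t_out)[:, None] * self.stride
            + np.arange(self.k)[None, :] * self.dilation
        )
        cols = xp[:, idx, :]  # (N, t_out, K, C)
        self._cols = cols
        self._shape = (N, T, left, xp.shape[1], idx)
        out = cols.reshape(N, t_out, self.k * C) @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, grad):
        N, T, left, Tp, idx = self._shape
        t_out = grad.shape[1]
        cols2 = self._cols.reshape(N * t_out, self.k * self.cin)
        g2 = grad.reshape(N * t_out, self.cout)
        self.W.grad += cols2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.T).reshape(N, t_out, self.k, self.cin)
        dxp = np.zeros((N, Tp, self.cin))
        for k in range(self.k):
            # idx[:, k] is strictly increasing (stride >= 1): no duplicates
            dxp[:, idx[:, k], :] += dcols[:, :, k, :]
        return dxp[:, left : left + T, :]


class BatchNorm1d(Module):
    """Batch normalization over batch (and time) per channel."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivar
        self._cache = (xhat, ivar, axes, x.shape)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad):
        xhat, ivar, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value
        # batch-statistics backward (training mode); in eval mode stats are
        # constants and the extra terms vanish, but backward is only used in
        # training
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * ivar
        return dx


class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Module):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training=False):
        N, T, C = x.shape
        t_out = T // self.pool
        xt = x[:, : t_out * self.pool, :].reshape(N, t_out, self.pool, C)
        self._argmax = xt.argmax(axis=2)
        self._shape = (N, T, C, t_out)
        return xt.max(axis=2)

    def backward(self, grad):
        N, T, C, t_out = self._shape
        dx = np.zeros((N, t_out, self.pool, C))
        n_i, t_i, c_i = np.meshgrid(
            np.arange(N), np.arange(t_out), np.arange(C), indexing="ij"
        )
        dx[n_i, t_i, self._argmax, c_i] = grad
        out = np.zeros((N, T, C))
        out[:, : t_out * self.pool, :] = dx.reshape(N, t_out * self.pool, C)
        return out


class GlobalAvgPool1d(Module):
    def forward(self, x, training=False):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._T, axis=1) / self._T


class Flatten(Module):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class LastStep(Module):
    """Select the final timestep of a (N, T, C) sequence."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, grad):
        out = np.zeros(self._shape)
        out[:, -1, :] = grad
        return out


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Module):
    """Two conv+BN stages with a skip connection.

    Main branch: Conv(k, stride) - BN - ReLU - Conv(k, 1) - BN.  The skip is
    the identity when shapes match, otherwise a 1x1 convolution (with BN) at
    the block's stride.  The branch output is *added* to the skip with no
    activation after the sum, so zeroing the branch weights makes the block
    the (shape-matched) identity exactly.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: str = "same"):
        # convolutions feeding batch norm are bias-free: BN's shift makes a
        # conv bias a null direction
        self.main = Sequential(
            Conv1d(in_channels, out_channels, kernel_size, rng, stride=stride,
                   padding=padding, bias=False),
            BatchNorm1d(out_channels),
            ReLU(),
            Conv1d(out_channels, out_channels, kernel_size, rng, padding=padding,
                   bias=False),
            BatchNorm1d(out_channels),
        )
        if in_channels == out_channels and stride == 1:
            self.shortcut: Module | None = None
        else:
            self.shortcut = Sequential(
                Conv1d(in_channels, out_channels, 1, rng, stride=stride,
                       padding=padding, bias=False),
                BatchNorm1d(out_channels),
            )

    def parameters(self) -> list[Param]:
        ps = self.main.parameters()
        if self.shortcut is not None:
            ps = ps + self.shortcut.parameters()
        return ps

    def shortcut_out(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x if self.shortcut is None else self.shortcut.forward(x, training)

    def forward(self, x, training=False):
        main = self.main.forward(x, training=training)
        skip = x if self.shortcut is None else self.shortcut.forward(x, training=training)
        return main + skip

    def backward(self, grad):
        d_main = self.main.backward(grad)
        d_skip = grad if self.shortcut is None else self.shortcut.backward(grad)
        return d_main + d_skip


class LSTM(Module):
    """Single LSTM layer returning the full hidden-state sequence.

    Gate order in the packed weight matrices is (input i, forget f,
    candidate g, output o):

        i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)
        f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)
        g_t = tanh   (W_g [h_{t-1}, x_t] + b_g)
        o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)
        c_t = f_t * c_{t-1} + i_t * g_t
        h_t = o_t * tanh(c_t)

    The forget-gate bias is initialized to one.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        H, I = hidden_size, input_size
        self.H = H
        self.Wx = Param(glorot(rng, (I, 4 * H), I + H, H))
        self.Wh = Param(glorot(rng, (H, 4 * H), I + H, H))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget bias
        self.b = Param(b)

    def parameters(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    def step(self, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray):
        """One cell update; returns (h_t, c_t, gates) for inspection/tests."""
        H = self.H
        z = x_t @ self.Wx.value + h_prev @ self.Wh.value + self.b.value
        i = self._sigmoid(z[:, :H])
        f = self._sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = self._sigmoid(z[:, 3 * H :])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return h, c, (i, f, g, o)

    def forward(self, x, training=False):
        N, T, _ = x.shape
        H = self.H
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        hs = np.empty((N, T, H))
        cache = []
        for t in range(T):
            h_prev, c_prev = h, c
            h, c, gates = self.step(x[:, t, :], h_prev, c_prev)
            hs[:, t, :] = h
            cache.append((x[:, t, :], h_prev, c_prev, c, gates))
        self._cache = cache
        return hs

    def backward(self, grad):
        cache = self._cache
        N, T, H = grad.shape[0], len(cache), self.H
        dx = np.empty((N, T, self.Wx.value.shape[0]))
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, c, (i, f, g, o) = cache[t]
            dh = grad[:, t, :] + dh_next
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.Wx.grad += x_t.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return dx


class Reverse(Module):
    """Flip the time axis (wraps an LSTM to run it backwards in time)."""

    def forward(self, x, training=False):
        return x[:, ::-1, :]

    def backward(self, grad):
        return grad[:, ::-1, :]


class BiConcat(Module):
    """Run two branches on the same input; concatenate outputs channel-wise.

    With branches ``LSTM`` and ``Reverse-LSTM-Reverse`` this is a
    bidirectional recurrent layer.
    """

    def __init__(self, forward_branch: Module, backward_branch: Module):
        self.fwd = forward_branch
        self.bwd = backward_branch

    def parameters(self) -> list[Param]:
        return self.fwd.parameters() + self.bwd.parameters()

    def forward(self, x, training=False):
        a = self.fwd.forward(x, training=training)
        b = self.bwd.forward(x, training=training)
        self._split = a.shape[-1]
        return np.concatenate([a, b], axis=-1)

    def backward(self, grad):
        s = self._split
        return self.fwd.backward(grad[..., :s]) + self.bwd.backward(grad[..., s:])
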