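"""Neural-network layers as fused autodiff nodes.

Each layer owns its parameter :class:`~stepop.nn.core.Tensor` objects and
implements a hand-written backward pass registered on a single graph node.
Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, time, features) for recurrent ones.
"""

from __future__ import annotations

import numpy as np

from .core import Tensor, accumulate, node, value, _sigmoid


class Layer:
    def parameters(self) -> list[Tensor]:
        return []

    def state_dict(self) -> dict:
        return {}

    def load_state(self, state: dict) -> None:
        pass


def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Tensor(_glorot(rng, (n_in, n_out), dtype), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x) -> Tensor:
        xv = value(x)
        W, b = self.W, self.b

        def backward(g):
            accumulate(W, xv.T @ g)
            accumulate(b, g.sum(axis=0))
            if isinstance(x, Tensor):
                accumulate(x, g @ W.data.T)

        return node(xv @ W.data + b.data, [x, W, b], backward)

    def parameters(self):
        return [self.W, self.b]


class Conv1d(Layer):
    """Valid-mode 1-D convolution, stride 1; x is (N, C_in, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = Tensor(
            (rng.standard_normal((c_out, c_in, kernel)) * scale).astype(dtype),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.kernel = kernel

    def __call__(self, x) -> Tensor:
        xv = value(x)
        K = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(xv, K, axis=2)  # (N,C,Lo,K)
        out = np.einsum("nclk,fck->nfl", win, self.W.data, optimize=True) + self.b.data[:, None]
        W, b = self.W, self.b

        def backward(g):
            accumulate(W, np.einsum("nclk,nfl->fck", win, g, optimize=True))
            accumulate(b, g.sum(axis=(0, 2)))
            if isinstance(x, Tensor) and x.requires_grad:
                gx = np.zeros_like(xv)
                Lo = g.shape[2]
                for k in range(K):
                    gx[:, :, k : k + Lo] += np.einsum(
                        "nfl,fc->ncl", g, W.data[:, :, k], optimize=True
                    )
                accumulate(x, gx)

        return node(out, [x, W, b], backward)

    def parameters(self):
        return [self.W, self.b]


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and length axes of (N, C, L)."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training: bool) -> Tensor:
        xv = value(x)
        if training:
            mu = xv.mean(axis=(0, 2))
            var = xv.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu = self.running_mean.astype(xv.dtype)
            var = self.running_var.astype(xv.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xv - mu[:, None]) * inv[:, None]
        out = self.gamma.data[:, None] * xhat + self.beta.data[:, None]
        gamma, beta = self.gamma, self.beta

        def backward(g):
            accumulate(gamma, (g * xhat).sum(axis=(0, 2)))
            accumulate(beta, g.sum(axis=(0, 2)))
            if isinstance(x, Tensor) and x.requires_grad:
                gxhat = g * gamma.data[:, None]
                if training:
                    m = xv.shape[0] * xv.shape[2]
                    s1 = gxhat.sum(axis=(0, 2))[:, None]
                    s2 = (gxhat * xhat).sum(axis=(0, 2))[:, None]
                    gx = (inv[:, None] / m) * (m * gxhat - s1 - xhat * s2)
                else:
                    gx = gxhat * inv[:, None]
                accumulate(x, gx)

        return node(out.astype(xv.dtype), [x, gamma, beta], backward)

    def parameters(self):
        return [self.gamma, self.beta]

    def state_dict(self):
        return {"running_mean": self.running_mean.copy(), "running_var": self.running_var.copy()}

    def load_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing samples that do not fill a
    window are dropped."""

    def __init__(self, pool: int):
        self.pool = pool

    def __call__(self, x) -> Tensor:
        xv = value(x)
        p = self.pool
        N, C, L = xv.shape
        Lp = (L // p) * p
        xr = xv[:, :, :Lp].reshape(N, C, Lp // p, p)
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

        def backward(g):
            if isinstance(x, Tensor) and x.requires_grad:
                gr = np.zeros((N, C, Lp // p, p), dtype=xv.dtype)
                np.put_along_axis(gr, idx[..., None], g[..., None], axis=3)
                gx = np.zeros_like(xv)
                gx[:, :, :Lp] = gr.reshape(N, C, Lp)
                accumulate(x, gx)

        return node(out, [x], backward)


def global_avg_pool(x) -> Tensor:
    """(N, C, L) -> (N, C) mean over length."""
    xv = value(x)
    L = xv.shape[2]

    def backward(g):
        accumulate(x, np.repeat(g[:, :, None] / L, L, axis=2))

    return node(xv.mean(axis=2), [x], backward)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def __call__(self, x, training: bool) -> Tensor:
        if not training or self.rate <= 0.0:
            return x if isinstance(x, Tensor) else Tensor(value(x))
        xv = value(x)
        keep = 1.0 - self.rate
        mask = (self.rng.random(xv.shape) < keep).astype(xv.dtype) / keep

        def backward(g):
            accumulate(x, g * mask)

        return node(xv * mask, [x], backward)


class LSTMCell(Layer):
    """One direction of one LSTM layer; gate order is (i, f, g, o).

    Forward precomputes the input projection for all time steps in a single
    matrix product, then iterates the recurrence; backward is a hand-written
    backpropagation-through-time pass over cached gate activations.
    """

    def __init__(self, n_in: int, hidden: int, rng, dtype=np.float32, reverse: bool = False):
        self.hidden = hidden
        self.reverse = reverse
        self.Wih = Tensor(_glorot(rng, (n_in, 4 * hidden), dtype), requires_grad=True)
        self.Whh = Tensor(_glorot(rng, (hidden, 4 * hidden), dtype), requires_grad=True)
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x) -> Tensor:
        xv = value(x)
        N, T, I = xv.shape
        H = self.hidden
        Wih, Whh, b = self.Wih, self.Whh, self.b
        pre = (xv.reshape(N * T, I) @ Wih.data).reshape(N, T, 4 * H) + b.data
        order = range(T - 1, -1, -1) if self.reverse else range(T)

        h = np.zeros((N, H), dtype=xv.dtype)
        c = np.zeros((N, H), dtype=xv.dtype)
        out = np.empty((N, T, H), dtype=xv.dtype)
        cache = []
        for t in order:
            z = pre[:, t] + h @ Whh.data
            i_ = _sigmoid(z[:, :H])
            f_ = _sigmoid(z[:, H : 2 * H])
            g_ = np.tanh(z[:, 2 * H : 3 * H])
            o_ = _sigmoid(z[:, 3 * H :])
            c_new = f_ * c + i_ * g_
            tc = np.tanh(c_new)
            cache.append((t, h, c, i_, f_, g_, o_, tc))
            h = o_ * tc
            c = c_new
            out[:, t] = h

        def backward(gout):
            dWhh = np.zeros_like(Whh.data)
            dpre = np.empty((N, T, 4 * H), dtype=xv.dtype)
            dh = np.zeros((N, H), dtype=xv.dtype)
            dc = np.zeros((N, H), dtype=xv.dtype)
            for t, h_prev, c_prev, i_, f_, g_, o_, tc in reversed(cache):
                dh_t = gout[:, t] + dh
                do = dh_t * tc
                dcn = dc + dh_t * o_ * (1.0 - tc * tc)
                di = dcn * g_
                df = dcn * c_prev
                dg = dcn * i_
                dc = dcn * f_
                dz = np.concatenate(
                    [
                        di * i_ * (1.0 - i_),
                        df * f_ * (1.0 - f_),
                        dg * (1.0 - g_ * g_),
                        do * o_ * (1.0 - o_),
                    ],
                    axis=1,
                )
                dWhh += h_prev.T @ dz
                dh = dz @ Whh.data.T
                dpre[:, t] = dz
            accumulate(Whh, dWhh)
            accumulate(b, dpre.sum(axis=(0, 1)))
            flat = dpre.reshape(N * T, 4 * H)
            accumulate(Wih, xv.reshape(N * T, I).T @ flat)
            if isinstance(x, Tensor) and x.requires_grad:
                accumulate(x, (flat @ Wih.data.T).reshape(N, T, I))

        return node(out, [x, Wih, Whh, b], backward)

    def parameters(self):
        return [self.Wih, self.Whh, self.b]
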