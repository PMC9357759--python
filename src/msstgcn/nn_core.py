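"""Minimal numpy neural-network core used by the classifier.

Activations flow channel-last as ``(N, T, V, C)`` — batch, frames, joints,
channels — so that every channel transform is a single BLAS matrix product
on the trailing axis.  Each layer caches what its backward pass needs during
``forward`` and releases it after ``backward``; gradients accumulate into
``Parameter.grad`` and are consumed by :class:`SGD`.

All backward passes are verified against central-difference numeric
gradients in the test suite (layers accept ``dtype=np.float64`` for that
purpose; training uses float32).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "PointwiseConv",
    "TemporalConv",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "Linear",
    "SGD",
    "softmax",
    "cross_entropy_with_grad",
    "temporal_padding",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name}, shape={self.value.shape})"


class Module:
    """Base class: explicit registration of parameters and submodules."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def register(self, name: str, value: np.ndarray) -> Parameter:
        p = Parameter(name, value)
        self._params[name] = p
        return p

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self) -> "Module":
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _kaiming(rng: np.random.Generator, fan_in: int, shape, dtype) -> np.ndarray:
    scale = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * scale).astype(dtype)


class PointwiseConv(Module):
    """1×1 channel transform on the trailing axis: ``y = x W + b``.

    Optionally subsamples the frame axis by ``stride`` (used by residual
    paths when a block strides time).
    """

    def __init__(self, c_in, c_out, *, bias=True, stride=1,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.weight = self.register("weight", _kaiming(rng, c_in, (c_in, c_out), dtype))
        self.bias = self.register("bias", np.zeros(c_out, dtype=dtype)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t_in = x.shape[1]
        if self.stride > 1:
            x = x[:, :: self.stride]
        self._x = x
        y = x @ self.weight.value
        if self.bias is not None:
            y += self.bias.value
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        self.weight.grad += np.tensordot(x, grad, axes=([0, 1, 2], [0, 1, 2]))
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 1, 2))
        gx = grad @ self.weight.value.T
        del self._x
        if self.stride > 1:
            full = np.zeros(
                (gx.shape[0], self._t_in) + gx.shape[2:], dtype=gx.dtype
            )
            full[:, :: self.stride] = gx
            gx = full
        return gx


def temporal_padding(kernel: int) -> tuple[int, int]:
    """Same-padding split for a frame-axis kernel: left ⌈(k−1)/2⌉, right ⌊(k−1)/2⌋."""
    return (kernel - 1 + 1) // 2, (kernel - 1) // 2


class TemporalConv(Module):
    """Convolution along the frame axis, independent per joint.

    Input ``(N, T, V, C_in)`` → output ``(N, ceil(T/stride), V, C_out)``
    with same-padding.  Implemented by gathering each output position's
    ``kernel × C_in`` receptive field into one matrix (im2col) so the whole
    convolution is a single BLAS product.
    """

    def __init__(self, c_in, c_out, kernel, *, stride=1, bias=True,
                 rng=None, dtype=np.float32):
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.stride = stride
        self.c_in = c_in
        self.weight = self.register(
            "weight", _kaiming(rng, c_in * kernel, (kernel, c_in, c_out), dtype)
        )
        self.bias = self.register("bias", np.zeros(c_out, dtype=dtype)) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, t, v, c = x.shape
        k = self.kernel
        left, right = temporal_padding(k)
        xp = np.pad(x, ((0, 0), (left, right), (0, 0), (0, 0)))
        t_out = (t + left + right - k) // self.stride + 1
        # (N, T_out, V, C, k) windows over the padded frame axis
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        win = win[:, :: self.stride] if self.stride > 1 else win
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3)).reshape(
            n * t_out * v, k * c
        )
        w2 = self.weight.value.reshape(k * c, -1)
        y = (cols @ w2).reshape(n, t_out, v, -1)
        if self.bias is not None:
            y += self.bias.value
        self._cols, self._shape = cols, (n, t, v, c, t_out, left)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, t, v, c, t_out, left = self._shape
        k = self.kernel
        gflat = grad.reshape(n * t_out * v, -1)
        # (gᵀ cols)ᵀ is markedly faster than colsᵀ g for these skinny shapes
        self.weight.grad += (gflat.T @ self._cols).T.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += gflat.sum(axis=0)
        w2 = self.weight.value.reshape(k * c, -1)
        gcols = (gflat @ w2.T).reshape(n, t_out, v, k, c)
        del self._cols
        # kernel-tap-leading contiguous layout makes the scatter adds stream
        gk = np.ascontiguousarray(gcols.transpose(3, 0, 1, 2, 4))
        lpad, rpad = temporal_padding(k)
        gxp = np.zeros((n, t + lpad + rpad, v, c), dtype=grad.dtype)
        for i in range(k):
            gxp[:, i : i + self.stride * t_out : self.stride] += gk[i]
        return gxp[:, left : left + t]


class BatchNorm(Module):
    """Batch normalization over all axes except the trailing channel axis."""

    def __init__(self, num_features, *, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.register("gamma", np.ones(num_features, dtype=dtype))
        self.beta = self.register("beta", np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value
        if not self.training:
            del self._cache
            return g * inv_std
        m = np.prod([xhat.shape[a] for a in axes])
        gx = (g - g.mean(axis=axes) - xhat * (g * xhat).sum(axis=axes) / m) * inv_std
        del self._cache
        return gx


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        del self._mask
        return g


class Dropout(Module):
    """Inverted dropout; identity in eval mode or at p = 0."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Linear(Module):
    def __init__(self, c_in, c_out, *, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = self.register("weight", _kaiming(rng, c_in, (c_in, c_out), dtype))
        self.bias = self.register("bias", np.zeros(c_out, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        gx = grad @ self.weight.value.T
        del self._x
        return gx


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stable."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits.astype(np.float64))
    nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(nll.mean()), (grad / n).astype(logits.dtype)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class Adam:
    """Adam optimizer (optional alternative to SGD)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1 - self.b1 ** self._t
        b2t = 1 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
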