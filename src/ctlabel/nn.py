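"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical engine behind the segmentation models: a taped
``Tensor`` with exactly the operations a 2-D encoder-decoder network needs
(convolution, batch normalisation, max-pooling, nearest upsampling, channel
concatenation, elementwise arithmetic and reductions) plus an Adam optimiser.
Gradients are accumulated by topological replay of the tape, as in any
define-by-run framework.

Convolutions are evaluated as a sum of ``kh * kw`` strided tensor
contractions (one per kernel offset) so both the forward and backward passes
run through BLAS; no im2col buffer is materialised.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def pow(self, exponent: float):
        """Elementwise power with a constant, non-negative-base exponent."""
        base = self.data

        def backward(g):
            if self.requires_grad:
                # d/dx x^e = e*x^(e-1); guard x=0 with fractional exponents
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = exponent * np.power(base, exponent - 1.0)
                d = np.where(np.isfinite(d), d, 0.0)
                self._accum(g * d)

        return Tensor._make(np.power(base, exponent), (self,), backward)

    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size
        return self.sum() * (1.0 / n)

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    # -- backward driver -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


# ---------------------------------------------------------------------------
# Spatial operations
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    f, cw, kh, kw = wd.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    s, p = stride, padding
    ho = (h + 2 * p - kh) // s + 1
    wo = (wid + 2 * p - kw) // s + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    out = np.zeros((n, f, ho, wo), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
            # (N,C,Ho,Wo) x (F,C) over C -> (N,Ho,Wo,F)
            out += np.tensordot(xs, wd[:, :, i, j], axes=([1], [1])).transpose(
                0, 3, 1, 2
            )

    def backward(g):
        if w.requires_grad:
            dw = np.empty_like(wd)
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
                if w.requires_grad:
                    dw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
                if dxp is not None:
                    dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.tensordot(
                        g, wd[:, :, i, j], axes=([1], [0])
                    ).transpose(0, 3, 1, 2)
        if w.requires_grad:
            w._accum(dw)
        if dxp is not None:
            x._accum(dxp[:, :, p : p + h, p : p + wid] if p else dxp)

    return Tensor._make(out, (x, w), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial dims")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(n, c, h // 2, w // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=x.data.dtype)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dr.reshape(n, c, h, w))

    return Tensor._make(out, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        if not x.requires_grad:
            return
        n, c, h, w = x.data.shape
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]
    out = np.concatenate([t.data for t in tensors], axis=1)

    def backward(g):
        for t, gp in zip(tensors, np.split(g, splits, axis=1)):
            if t.requires_grad:
                t._accum(gp)

    return Tensor._make(out, tensors, backward)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Base class with torch-style named parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for k, p in self._params.items():
            out[prefix + k] = p.data
        for k, v in getattr(self, "_buffers", {}).items():
            out[prefix + k] = v
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for k, p in self._params.items():
            key = prefix + k
            if key not in state:
                raise KeyError(f"missing parameter: {key}")
            if state[key].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: "
                    f"{state[key].shape} vs {p.data.shape}"
                )
            p.data = state[key].astype(p.data.dtype)
        for k in getattr(self, "_buffers", {}):
            key = prefix + k
            if key not in state:
                raise KeyError(f"missing buffer: {key}")
            self._buffers[k] = state[key].copy()
        for k, m in self._modules.items():
            m.load_state_dict(state, prefix + k + ".")

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class ModuleList(Module):
    def __init__(self, modules):
        super().__init__()
        self._items = list(modules)
        for i, m in enumerate(self._items):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def __len__(self):
        return len(self._items)


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, stride=1, padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros((1, c_out, 1, 1), DTYPE), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.stride, self.padding)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1, 1), DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), DTYPE), requires_grad=True)
        object.__setattr__(
            self,
            "_buffers",
            {
                "running_mean": np.zeros((1, channels, 1, 1), DTYPE),
                "running_var": np.ones((1, channels, 1, 1), DTYPE),
            },
        )
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mean = x.data.mean(axis=axes, keepdims=True)
            var = x.data.var(axis=axes, keepdims=True)
            m = self.momentum
            nred = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            bessel = nred / max(nred - 1, 1)
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mean
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var * bessel
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean) * invstd
        out = self.gamma.data * xhat + self.beta.data
        gamma, beta, training = self.gamma, self.beta, self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes, keepdims=True))
            if not x.requires_grad:
                return
            if training:
                nred = g.shape[0] * g.shape[2] * g.shape[3]
                gsum = g.sum(axis=axes, keepdims=True)
                gxsum = (g * xhat).sum(axis=axes, keepdims=True)
                dx = (gamma.data * invstd / nred) * (nred * g - gsum - xhat * gxsum)
            else:
                dx = gamma.data * invstd * g
            x._accum(dx.astype(x.data.dtype))

        return Tensor._make(out.astype(x.data.dtype), (x, gamma, beta), backward)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
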