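"""Neural-network layer stack on top of :mod:`pestdet.autograd`.

Conventions
-----------
* Tensor layout is NCHW, float32.
* Spatial "same" padding uses edge replication rather than zeros.  With edge
  padding a per-channel-constant feature map convolves to an exactly constant
  map, which is what makes channel pruning with bias absorption exactly
  function-preserving (see :mod:`pestdet.sparsity_pruning`).
* Grouped convolution supports the two cases the architectures use: dense
  (groups=1) and depthwise (groups == in_channels == out_channels).
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential",
    "Conv2d", "BatchNorm2d", "SiLU", "TS", "Identity",
    "conv2d", "maxpool2d_same", "upsample_nearest", "SGD",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


# ---------------------------------------------------------------------------
# fused primitives
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
    return cols.reshape(n, c, k * k, ho * wo)


def _col2im(dcols: np.ndarray, shape, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    n, c, hp, wp = shape
    dxp = np.zeros(shape, dtype=np.float32)
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, i, j]
    return dxp


def _fold_edge_pad(dxp: np.ndarray, p: int) -> np.ndarray:
    """Adjoint of np.pad(..., mode='edge') with symmetric pad p."""
    if p == 0:
        return dxp
    h = dxp.shape[2] - 2 * p
    w = dxp.shape[3] - 2 * p
    tmp = dxp[:, :, p:p + h, :].copy()
    tmp[:, :, 0, :] += dxp[:, :, :p, :].sum(axis=2)
    tmp[:, :, -1, :] += dxp[:, :, p + h:, :].sum(axis=2)
    dx = tmp[:, :, :, p:p + w].copy()
    dx[:, :, :, 0] += tmp[:, :, :, :p].sum(axis=3)
    dx[:, :, :, -1] += tmp[:, :, :, p + w:].sum(axis=3)
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int | None = None, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) with edge 'same' padding."""
    cout, cin_g, k, _ = weight.shape
    n, cin, h, w = x.shape
    p = k // 2 if padding is None else padding
    if groups == 1:
        if cin_g != cin:
            raise ValueError(f"conv2d: expected {cin_g} input channels, got {cin}")
    elif not (groups == cin == cout and cin_g == 1):
        raise ValueError("conv2d: only dense (groups=1) or depthwise convolutions supported")

    ho = (h + 2 * p - k) // stride + 1
    wo = (w + 2 * p - k) // stride + 1

    if k == 1 and p == 0 and groups == 1:
        return _conv1x1(x, weight, bias, stride, ho, wo)

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge") if p else x.data
    cols = _im2col(xp, k, stride, ho, wo)  # (n, cin, k*k, L)

    if groups == 1:
        w2 = weight.data.reshape(cout, cin * k * k)
        out = np.matmul(w2[None], cols.reshape(n, cin * k * k, ho * wo))
    else:  # depthwise
        w2 = weight.data.reshape(cout, k * k)
        out = np.einsum("nckl,ck->ncl", cols, w2, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None]
    out = out.reshape(n, cout, ho, wo)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g, node):
        gf = g.reshape(n, cout, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gf.sum(axis=(0, 2)))
        if groups == 1:
            if weight.requires_grad:
                dw = np.tensordot(gf, cols.reshape(n, cin * k * k, ho * wo), axes=([0, 2], [0, 2]))
                weight._accum(dw.reshape(weight.shape))
            if x.requires_grad:
                dcols = np.matmul(w2.T[None], gf)
        else:
            if weight.requires_grad:
                dw = np.einsum("ncl,nckl->ck", gf, cols, optimize=True)
                weight._accum(dw.reshape(weight.shape))
            if x.requires_grad:
                dcols = gf[:, :, None, :] * w2[None, :, :, None]
        if x.requires_grad:
            dxp = _col2im(dcols.reshape(n, cin, k * k, ho * wo), xp.shape, k, stride, ho, wo)
            x._accum(_fold_edge_pad(dxp, p))

    return Tensor._node(out, parents, bw)


def _conv1x1(x: Tensor, weight: Tensor, bias, stride: int, ho: int, wo: int) -> Tensor:
    """Pointwise convolution as a single matmul (no im2col)."""
    n, cin, h, w = x.shape
    cout = weight.shape[0]
    xd = x.data[:, :, ::stride, ::stride] if stride > 1 else x.data
    xf = np.ascontiguousarray(xd).reshape(n, cin, ho * wo)
    w2 = weight.data.reshape(cout, cin)
    out = np.matmul(w2[None], xf)
    if bias is not None:
        out = out + bias.data[None, :, None]
    out = out.reshape(n, cout, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g, node):
        gf = g.reshape(n, cout, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gf.sum(axis=(0, 2)))
        if weight.requires_grad:
            dw = np.tensordot(gf, xf, axes=([0, 2], [0, 2]))
            weight._accum(dw.reshape(weight.shape))
        if x.requires_grad:
            dxf = np.matmul(w2.T[None], gf).reshape(n, cin, ho, wo)
            if stride > 1:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxf
            else:
                dx = dxf
            x._accum(dx)

    return Tensor._node(out, parents, bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch norm over (N, H, W) per channel.

    Returns (out, batch_mean, batch_var) with biased variance.
    """
    n, c, h, w = x.shape
    m = n * h * w
    mu = x.data.mean(axis=(0, 2, 3))
    xc = x.data - mu[None, :, None, None]
    var = np.einsum("nchw,nchw->c", xc, xc) / m
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g, node):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        dgamma = np.einsum("nchw,nchw->c", g, xhat)
        if gamma.requires_grad:
            gamma._accum(dgamma)
        if x.requires_grad:
            gsum = g.sum(axis=(0, 2, 3))
            dx = (gamma.data * inv / m)[None, :, None, None] * (
                m * g - gsum[None, :, None, None] - xhat * dgamma[None, :, None, None])
            x._accum(dx.astype(np.float32))

    return Tensor._node(out.astype(np.float32), (x, gamma, beta), bw), mu, var


def channel_affine(x: Tensor, gamma: Tensor, beta: Tensor,
                   scale: np.ndarray, shift: np.ndarray):
    """Eval-mode batch norm: y = gamma*scale*x + (gamma*shift + beta), with
    scale/shift the frozen 1/sqrt(var+eps) and -mean/sqrt(var+eps)."""
    a = (gamma.data * scale)[None, :, None, None]
    b = (gamma.data * shift + beta.data)[None, :, None, None]
    out = a * x.data + b

    def bw(g, node):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum(np.einsum("nchw,nchw->c", g, x.data) * scale
                         + g.sum(axis=(0, 2, 3)) * shift)
        if x.requires_grad:
            x._accum(g * a)

    return Tensor._node(out, (x, gamma, beta), bw)


def maxpool2d_same(x: Tensor, k: int) -> Tensor:
    """Max pool with stride 1 and 'same' output size (-inf padded)."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                mode="constant", constant_values=-np.inf)
    cols = _im2col(xp, k, 1, h, w)  # (n, c, k*k, h*w)
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :].reshape(n, c, h, w)

    def bw(g, node):
        if not x.requires_grad:
            return
        gf = g.reshape(n, c, h * w)
        dcols = np.zeros_like(cols)
        np.put_along_axis(dcols, arg[:, :, None, :], gf[:, :, None, :], axis=2)
        dxp = _col2im(dcols, xp.shape, k, 1, h, w)
        x._accum(dxp[:, :, p:p + h, p:p + w])

    return Tensor._node(out, (x,), bw)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    def bw(g, node):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    return Tensor._node(out, (x,), bw)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield (prefix + k, p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield (prefix.rstrip("."), self)
        for k, m in self._modules.items():
            yield from m.named_modules(prefix + k + ".")

    def modules(self):
        for _, m in self.named_modules():
            yield m

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                d[mname + ".running_mean"] = m.running_mean.copy()
                d[mname + ".running_var"] = m.running_var.copy()
        return d

    def load_state_dict(self, d: dict):
        for name, p in self.named_parameters():
            p.data = np.asarray(d[name], dtype=np.float32).reshape(p.data.shape)
        for mname, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(d[mname + ".running_mean"], dtype=np.float32)
                m.running_var = np.asarray(d[mname + ".running_var"], dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = []
        for m in mods:
            self._modules[str(len(self._list))] = m
            self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Conv2d(Module):
    """Convolution layer; He-normal weight init, optional bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel_size ** 2
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(
            rng.standard_normal(
                (out_channels, in_channels // groups, kernel_size, kernel_size),
                dtype=np.float32) * std)
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.last_in_hw = None
        self.last_out_hw = None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, stride=self.stride, groups=self.groups)
        self.last_in_hw = x.shape[2:]
        self.last_out_hw = out.shape[2:]
        return out


class BatchNorm2d(Module):
    """Batch normalization: z_out = gamma * (z_in - mu) / sqrt(var + eps) + beta.

    `prunable` marks whether the channel-pruning workflow may remove channels
    of this layer (set False on stems, heads and otherwise-constrained BNs).
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.prunable = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = batch_norm(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
            return out
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return channel_affine(x, self.gamma, self.beta, inv,
                              -self.running_mean * inv)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        from .autograd import silu
        return silu(x)


class TS(Module):
    """Tanh-Softplus activation: TS(x) = tanh(x) * log(1 + e^x)."""

    def forward(self, x: Tensor) -> Tensor:
        from .autograd import ts
        return ts(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SGD:
    """SGD with classical momentum and decoupled L2 weight decay on the gradient."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= np.float32(self.lr) * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
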