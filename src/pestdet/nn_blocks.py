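"""Building blocks for the lightweight pest detector.

Contents: the Tanh-Softplus (TS) activation, the ghost module and its
conv-cost model, efficient channel attention (ECA), the ghost-bottleneck
block with ECA inserted (GE block), the Focus stem slicing, spatial pyramid
pooling, the CBS/CBT conv-BN-activation unit and a standalone batch-norm
transform used by the pruning maths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, concat, softplus

__all__ = [
    "GhostSpec", "EcaSpec", "BnParams",
    "ts_activation", "eca_kernel_size", "conv_cost", "ghost_cost", "bn_forward",
    "focus_forward", "unfocus", "spp_forward",
    "ConvBnAct", "Focus", "SPPBottleneck", "EcaLayer", "GhostModule",
    "GhostBottleneckGE", "make_activation",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GhostSpec:
    """Shape/cost descriptor of one ghost module.

    ``c`` input channels, ``n`` output channels, ``k`` primary kernel size,
    ``s`` split factor (1 = plain convolution), ``stride`` and the output
    spatial size ``out_h`` x ``out_w``.
    """
    c: int
    n: int
    k: int
    s: int
    stride: int = 1
    out_h: int = 1
    out_w: int = 1

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("ghost split s must be >= 1")
        if self.n % self.s:
            raise ValueError(f"out_channels n={self.n} not divisible by split s={self.s}")
        if self.k % 2 == 0:
            raise ValueError("kernel size must be odd")


@dataclass(frozen=True)
class EcaSpec:
    """ECA configuration; ``kernel=None`` derives k from the channel count."""
    channels: int
    kernel: int | None = None
    gamma: int = 2
    b: int = 1

    def resolved_kernel(self) -> int:
        k = self.kernel if self.kernel is not None else eca_kernel_size(
            self.channels, self.gamma, self.b)
        if k < 1 or k % 2 == 0:
            raise ValueError("ECA kernel must be odd and >= 1")
        return k


@dataclass
class BnParams:
    """Learned batch-norm parameters plus the batch statistics they normalize by."""
    gamma: np.ndarray
    beta: np.ndarray
    batch_mean: np.ndarray
    batch_std: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.batch_mean = np.asarray(self.batch_mean, dtype=np.float64)
        self.batch_std = np.asarray(self.batch_std, dtype=np.float64)
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        n = len(self.gamma)
        if not (len(self.beta) == len(self.batch_mean) == len(self.batch_std) == n):
            raise ValueError("BnParams arrays must share channel length")


# ---------------------------------------------------------------------------
# scalar / array operations
# ---------------------------------------------------------------------------

def ts_activation(x):
    """TS(x) = tanh(x) * softplus(x), with softplus = max(x,0) + log1p(e^-|x|)."""
    x = np.asarray(x, dtype=np.float64)
    sp = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    out = np.tanh(x) * sp
    return out if out.ndim else float(out)


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel size: nearest odd integer to log2(C)/gamma + b/gamma.

    Ties (x exactly midway between two odd integers) round up.  Result is
    always an odd integer >= 1.
    """
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    x = np.log2(channels) / gamma + b / gamma
    # odd integers are 2m+1; nearest with round-half-up on m
    m = int(np.floor((x - 1.0) / 2.0 + 0.5))
    return max(1, 2 * m + 1)


def conv_cost(spec: GhostSpec) -> int:
    """Multiplication count of a dense convolution: h'·w'·n·k²·c."""
    return spec.out_h * spec.out_w * spec.n * spec.k ** 2 * spec.c


def ghost_cost(spec: GhostSpec) -> int:
    """Ghost-module cost: primary conv on n/s channels plus (s-1) cheap
    per-channel transforms: h'·w'·(n/s)·k²·c + (s-1)·h'·w'·(n/s)·k²."""
    m = spec.n // spec.s
    hw = spec.out_h * spec.out_w
    return hw * m * spec.k ** 2 * spec.c + (spec.s - 1) * hw * m * spec.k ** 2


def bn_forward(z_in: np.ndarray, params: BnParams) -> np.ndarray:
    """Per-channel z_out = gamma*(z - mu)/sqrt(sigma^2 + eps) + beta.

    ``z_in`` has channels on the first axis.
    """
    z = np.asarray(z_in, dtype=np.float64)
    shape = (-1,) + (1,) * (z.ndim - 1)
    g = params.gamma.reshape(shape)
    b = params.beta.reshape(shape)
    mu = params.batch_mean.reshape(shape)
    sd = np.sqrt(params.batch_std.reshape(shape) ** 2 + params.eps)
    return g * (z - mu) / sd + b


# ---------------------------------------------------------------------------
# functional feature-map ops
# ---------------------------------------------------------------------------

def focus_forward(x: Tensor) -> Tensor:
    """Space-to-depth slicing: (N,C,H,W) -> (N,4C,H/2,W/2); lossless."""
    if x.shape[2] % 2 or x.shape[3] % 2:
        raise ValueError("focus requires even spatial dims")
    tl = x[:, :, ::2, ::2]
    bl = x[:, :, 1::2, ::2]
    tr = x[:, :, ::2, 1::2]
    br = x[:, :, 1::2, 1::2]
    return concat([tl, bl, tr, br], axis=1)


def unfocus(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`focus_forward` on raw arrays (round-trip identity)."""
    n, c4, h2, w2 = y.shape
    c = c4 // 4
    out = np.empty((n, c, h2 * 2, w2 * 2), dtype=y.dtype)
    out[:, :, ::2, ::2] = y[:, :c]
    out[:, :, 1::2, ::2] = y[:, c:2 * c]
    out[:, :, ::2, 1::2] = y[:, 2 * c:3 * c]
    out[:, :, 1::2, 1::2] = y[:, 3 * c:]
    return out


def spp_forward(x: Tensor, pool_sizes=(5, 9, 13)) -> Tensor:
    """Concatenate x with same-size max-pools; channels x (1+len(pool_sizes))."""
    return concat([x] + [nn.maxpool2d_same(x, k) for k in pool_sizes], axis=1)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def make_activation(name: str) -> nn.Module:
    if name == "silu":
        return nn.SiLU()
    if name == "ts":
        return nn.TS()
    if name == "none":
        return nn.Identity()
    raise ValueError(f"unknown activation {name!r}")


class ConvBnAct(nn.Module):
    """The CBS (SiLU) / CBT (TS) composite: conv -> batch norm -> activation."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 groups: int = 1, act: str = "silu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, groups=groups, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = make_activation(act)

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Focus(nn.Module):
    """Focus stem: interval slicing to 4C channels followed by a CBS conv."""

    def __init__(self, cin: int, cout: int, k: int = 3, act: str = "silu", rng=None):
        super().__init__()
        self.conv = ConvBnAct(cin * 4, cout, k, act=act, rng=rng)

    def forward(self, x):
        return self.conv(focus_forward(x))


class SPPBottleneck(nn.Module):
    """1x1 reduce -> parallel max-pools (5,9,13) -> concat -> 1x1 expand."""

    def __init__(self, cin: int, cout: int, pool_sizes=(5, 9, 13), act: str = "silu", rng=None):
        super().__init__()
        hidden = cin // 2
        self.pool_sizes = tuple(pool_sizes)
        self.conv1 = ConvBnAct(cin, hidden, 1, act=act, rng=rng)
        self.conv2 = ConvBnAct(hidden * (len(self.pool_sizes) + 1), cout, 1, act=act, rng=rng)

    def forward(self, x):
        return self.conv2(spp_forward(self.conv1(x), self.pool_sizes))


class EcaLayer(nn.Module):
    """Efficient channel attention: GAP -> 1-D conv (zero padded, no bias)
    across the channel descriptor -> sigmoid gate -> channel-wise rescale."""

    def __init__(self, spec: EcaSpec | int, rng=None):
        super().__init__()
        if isinstance(spec, int):
            spec = EcaSpec(spec)
        self.spec = spec
        self.k = spec.resolved_kernel()
        rng = rng or np.random.default_rng(0)
        std = float(np.sqrt(1.0 / self.k))
        self.weight = nn.Parameter(rng.standard_normal(self.k, dtype=np.float32) * std)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        if c != self.spec.channels:
            raise ValueError(f"ECA built for {self.spec.channels} channels, got {c}")
        y = x.mean(axis=(2, 3))  # (N, C)
        p = self.k // 2
        if p:
            zeros = Tensor(np.zeros((n, p), dtype=np.float32))
            ypad = concat([zeros, y, zeros], axis=1)
        else:
            ypad = y
        z = None
        for j in range(self.k):
            term = ypad[:, j:j + c] * self.weight[j]
            z = term if z is None else z + term
        gate = z.sigmoid().reshape(n, c, 1, 1)
        return x * gate


class GhostModule(nn.Module):
    """Ghost convolution: a primary dense conv produces n/s 'real' channels;
    (s-1) cheap depthwise convs synthesize the remaining ghost channels;
    outputs are concatenated to exactly n channels."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1, s: int = 2,
                 dw_kernel: int = 3, act: str = "silu", rng=None):
        super().__init__()
        if cout % s:
            raise ValueError(f"out_channels {cout} not divisible by split {s}")
        self.cin, self.cout, self.s = cin, cout, s
        m = cout // s
        self.primary = ConvBnAct(cin, m, k, stride=stride, act=act, rng=rng)
        self.cheap = nn.ModuleList(
            [ConvBnAct(m, m, dw_kernel, groups=m, act=act, rng=rng)
             for _ in range(s - 1)])

    def forward(self, x):
        real = self.primary(x)
        if self.s == 1:
            return real
        return concat([real] + [op(real) for op in self.cheap], axis=1)


class GhostBottleneckGE(nn.Module):
    """GE block: ghost module -> (stride-2 depthwise) -> ECA -> ghost module,
    wrapped with a residual shortcut.

    stride 1 with cin == cout uses an identity shortcut; stride 2 (or a channel
    change) uses a downsampling shortcut (depthwise stride-2 conv + pointwise
    conv, each with BN).
    """

    def __init__(self, cin: int, cout: int, stride: int = 1, mid: int | None = None,
                 s: int = 2, act: str = "silu", eca: bool = True, rng=None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("GE block stride must be 1 or 2")
        self.cin, self.cout, self.stride = cin, cout, stride
        mid = mid or cout
        if mid % s:
            mid += s - mid % s
        s_out = s if cout % s == 0 else 1  # odd widths fall back to a plain conv
        self.ghost1 = GhostModule(cin, mid, k=1, s=s, act=act, rng=rng)
        self.down = (ConvBnAct(mid, mid, 3, stride=2, groups=mid, act="none", rng=rng)
                     if stride == 2 else None)
        self.eca = EcaLayer(EcaSpec(mid), rng=rng) if eca else None
        self.ghost2 = GhostModule(mid, cout, k=1, s=s_out, act="none", rng=rng)
        if stride == 1 and cin == cout:
            self.shortcut = None
        else:
            self.shortcut = nn.Sequential(
                ConvBnAct(cin, cin, 3, stride=stride, groups=cin, act="none", rng=rng),
                ConvBnAct(cin, cout, 1, act="none", rng=rng))

    def forward(self, x):
        h = self.ghost1(x)
        if self.down is not None:
            h = self.down(h)
        if self.eca is not None:
            h = self.eca(h)
        h = self.ghost2(h)
        sc = x if self.shortcut is None else self.shortcut(x)
        return h + sc
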