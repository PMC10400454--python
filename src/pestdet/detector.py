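"""Full detector assembly and complexity accounting.

Two backbones are available: the standard CSPDarknet used by the reference
YOLOX variants (whose parameter counts are validated against the published
9.0/25.3/54.2/99.1 M figures), and a ghost/ECA (GE-block) backbone for the
lightweight pest model.  The neck is a PAFPN, optionally followed by adaptive
spatial feature fusion (ASFF) of the three pyramid levels; heads are the
anchor-free decoupled YOLOX heads with either SiLU (CBS) or TS (CBT) units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .autograd import Tensor, concat, no_grad
from .nn_blocks import (ConvBnAct, Focus, GhostBottleneckGE, SPPBottleneck,
                        make_activation)

__all__ = [
    "ModelConfig", "VARIANTS", "AsffWeights", "LayerSummary",
    "build_model", "asff_combine", "count_params", "count_flops",
    "summarize_layers", "write_layer_summaries",
]

STRIDES = (8, 16, 32)


@dataclass(frozen=True)
class ModelConfig:
    """Descriptor from which a detector network is instantiated."""
    variant: str = "custom"
    depth_multiplier: float = 0.33
    width_multiplier: float = 0.50
    backbone: str = "cspdarknet"        # cspdarknet | ghostnet_ge
    neck: str = "pafpn"                 # pafpn | pafpn_asff
    head_activation: str = "silu"       # silu | ts
    num_classes: int = 80
    input_size: int = 640

    def __post_init__(self):
        if self.depth_multiplier <= 0 or self.width_multiplier <= 0:
            raise ValueError("depth/width multipliers must be > 0")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")
        if self.backbone not in ("cspdarknet", "ghostnet_ge"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.neck not in ("pafpn", "pafpn_asff"):
            raise ValueError(f"unknown neck {self.neck!r}")
        if self.head_activation not in ("silu", "ts"):
            raise ValueError(f"unknown head activation {self.head_activation!r}")


#: Reference configurations.  The yolox-* rows reproduce the standard
#: 80-class architectures; "pest" is the lightweight 2-class larva detector
#: (ghost/ECA backbone, ASFF neck, TS heads); "pest-smoke" is the same design
#: scaled for CPU-size end-to-end runs.
VARIANTS = {
    "yolox-s": ModelConfig("yolox-s", 0.33, 0.50),
    "yolox-m": ModelConfig("yolox-m", 0.67, 0.75),
    "yolox-l": ModelConfig("yolox-l", 1.00, 1.00),
    "yolox-x": ModelConfig("yolox-x", 1.33, 1.25),
    "pest": ModelConfig("pest", 0.33, 0.50, backbone="ghostnet_ge",
                        neck="pafpn_asff", head_activation="ts", num_classes=2),
    "pest-smoke": ModelConfig("pest-smoke", 0.33, 0.125, backbone="ghostnet_ge",
                              neck="pafpn_asff", head_activation="ts",
                              num_classes=2, input_size=256),
}


def get_config(variant: str, **overrides) -> ModelConfig:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    return replace(VARIANTS[variant], **overrides)


# ---------------------------------------------------------------------------
# CSPDarknet pieces
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    def __init__(self, cin, cout, shortcut=True, act="silu", rng=None):
        super().__init__()
        self.conv1 = ConvBnAct(cin, cout, 1, act=act, rng=rng)
        self.conv2 = ConvBnAct(cout, cout, 3, act=act, rng=rng)
        self.use_add = shortcut and cin == cout

    def forward(self, x):
        y = self.conv2(self.conv1(x))
        return y + x if self.use_add else y


class CSPLayer(nn.Module):
    """Cross-stage-partial layer: split 1x1 branches, n bottlenecks, merge."""

    def __init__(self, cin, cout, n=1, shortcut=True, act="silu", rng=None):
        super().__init__()
        hidden = cout // 2
        self.conv1 = ConvBnAct(cin, hidden, 1, act=act, rng=rng)
        self.conv2 = ConvBnAct(cin, hidden, 1, act=act, rng=rng)
        self.blocks = nn.Sequential(*[
            Bottleneck(hidden, hidden, shortcut, act=act, rng=rng) for _ in range(n)])
        self.conv3 = ConvBnAct(2 * hidden, cout, 1, act=act, rng=rng)

    def forward(self, x):
        a = self.blocks(self.conv1(x))
        b = self.conv2(x)
        return self.conv3(concat([a, b], axis=1))


class CSPDarknet(nn.Module):
    def __init__(self, depth, width, act="silu", rng=None):
        super().__init__()
        bc = int(64 * width)
        bd = max(round(3 * depth), 1)
        self.stem = Focus(3, bc, 3, act=act, rng=rng)
        self.dark2 = nn.Sequential(
            ConvBnAct(bc, bc * 2, 3, 2, act=act, rng=rng),
            CSPLayer(bc * 2, bc * 2, bd, act=act, rng=rng))
        self.dark3 = nn.Sequential(
            ConvBnAct(bc * 2, bc * 4, 3, 2, act=act, rng=rng),
            CSPLayer(bc * 4, bc * 4, bd * 3, act=act, rng=rng))
        self.dark4 = nn.Sequential(
            ConvBnAct(bc * 4, bc * 8, 3, 2, act=act, rng=rng),
            CSPLayer(bc * 8, bc * 8, bd * 3, act=act, rng=rng))
        self.dark5 = nn.Sequential(
            ConvBnAct(bc * 8, bc * 16, 3, 2, act=act, rng=rng),
            SPPBottleneck(bc * 16, bc * 16, act=act, rng=rng),
            CSPLayer(bc * 16, bc * 16, bd, shortcut=False, act=act, rng=rng))

    def forward(self, x):
        x = self.dark2(self.stem(x))
        c3 = self.dark3(x)
        c4 = self.dark4(c3)
        c5 = self.dark5(c4)
        return c3, c4, c5


class GhostGEBackbone(nn.Module):
    """CSPDarknet-shaped backbone with stages built from GE blocks.

    Stride schedule and stage widths mirror CSPDarknet so the PAFPN interface
    (strides 8/16/32, channels 4/8/16 x base) is preserved; SPP is retained in
    the deepest stage.
    """

    def __init__(self, depth, width, act="silu", rng=None):
        super().__init__()
        bc = int(64 * width)
        bd = max(round(3 * depth), 1)

        def stage(cin, cout, n):
            mods = [GhostBottleneckGE(cin, cout, stride=2, act=act, rng=rng)]
            mods += [GhostBottleneckGE(cout, cout, act=act, rng=rng) for _ in range(n)]
            return nn.Sequential(*mods)

        self.stem = Focus(3, bc, 3, act=act, rng=rng)
        self.stage2 = stage(bc, bc * 2, bd)
        self.stage3 = stage(bc * 2, bc * 4, bd * 3)
        self.stage4 = stage(bc * 4, bc * 8, bd * 3)
        self.stage5 = nn.Sequential(
            GhostBottleneckGE(bc * 8, bc * 16, stride=2, act=act, rng=rng),
            SPPBottleneck(bc * 16, bc * 16, act=act, rng=rng),
            *[GhostBottleneckGE(bc * 16, bc * 16, act=act, rng=rng) for _ in range(bd)])

    def forward(self, x):
        x = self.stage2(self.stem(x))
        c3 = self.stage3(x)
        c4 = self.stage4(c3)
        c5 = self.stage5(c4)
        return c3, c4, c5


# ---------------------------------------------------------------------------
# PAFPN neck and ASFF
# ---------------------------------------------------------------------------

class YOLOPAFPN(nn.Module):
    def __init__(self, depth, width, act="silu", rng=None):
        super().__init__()
        c0, c1, c2 = int(256 * width), int(512 * width), int(1024 * width)
        n = max(round(3 * depth), 1)
        self.lateral_conv0 = ConvBnAct(c2, c1, 1, act=act, rng=rng)
        self.C3_p4 = CSPLayer(2 * c1, c1, n, shortcut=False, act=act, rng=rng)
        self.reduce_conv1 = ConvBnAct(c1, c0, 1, act=act, rng=rng)
        self.C3_p3 = CSPLayer(2 * c0, c0, n, shortcut=False, act=act, rng=rng)
        self.bu_conv2 = ConvBnAct(c0, c0, 3, 2, act=act, rng=rng)
        self.C3_n3 = CSPLayer(2 * c0, c1, n, shortcut=False, act=act, rng=rng)
        self.bu_conv1 = ConvBnAct(c1, c1, 3, 2, act=act, rng=rng)
        self.C3_n4 = CSPLayer(2 * c1, c2, n, shortcut=False, act=act, rng=rng)
        self.out_channels = (c0, c1, c2)

    def forward(self, feats):
        x2, x1, x0 = feats  # strides 8, 16, 32
        fpn0 = self.lateral_conv0(x0)
        f0 = self.C3_p4(concat([nn.upsample_nearest(fpn0, 2), x1], axis=1))
        fpn1 = self.reduce_conv1(f0)
        pan2 = self.C3_p3(concat([nn.upsample_nearest(fpn1, 2), x2], axis=1))
        pan1 = self.C3_n3(concat([self.bu_conv2(pan2), fpn1], axis=1))
        pan0 = self.C3_n4(concat([self.bu_conv1(pan1), fpn0], axis=1))
        return pan2, pan1, pan0


@dataclass
class AsffWeights:
    """Per-position fusion weights for the three pyramid levels."""
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        for w in (self.alpha, self.beta, self.gamma):
            if np.any(w < -1e-6) or np.any(w > 1 + 1e-6):
                raise ValueError("ASFF weights must lie in [0, 1]")
        if not np.allclose(self.alpha + self.beta + self.gamma, 1.0, atol=1e-5):
            raise ValueError("ASFF weights must sum to 1 at every position")


def asff_combine(aligned, logits):
    """Softmax-normalize per-position logits over the three levels and blend.

    aligned: three feature Tensors of identical shape (already resized to the
    target level).  logits: Tensor (N, 3, H, W).  Returns (fused, weights)
    where weights is an AsffWeights of numpy arrays.
    """
    if len(aligned) != 3:
        raise ValueError("ASFF fuses exactly three levels")
    shape = aligned[0].shape
    for a in aligned[1:]:
        if a.shape != shape:
            raise ValueError("aligned ASFF inputs must share a shape")
    # stable softmax over the level axis
    mx = Tensor(logits.data.max(axis=1, keepdims=True))
    e = (logits - mx).exp()
    denom = e.sum(axis=1, keepdims=True)
    w = e / denom
    fused = (aligned[0] * w[:, 0:1] + aligned[1] * w[:, 1:2] + aligned[2] * w[:, 2:3])
    wd = w.data
    weights = AsffWeights(wd[:, 0], wd[:, 1], wd[:, 2])
    return fused, weights


class AsffFuse(nn.Module):
    """ASFF for one target level: compress+resize the other levels, derive
    per-position weight logits via 1x1 convs, softmax, weighted sum."""

    def __init__(self, channels, target_level: int, act="silu", rng=None):
        super().__init__()
        if target_level not in (0, 1, 2):
            raise ValueError("target_level must be 0, 1 or 2")
        self.target = target_level
        ct = channels[target_level]
        self.resize = nn.ModuleList()
        for lvl in range(3):
            if lvl == self.target:
                self.resize.append(nn.Identity())
            elif lvl > self.target:  # coarser: compress then upsample
                self.resize.append(_CompressUp(channels[lvl], ct,
                                               2 ** (lvl - self.target), act, rng))
            else:  # finer: compress then strided downsample(s)
                mods = [ConvBnAct(channels[lvl], ct, 1, act=act, rng=rng)]
                mods += [ConvBnAct(ct, ct, 3, 2, act=act, rng=rng)
                         for _ in range(self.target - lvl)]
                self.resize.append(nn.Sequential(*mods))
        self.weight_convs = nn.ModuleList(
            [nn.Conv2d(ct, 1, 1, bias=True, rng=rng) for _ in range(3)])

    def forward(self, levels):
        aligned = [self.resize[i](levels[i]) for i in range(3)]
        logits = concat([self.weight_convs[i](aligned[i]) for i in range(3)], axis=1)
        fused, _ = asff_combine(aligned, logits)
        return fused


class _CompressUp(nn.Module):
    def __init__(self, cin, cout, factor, act, rng):
        super().__init__()
        self.conv = ConvBnAct(cin, cout, 1, act=act, rng=rng)
        self.factor = factor

    def forward(self, x):
        return nn.upsample_nearest(self.conv(x), self.factor)


# ---------------------------------------------------------------------------
# decoupled head and full model
# ---------------------------------------------------------------------------

class YOLOXHead(nn.Module):
    """Anchor-free decoupled head; per level emits (4 box, 1 obj, C cls) maps."""

    def __init__(self, num_classes, width, in_channels, act="silu", rng=None):
        super().__init__()
        self.num_classes = num_classes
        hc = int(256 * width)
        self.stems = nn.ModuleList()
        self.cls_convs = nn.ModuleList()
        self.reg_convs = nn.ModuleList()
        self.cls_preds = nn.ModuleList()
        self.reg_preds = nn.ModuleList()
        self.obj_preds = nn.ModuleList()
        for cin in in_channels:
            self.stems.append(ConvBnAct(cin, hc, 1, act=act, rng=rng))
            self.cls_convs.append(nn.Sequential(
                ConvBnAct(hc, hc, 3, act=act, rng=rng),
                ConvBnAct(hc, hc, 3, act=act, rng=rng)))
            self.reg_convs.append(nn.Sequential(
                ConvBnAct(hc, hc, 3, act=act, rng=rng),
                ConvBnAct(hc, hc, 3, act=act, rng=rng)))
            self.cls_preds.append(nn.Conv2d(hc, num_classes, 1, bias=True, rng=rng))
            self.reg_preds.append(nn.Conv2d(hc, 4, 1, bias=True, rng=rng))
            self.obj_preds.append(nn.Conv2d(hc, 1, 1, bias=True, rng=rng))

    def init_priors(self, obj_prior: float = 0.02, wh_bias: float = 1.0):
        """Bias the objectness logit toward a low prior and the raw w/h
        toward exp(wh_bias) cells, which stabilizes early training."""
        b = float(np.log(obj_prior / (1 - obj_prior)))
        for op, rp in zip(self.obj_preds, self.reg_preds):
            op.bias.data[:] = b
            rp.bias.data[2:4] = wh_bias

    def forward(self, feats):
        outs = []
        for i, f in enumerate(feats):
            x = self.stems[i](f)
            cls = self.cls_preds[i](self.cls_convs[i](x))
            r = self.reg_convs[i](x)
            reg = self.reg_preds[i](r)
            obj = self.obj_preds[i](r)
            outs.append(concat([reg, obj, cls], axis=1))
        return outs


class DetectorModel(nn.Module):
    """backbone -> PAFPN -> (ASFF) -> decoupled heads; three outputs at
    strides 8/16/32 with 5 + num_classes channels each."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.strides = STRIDES
        rng = np.random.default_rng(seed)
        act = "silu"
        d, w = config.depth_multiplier, config.width_multiplier
        if config.backbone == "cspdarknet":
            self.backbone = CSPDarknet(d, w, act=act, rng=rng)
        else:
            self.backbone = GhostGEBackbone(d, w, act=act, rng=rng)
        self.neck = YOLOPAFPN(d, w, act=act, rng=rng)
        if config.neck == "pafpn_asff":
            self.asff = nn.ModuleList(
                [AsffFuse(self.neck.out_channels, lvl, act=act, rng=rng)
                 for lvl in range(3)])
        else:
            self.asff = None
        self.head = YOLOXHead(config.num_classes, w, self.neck.out_channels,
                              act=config.head_activation, rng=rng)
        # the stem is never pruned (fixed image interface)
        self.backbone.stem.conv.bn.prunable = False

    def forward(self, x):
        feats = self.neck(self.backbone(x))
        if self.asff is not None:
            feats = [fuse(feats) for fuse in self.asff]
        return self.head(feats)

    def backbone_parameters(self):
        return list(self.backbone.parameters())


def build_model(config: ModelConfig | str, seed: int = 0, **overrides) -> DetectorModel:
    if isinstance(config, str):
        config = get_config(config, **overrides)
    elif overrides:
        config = replace(config, **overrides)
    return DetectorModel(config, seed=seed)


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

@dataclass
class LayerSummary:
    name: str
    H: int
    W: int
    K: int
    C_in: int
    C_out: int
    params: int
    flops: int


def count_params(network: nn.Module) -> int:
    """Total learnable scalars: conv kernels, biases, BN scale/shift."""
    return network.num_params()


def summarize_layers(network: nn.Module, input_size: int | None = None,
                     convention: str = "paper") -> list[LayerSummary]:
    """Per-convolution table of shapes, params and FLOPs.

    Runs one zero forward pass at `input_size` (eval mode) to record spatial
    sizes.  `convention`: "paper" counts 2*H*W*(Cin*K^2+1)*Cout per conv
    (H, W the output size); "mac" counts multiply-accumulates
    H*W*Cin*K^2*Cout (half, without the +1 bias term).
    """
    if convention not in ("paper", "mac"):
        raise ValueError("convention must be 'paper' or 'mac'")
    size = input_size or getattr(getattr(network, "config", None), "input_size", None)
    if size is None:
        raise ValueError("input_size required for a network without a config")
    was_training = network.training
    network.eval()
    with no_grad():
        network(Tensor(np.zeros((1, 3, size, size), dtype=np.float32)))
    if was_training:
        network.train()
    rows = []
    for name, mod in network.named_modules():
        if not isinstance(mod, nn.Conv2d):
            continue
        if mod.last_out_hw is None:
            continue
        h, w = mod.last_out_hw
        cin_g = mod.in_channels // mod.groups
        k = mod.kernel_size
        params = mod.weight.data.size + (mod.bias.data.size if mod.bias is not None else 0)
        if convention == "paper":
            flops = 2 * h * w * (cin_g * k * k + 1) * mod.out_channels
        else:
            flops = h * w * cin_g * k * k * mod.out_channels
        rows.append(LayerSummary(name, h, w, k, mod.in_channels, mod.out_channels,
                                 int(params), int(flops)))
    return rows


def count_flops(network: nn.Module, input_size: int | None = None,
                convention: str = "paper") -> int:
    """Total convolution FLOPs at the given input size (see summarize_layers)."""
    return sum(r.flops for r in summarize_layers(network, input_size, convention))


def write_layer_summaries(path, rows: list[LayerSummary]):
    with open(path, "w") as fh:
        fh.write("name\tH\tW\tK\tC_in\tC_out\tparams\tflops\n")
        for r in rows:
            fh.write(f"{r.name}\t{r.H}\t{r.W}\t{r.K}\t{r.C_in}\t{r.C_out}"
                     f"\t{r.params}\t{r.flops}\n")
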