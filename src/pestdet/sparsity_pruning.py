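"""Structured channel pruning driven by batch-norm scaling factors.

Workflow: (1) sparsity training adds an L1 penalty lambda * sum|gamma| on the
BN scales, pushing unimportant channels toward zero; (2) all prunable |gamma|
are ranked globally and a ratio-quantile threshold gamma* is chosen; (3) a
PruningPlan of per-layer keep masks is built, honoring a >=1-channel floor
per layer and coupling constraints (channels joined by residual additions,
depthwise convolutions, ghost concatenations or ASFF sums are pruned only if
prunable everywhere — intersection rule); (4) the plan is applied
structurally: pruned channels are removed from the BN, from the producing
convolution's filters and from every consumer's input slices, with each
removed channel's constant contribution act(beta) absorbed into the
downstream running statistics or biases.  Because convolutions use edge
padding, a gamma=0 channel's removal is exactly function-preserving in eval
mode; (5) fine-tuning with a warm-up learning rate recovers accuracy.

The stem convolution and the head prediction convolutions are never pruned.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .detector import (AsffFuse, Bottleneck, CSPLayer, DetectorModel,
                       YOLOPAFPN, YOLOXHead, _CompressUp)
from .nn_blocks import (ConvBnAct, EcaLayer, EcaSpec, Focus, GhostBottleneckGE,
                        GhostModule, SPPBottleneck, ts_activation)
from .train_sched import cosine_lr, run_training

__all__ = [
    "SparsityConfig", "PruningPlan",
    "sparsity_penalty", "sparsity_train", "prunable_bns", "rank_channels",
    "build_pruning_plan", "apply_pruning", "finetune",
    "save_plan", "load_plan",
]


@dataclass(frozen=True)
class SparsityConfig:
    """Study-condition defaults for the sparsity-training phase."""
    penalty: float = 0.001
    learning_rate: float = 0.0001
    batch_size: int = 16
    epochs: int = 100   # the printed "iterations" read as epochs

    def __post_init__(self):
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")


def sparsity_penalty(scales, lam: float) -> float:
    """L1 regularizer lambda * sum|gamma|; added to the baseline loss."""
    if lam < 0:
        raise ValueError("penalty factor must be >= 0")
    if isinstance(scales, (list, tuple)):
        parts = [np.ravel(np.asarray(s, dtype=np.float64)) for s in scales]
        flat = np.concatenate(parts) if parts else np.zeros(0)
    else:
        flat = np.ravel(np.asarray(scales, dtype=np.float64))
    return float(lam * np.abs(flat).sum())


def _l1_grad_hook(lam: float):
    def hook(model):
        for _, bn in prunable_bns(model):
            g = lam * np.sign(bn.gamma.data)
            if bn.gamma.grad is None:
                bn.gamma.grad = g.astype(np.float32)
            else:
                bn.gamma.grad += g.astype(np.float32)
    return hook


def sparsity_train(model, items, cfg: SparsityConfig | None = None, seed: int = 0,
                   history: list | None = None):
    """Train with the L1 subgradient of the BN-scale penalty added to the
    gamma gradients (exactly the penalty term's contribution to the loss)."""
    cfg = cfg or SparsityConfig()
    return run_training(model, items, epochs=cfg.epochs, batch_size=cfg.batch_size,
                        lr=cfg.learning_rate, seed=seed,
                        grad_hook=_l1_grad_hook(cfg.penalty) if cfg.penalty else None,
                        lr_fn=lambda t, T: cfg.learning_rate,
                        history=history, phase="sparsity")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def prunable_bns(network) -> list:
    """Ordered (name, BatchNorm2d) pairs with bn.prunable set."""
    return [(name, m) for name, m in network.named_modules()
            if isinstance(m, nn.BatchNorm2d) and m.prunable]


def rank_channels(network):
    """Globally ascending |gamma| with (layer_index, channel_index) provenance;
    ties broken by provenance order (stable)."""
    bns = prunable_bns(network)
    if not bns:
        raise ValueError("network has no prunable BN layers")
    rows = []
    for li, (name, bn) in enumerate(bns):
        for ci, g in enumerate(np.abs(bn.gamma.data)):
            rows.append((float(g), li, ci, name))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    return rows


# ---------------------------------------------------------------------------
# coupling analysis (tie pass)
# ---------------------------------------------------------------------------

_PIN = ("__pinned__", -1)


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, a):
        p = self.parent.setdefault(a, a)
        if p != a:
            p = self.parent[a] = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _bn_iface(bn):
    return [(id(bn), c) for c in range(bn.channels)]


def _tie(uf, a, b):
    """Couple two channel slots; a None slot pins the group (never pruned)."""
    if a is None and b is None:
        return
    if a is None:
        uf.union(b, _PIN)
    elif b is None:
        uf.union(a, _PIN)
    else:
        uf.union(a, b)


def _trace(mod, iface, uf):
    """Walk `mod` mirroring its forward dataflow, recording couplings in `uf`.
    `iface` is one slot per input channel: (bn_id, ch) or None."""
    if isinstance(mod, (nn.Identity, EcaLayer)):
        return iface
    if isinstance(mod, nn.Conv2d):  # bare conv: output channels are fixed
        return [None] * mod.out_channels
    if isinstance(mod, ConvBnAct):
        out = _bn_iface(mod.bn) if mod.bn.prunable else [None] * mod.bn.channels
        if mod.conv.groups > 1:  # depthwise: out channel c tied to in channel c
            for a, b in zip(iface, out):
                _tie(uf, a, b)
        return out
    if isinstance(mod, Focus):
        return _trace(mod.conv, [None] * (4 * len(iface)), uf)
    if isinstance(mod, GhostModule):
        real = _trace(mod.primary, iface, uf)
        out = list(real)
        for cheap in mod.cheap:
            out += _trace(cheap, real, uf)
        return out
    if isinstance(mod, GhostBottleneckGE):
        h = _trace(mod.ghost1, iface, uf)
        if mod.down is not None:
            h = _trace(mod.down, h, uf)
        if mod.eca is not None:
            h = _trace(mod.eca, h, uf)
        h = _trace(mod.ghost2, h, uf)
        sc = iface if mod.shortcut is None else _trace(mod.shortcut, iface, uf)
        for a, b in zip(h, sc):
            _tie(uf, a, b)
        return h
    if isinstance(mod, SPPBottleneck):
        h = _trace(mod.conv1, iface, uf)
        return _trace(mod.conv2, h * (len(mod.pool_sizes) + 1), uf)
    if isinstance(mod, Bottleneck):
        h = _trace(mod.conv2, _trace(mod.conv1, iface, uf), uf)
        if mod.use_add:
            for a, b in zip(h, iface):
                _tie(uf, a, b)
        return h
    if isinstance(mod, CSPLayer):
        a = _trace(mod.blocks, _trace(mod.conv1, iface, uf), uf)
        b = _trace(mod.conv2, iface, uf)
        return _trace(mod.conv3, a + b, uf)
    if isinstance(mod, _CompressUp):
        return _trace(mod.conv, iface, uf)
    if isinstance(mod, nn.Sequential):
        for sub in mod:
            iface = _trace(sub, iface, uf)
        return iface
    raise TypeError(f"pruning does not know module type {type(mod).__name__}")


def _trace_neck(neck: YOLOPAFPN, feats, uf):
    x2, x1, x0 = feats
    fpn0 = _trace(neck.lateral_conv0, x0, uf)
    f0 = _trace(neck.C3_p4, fpn0 + x1, uf)
    fpn1 = _trace(neck.reduce_conv1, f0, uf)
    pan2 = _trace(neck.C3_p3, fpn1 + x2, uf)
    pan1 = _trace(neck.C3_n3, _trace(neck.bu_conv2, pan2, uf) + fpn1, uf)
    pan0 = _trace(neck.C3_n4, _trace(neck.bu_conv1, pan1, uf) + fpn0, uf)
    return pan2, pan1, pan0


def _trace_asff(fuse: AsffFuse, feats, uf):
    aligned = [_trace(fuse.resize[i], feats[i], uf) for i in range(3)]
    for lvl in (1, 2):
        for a, b in zip(aligned[0], aligned[lvl]):
            _tie(uf, a, b)
    return aligned[fuse.target]


def _trace_head(head: YOLOXHead, feats, uf):
    for i, f in enumerate(feats):
        st = _trace(head.stems[i], f, uf)
        _trace(head.cls_convs[i], st, uf)
        _trace(head.reg_convs[i], st, uf)
        # prediction convs consume the branch outputs; their own outputs are
        # the fixed detector interface (handled in the apply pass)


def _trace_model(model, uf):
    if isinstance(model, DetectorModel):
        x = [None] * 3
        b = model.backbone
        if hasattr(b, "dark2"):  # CSPDarknet
            x = _trace(b.stem, x, uf)
            x = _trace(b.dark2, x, uf)
            c3 = _trace(b.dark3, x, uf)
            c4 = _trace(b.dark4, c3, uf)
            c5 = _trace(b.dark5, c4, uf)
        else:  # GhostGEBackbone
            x = _trace(b.stem, x, uf)
            x = _trace(b.stage2, x, uf)
            c3 = _trace(b.stage3, x, uf)
            c4 = _trace(b.stage4, c3, uf)
            c5 = _trace(b.stage5, c4, uf)
        feats = _trace_neck(model.neck, (c3, c4, c5), uf)
        if model.asff is not None:
            feats = [_trace_asff(f, feats, uf) for f in model.asff]
        _trace_head(model.head, feats, uf)
        return
    # generic chain (e.g. a plain Sequential test network)
    first = next((m for m in model.modules() if isinstance(m, nn.Conv2d)), None)
    if first is None:
        raise ValueError("no convolutions to prune")
    _trace(model, [None] * first.in_channels, uf)


# ---------------------------------------------------------------------------
# plan
# ---------------------------------------------------------------------------

@dataclass
class PruningPlan:
    keep_masks: dict            # layer name -> bool array
    ratio: float
    threshold: float
    achieved_fraction: float

    def n_pruned(self) -> int:
        return int(sum((~m).sum() for m in self.keep_masks.values()))


def build_pruning_plan(network, ratio: float | None = 0.65,
                       threshold: float | None = None,
                       max_layer_prune: float = 1.0) -> PruningPlan:
    """Derive per-layer keep masks from globally ranked |gamma|.

    gamma* is the nearest-rank ratio-quantile of the ascending global list
    (index floor(ratio * n)); channels with |gamma| < gamma* are pruned,
    subject to the per-layer floor (>= 1 channel kept) and the coupling
    intersection rule.  Passing an explicit `threshold` bypasses the
    quantile (used to re-apply a previous plan's gamma*).

    `max_layer_prune` optionally caps the pruned fraction of any single
    layer (1.0 = no cap beyond the floor).  With weakly separated scaling
    factors a global quantile can otherwise hollow out individual layers to
    the floor; capping trades some global ratio for per-layer capacity.
    """
    if not (0.0 < max_layer_prune <= 1.0):
        raise ValueError("max_layer_prune must lie in (0, 1]")
    if threshold is None:
        if ratio is None or not (0.0 <= ratio < 1.0):
            raise ValueError("pruning ratio must lie in [0, 1)")
        rows = rank_channels(network)
        k = int(math.floor(ratio * len(rows)))
        threshold = rows[k][0] if k < len(rows) else math.inf
    bns = prunable_bns(network)
    uf = _UnionFind()
    _trace_model(network, uf)
    keep = {name: np.abs(bn.gamma.data) >= threshold for name, bn in bns}
    if max_layer_prune < 1.0:
        for name, bn in bns:
            k = keep[name]
            max_pruned = int(math.floor(max_layer_prune * len(k)))
            excess = int((~k).sum()) - max_pruned
            if excess > 0:
                pruned_idx = np.flatnonzero(~k)
                order = pruned_idx[np.argsort(-np.abs(bn.gamma.data[pruned_idx]),
                                              kind="stable")]
                k[order[:excess]] = True

    def resolve():
        groups: dict = {}
        for name, bn in bns:
            for c in range(bn.channels):
                root = uf.find((id(bn), c))
                groups.setdefault(root, []).append((name, c))
        pin_root = uf.find(_PIN) if _PIN in uf.parent else None
        for root, members in groups.items():
            keep_any = (root == pin_root) or any(keep[n][c] for n, c in members)
            if keep_any:
                for n, c in members:
                    keep[n][c] = True

    resolve()
    for _ in range(10):  # floor rule, then re-propagate couplings
        changed = False
        for name, bn in bns:
            if not keep[name].any():
                keep[name][int(np.argmax(np.abs(bn.gamma.data)))] = True
                changed = True
        if not changed:
            break
        resolve()
    total = sum(bn.channels for _, bn in bns)
    pruned = sum(int((~keep[name]).sum()) for name, _ in bns)
    ratio_val = ratio if ratio is not None else float("nan")
    return PruningPlan({n: k for n, k in keep.items()}, ratio_val,
                       float(threshold), pruned / total if total else 0.0)


def save_plan(path, plan: PruningPlan):
    with open(path, "w") as fh:
        json.dump({"ratio": plan.ratio, "threshold": plan.threshold,
                   "achieved_fraction": plan.achieved_fraction,
                   "keep_masks": {k: v.astype(int).tolist()
                                  for k, v in plan.keep_masks.items()}}, fh, indent=2)


def load_plan(path) -> PruningPlan:
    with open(path) as fh:
        d = json.load(fh)
    return PruningPlan({k: np.asarray(v, dtype=bool)
                        for k, v in d["keep_masks"].items()},
                       d["ratio"], d["threshold"], d["achieved_fraction"])


# ---------------------------------------------------------------------------
# apply pass
# ---------------------------------------------------------------------------

def _act_value(act_mod, x: np.ndarray) -> np.ndarray:
    if isinstance(act_mod, nn.SiLU):
        return x / (1.0 + np.exp(-x))
    if isinstance(act_mod, nn.TS):
        return np.asarray(ts_activation(x))
    return x  # Identity


class _Apply:
    """Carries the resolved masks while structurally slicing a network copy.

    State flowing between modules: (keep, const) where `keep` is a bool array
    over the producer's original channels (None = fixed interface) and
    `const` holds, for removed channels, the constant value the channel
    contributes downstream (act(beta)); entries of kept channels are 0.
    """

    def __init__(self, masks_by_id):
        self.masks = masks_by_id

    def run(self, mod, keep, const):
        if isinstance(mod, nn.Identity):
            return keep, const
        if isinstance(mod, EcaLayer):
            if keep is not None:
                newc = int(keep.sum())
                mod.spec = EcaSpec(newc, kernel=mod.k)
            return keep, const
        if isinstance(mod, nn.Conv2d):
            self._slice_conv_input(mod, keep, const, absorb_bias=True)
            return None, None
        if isinstance(mod, ConvBnAct):
            return self._conv_bn_act(mod, keep, const)
        if isinstance(mod, Focus):
            return self.run(mod.conv, None, None)
        if isinstance(mod, GhostModule):
            mk, mc = self.run(mod.primary, keep, const)
            keeps, consts = [mk], [mc]
            for cheap in mod.cheap:
                ck, cc = self.run(cheap, mk, mc)
                keeps.append(ck); consts.append(cc)
            if keep is not None:
                mod.cin = int(keep.sum())
            mod.cout = int(sum(k.sum() for k in keeps))
            return np.concatenate(keeps), np.concatenate(consts)
        if isinstance(mod, GhostBottleneckGE):
            hk, hc = self.run(mod.ghost1, keep, const)
            if mod.down is not None:
                hk, hc = self.run(mod.down, hk, hc)
            if mod.eca is not None:
                hk, hc = self.run(mod.eca, hk, hc)
            hk, hc = self.run(mod.ghost2, hk, hc)
            if mod.shortcut is None:
                sk, sc = keep, const
            else:
                sk, sc = self.run(mod.shortcut, keep, const)
            if sk is None:  # pinned input: ties force everything kept
                return hk, hc
            return hk, hc + sc
        if isinstance(mod, SPPBottleneck):
            hk, hc = self.run(mod.conv1, keep, const)
            rep = len(mod.pool_sizes) + 1
            return self.run(mod.conv2, np.tile(hk, rep), np.tile(hc, rep))
        if isinstance(mod, Bottleneck):
            hk, hc = self.run(mod.conv2, *self.run(mod.conv1, keep, const))
            if mod.use_add and keep is not None:
                hc = hc + const
            return hk, hc
        if isinstance(mod, CSPLayer):
            ak, ac = self.run(mod.blocks, *self.run(mod.conv1, keep, const))
            bk, bc = self.run(mod.conv2, keep, const)
            return self.run(mod.conv3, np.concatenate([ak, bk]),
                            np.concatenate([ac, bc]))
        if isinstance(mod, _CompressUp):
            return self.run(mod.conv, keep, const)
        if isinstance(mod, nn.Sequential):
            for sub in mod:
                keep, const = self.run(sub, keep, const)
            return keep, const
        raise TypeError(f"pruning does not know module type {type(mod).__name__}")

    # -- helpers ------------------------------------------------------------
    def _slice_conv_input(self, conv: nn.Conv2d, keep, const, absorb_bias=False):
        if keep is None or keep.all():
            return
        if conv.groups > 1:
            conv.weight.data = conv.weight.data[keep]
            conv.in_channels = conv.out_channels = conv.groups = int(keep.sum())
            return
        removed = ~keep
        delta = np.tensordot(conv.weight.data[:, removed].sum(axis=(2, 3)),
                             const[removed], axes=([1], [0]))
        if absorb_bias:
            if conv.bias is not None:
                conv.bias.data += delta.astype(np.float32)
            # bias-less bare conv: constant is genuinely lost (not used here)
        self._pending_delta = delta  # picked up by the following BN
        conv.weight.data = conv.weight.data[:, keep]
        conv.in_channels = int(keep.sum())

    def _conv_bn_act(self, mod: ConvBnAct, keep, const):
        self._pending_delta = None
        depthwise = mod.conv.groups > 1
        if depthwise:
            m = keep if keep is not None else np.ones(mod.bn.channels, dtype=bool)
            bn = mod.bn
            # removed input channel c (constant v) feeds only output c:
            # pre-activation constant is the BN transform of kernel_sum * v
            z = (mod.conv.weight.data.sum(axis=(1, 2, 3)).astype(np.float64)
                 * (const if const is not None else 0.0))
            oconst_pre = (bn.gamma.data * (z - bn.running_mean)
                          / np.sqrt(bn.running_var + bn.eps) + bn.beta.data)
            self._slice_conv_input(mod.conv, keep, const)
        else:
            self._slice_conv_input(mod.conv, keep, const)
            if self._pending_delta is not None:
                # removing a constant input contribution delta from z is
                # compensated by shifting the BN running mean
                mod.bn.running_mean = (mod.bn.running_mean
                                       - self._pending_delta.astype(np.float32))
            m = self.masks.get(id(mod.bn))
            if m is None:
                m = np.ones(mod.bn.channels, dtype=bool)
            oconst_pre = mod.bn.beta.data.astype(np.float64).copy()
        # output constants of removed channels: eval-mode BN output ~ beta
        oconst = np.where(m, 0.0, _act_value(mod.act, oconst_pre))
        if not m.all():
            if not depthwise:
                mod.conv.weight.data = mod.conv.weight.data[m]
                if mod.conv.bias is not None:
                    mod.conv.bias.data = mod.conv.bias.data[m]
                mod.conv.out_channels = int(m.sum())
            bn = mod.bn
            bn.gamma.data = bn.gamma.data[m]
            bn.beta.data = bn.beta.data[m]
            bn.running_mean = bn.running_mean[m]
            bn.running_var = bn.running_var[m]
            bn.channels = int(m.sum())
        return m, oconst


def apply_pruning(network, plan: PruningPlan):
    """Return a structurally pruned deep copy of `network`."""
    net = copy.deepcopy(network)
    names = dict(net.named_modules())
    masks_by_id = {}
    for name, mask in plan.keep_masks.items():
        bn = names.get(name)
        if bn is None or not isinstance(bn, nn.BatchNorm2d):
            raise ValueError(f"plan refers to unknown BN layer {name!r}")
        if bn.channels != len(mask):
            raise ValueError(f"plan mask for {name!r} has {len(mask)} channels, "
                             f"layer has {bn.channels}")
        masks_by_id[id(bn)] = np.asarray(mask, dtype=bool)
    ap = _Apply(masks_by_id)
    if isinstance(net, DetectorModel):
        b = net.backbone
        if hasattr(b, "dark2"):
            x = ap.run(b.stem, None, None)
            x = ap.run(b.dark2, *x)
            c3 = ap.run(b.dark3, *x)
            c4 = ap.run(b.dark4, *c3)
            c5 = ap.run(b.dark5, *c4)
        else:
            x = ap.run(b.stem, None, None)
            x = ap.run(b.stage2, *x)
            c3 = ap.run(b.stage3, *x)
            c4 = ap.run(b.stage4, *c3)
            c5 = ap.run(b.stage5, *c4)
        nk = net.neck
        fpn0 = ap.run(nk.lateral_conv0, *c5)
        f0 = ap.run(nk.C3_p4, np.concatenate([fpn0[0], c4[0]]),
                    np.concatenate([fpn0[1], c4[1]]))
        fpn1 = ap.run(nk.reduce_conv1, *f0)
        pan2 = ap.run(nk.C3_p3, np.concatenate([fpn1[0], c3[0]]),
                      np.concatenate([fpn1[1], c3[1]]))
        bu2 = ap.run(nk.bu_conv2, *pan2)
        pan1 = ap.run(nk.C3_n3, np.concatenate([bu2[0], fpn1[0]]),
                      np.concatenate([bu2[1], fpn1[1]]))
        bu1 = ap.run(nk.bu_conv1, *pan1)
        pan0 = ap.run(nk.C3_n4, np.concatenate([bu1[0], fpn0[0]]),
                      np.concatenate([bu1[1], fpn0[1]]))
        feats = [pan2, pan1, pan0]
        if net.asff is not None:
            fused = []
            for fuse in net.asff:
                aligned = []
                for i in range(3):
                    aligned.append(ap.run(fuse.resize[i], *feats[i]))
                for i in range(3):
                    ap.run(fuse.weight_convs[i], aligned[i][0], aligned[i][1])
                # ties force identical masks; constants blend with unknown
                # weights, approximate by the target level's constants
                fused.append(aligned[fuse.target])
            feats = fused
        hd = net.head
        for i in range(3):
            st = ap.run(hd.stems[i], *feats[i])
            ck = ap.run(hd.cls_convs[i], *st)
            rk = ap.run(hd.reg_convs[i], *st)
            ap.run(hd.cls_preds[i], ck[0], ck[1])
            ap.run(hd.reg_preds[i], rk[0], rk[1])
            ap.run(hd.obj_preds[i], rk[0], rk[1])
    else:
        ap.run(net, None, None)
    return net


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def finetune(network, items, epochs: int = 10, batch_size: int = 8,
             peak_lr: float = 0.01, warmup_fraction: float = 0.1,
             momentum: float = 0.93, weight_decay: float = 5e-4,
             seed: int = 0, history: list | None = None):
    """Accuracy-recovery training with linear warm-up to `peak_lr` followed
    by cosine decay; lr at step 0 is a fraction of the peak."""
    if epochs == 0:
        return network, (history if history is not None else [])

    def lr_fn(t, T):
        warm = max(1, int(warmup_fraction * T))
        if t < warm:
            return peak_lr * (t + 1) / (warm + 1)
        return cosine_lr(t - warm, max(T - warm, 1), peak_lr)

    hist = run_training(network, items, epochs=epochs, batch_size=batch_size,
                        lr=peak_lr, momentum=momentum, weight_decay=weight_decay,
                        seed=seed, lr_fn=lr_fn, history=history, phase="finetune")
    return network, hist
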