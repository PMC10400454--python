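import numpy as np
import pytest

from pestdet import nn
from pestdet.nn_blocks import ConvBnAct, GhostModule
from pestdet.detector import Bottleneck, CSPLayer


@pytest.fixture(scope="session")
def smoke_run():
    """One full desk-scale pipeline (synth -> two-phase train -> sparsity ->
    prune -> finetune -> eval), shared by the end-to-end tests."""
    from pestdet.pipeline import run_smoke_pipeline
    return run_smoke_pipeline(seed=0)


def make_compact_net(seed=0, cbase=8):
    """Small conv net exercising the pruning-relevant structures (plain
    conv-BN-act stacks, a ghost module, a residual bottleneck, a CSP layer)
    without ECA, ending in a fixed-output 1x1 conv."""
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        ConvBnAct(3, cbase, 3, stride=2, rng=rng),
        ConvBnAct(cbase, 2 * cbase, 3, stride=2, rng=rng),
        GhostModule(2 * cbase, 2 * cbase, k=1, s=2, rng=rng),
        Bottleneck(2 * cbase, 2 * cbase, shortcut=True, rng=rng),
        CSPLayer(2 * cbase, 2 * cbase, n=1, shortcut=False, rng=rng),
        nn.Conv2d(2 * cbase, 4, 1, bias=True, rng=rng),
    )


def randomize_bn_stats(net, seed=0):
    """Give every BN realistic non-default statistics and affine params so
    eval-mode behavior is nontrivial."""
    rng = np.random.default_rng(seed)
    for m in net.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.gamma.data = rng.uniform(0.3, 1.5, m.channels).astype(np.float32)
            m.beta.data = rng.normal(0, 0.4, m.channels).astype(np.float32)
            m.running_mean = rng.normal(0, 0.3, m.channels).astype(np.float32)
            m.running_var = rng.uniform(0.5, 2.0, m.channels).astype(np.float32)
    return net
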