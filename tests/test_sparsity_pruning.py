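"""Channel-pruning workflow tests: L1 penalty, global ranking, plan
construction (quantile, floor, couplings), function-preserving application
with bias absorption, and the sparsity-training effect on BN scales."""

import copy

import numpy as np
import pytest

from pestdet import nn
from pestdet.autograd import Tensor, no_grad
from pestdet.detector import build_model
from pestdet.nn_blocks import ConvBnAct
from pestdet.sparsity_pruning import (PruningPlan, SparsityConfig,
                                      apply_pruning, build_pruning_plan,
                                      finetune, load_plan, prunable_bns,
                                      rank_channels, save_plan,
                                      sparsity_penalty, sparsity_train)

from conftest import make_compact_net, randomize_bn_stats


class TestSparsityPenalty:
    def test_zero_lambda(self):
        assert sparsity_penalty([1.0, -2.0, 3.0], 0.0) == 0.0

    def test_reference_value(self):
        assert sparsity_penalty([1.0, -2.0, 3.0], 0.001) == pytest.approx(0.006)

    def test_all_zero_scales(self):
        assert sparsity_penalty(np.zeros(10), 0.5) == 0.0

    def test_list_of_arrays(self):
        assert sparsity_penalty([np.array([1.0, -1.0]), np.array([2.0])],
                                0.1) == pytest.approx(0.4)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            sparsity_penalty([1.0], -0.1)


def _chain_net(gammas, seed=0):
    """Plain conv chain with prescribed BN gammas (no couplings)."""
    rng = np.random.default_rng(seed)
    mods = []
    cin = 3
    for g in gammas:
        m = ConvBnAct(cin, len(g), 3, rng=rng)
        m.bn.gamma.data = np.asarray(g, dtype=np.float32)
        mods.append(m)
        cin = len(g)
    mods.append(nn.Conv2d(cin, 2, 1, bias=True, rng=rng))
    return nn.Sequential(*mods)


class TestRankChannels:
    def test_global_ascending_order(self):
        net = _chain_net([[0.1, 0.5], [0.2]])
        rows = rank_channels(net)
        assert [r[0] for r in rows] == pytest.approx([0.1, 0.2, 0.5])

    def test_tie_break_by_provenance(self):
        net = _chain_net([[0.3, 0.3], [0.3]])
        rows = rank_channels(net)
        assert [(r[1], r[2]) for r in rows] == [(0, 0), (0, 1), (1, 0)]

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(5)
        gam = [rng.uniform(0, 2, 7).tolist(), rng.uniform(0, 2, 5).tolist()]
        net = _chain_net(gam)
        rows = rank_channels(net)
        want = sorted(abs(v) for layer in gam for v in layer)
        assert [r[0] for r in rows] == pytest.approx(want)

    def test_no_prunable_layers_rejected(self):
        net = nn.Sequential(nn.Conv2d(3, 4, 1))
        with pytest.raises(ValueError):
            rank_channels(net)


class TestBuildPlan:
    def test_ratio_zero_keeps_everything(self):
        net = _chain_net([[0.1, 0.5, 0.9], [0.2, 0.4]])
        plan = build_pruning_plan(net, 0.0)
        assert plan.n_pruned() == 0

    def test_ten_channel_quantile_example(self):
        # 10 distinct gammas, ratio 0.65 -> nearest-rank threshold at index
        # floor(6.5)=6 -> exactly 6 channels pruned
        gammas = [[0.05, 0.25, 0.45, 0.65, 0.85], [0.15, 0.35, 0.55, 0.75, 0.95]]
        net = _chain_net(gammas)
        plan = build_pruning_plan(net, 0.65)
        assert plan.n_pruned() == 6
        assert plan.threshold == pytest.approx(0.65)

    def test_floor_keeps_one_channel(self):
        # every gamma of layer 0 falls below the threshold -> 1 survivor
        net = _chain_net([[0.01, 0.02, 0.03], [1.0, 1.1, 1.2, 1.3]])
        plan = build_pruning_plan(net, threshold=0.5)
        masks = plan.keep_masks
        first = [k for k in masks if "0" in k.split(".")[0]][0]
        assert masks[first].sum() == 1
        assert masks[first][2]  # the largest |gamma| survives

    def test_achieved_fraction_within_two_points_on_uncoupled_net(self):
        rng = np.random.default_rng(11)
        gammas = [rng.uniform(0.01, 2.0, 40).tolist(),
                  rng.uniform(0.01, 2.0, 48).tolist(),
                  rng.uniform(0.01, 2.0, 32).tolist()]
        net = _chain_net(gammas)
        total = sum(len(g) for g in gammas)
        assert total >= 100
        for ratio in (0.3, 0.5, 0.65):
            plan = build_pruning_plan(net, ratio)
            assert abs(plan.achieved_fraction - ratio) <= 0.02

    def test_max_layer_prune_cap(self):
        net = _chain_net([[0.01, 0.02, 0.03, 0.04], [1.0, 1.1, 1.2, 1.3]])
        plan = build_pruning_plan(net, threshold=0.5, max_layer_prune=0.5)
        first = sorted(plan.keep_masks)[0]
        assert plan.keep_masks[first].sum() == 2

    def test_invalid_ratio(self):
        net = _chain_net([[0.5, 0.5]])
        with pytest.raises(ValueError):
            build_pruning_plan(net, 1.0)

    def test_plan_json_round_trip(self, tmp_path):
        net = _chain_net([[0.1, 0.9], [0.2, 0.8]])
        plan = build_pruning_plan(net, 0.5)
        save_plan(tmp_path / "p.json", plan)
        back = load_plan(tmp_path / "p.json")
        assert back.ratio == plan.ratio
        assert back.threshold == pytest.approx(plan.threshold)
        for k in plan.keep_masks:
            assert np.array_equal(back.keep_masks[k], plan.keep_masks[k])


def _forward(net, x):
    net.eval()
    with no_grad():
        return net(Tensor(x)).data


class TestApplyPruning:
    def test_ratio_zero_behavior_identical(self):
        net = randomize_bn_stats(make_compact_net(seed=1), seed=2)
        plan = build_pruning_plan(net, 0.0)
        pruned = apply_pruning(net, plan)
        x = np.random.default_rng(0).standard_normal((2, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(_forward(net, x), _forward(pruned, x))

    @pytest.mark.parametrize("seed", range(3))
    def test_gamma_zero_channels_prune_exactly(self, seed):
        """Channels with gamma=0 contribute a constant act(beta); removing
        them with bias absorption must preserve eval outputs to 1e-5."""
        net = randomize_bn_stats(make_compact_net(seed=seed), seed=seed + 10)
        rng = np.random.default_rng(seed + 20)
        zeroed = 0
        for name, bn in prunable_bns(net):
            if bn.channels >= 8 and rng.uniform() < 0.8:
                k = rng.integers(1, 3)
                idx = rng.choice(bn.channels, size=k, replace=False)
                bn.gamma.data[idx] = 0.0
                zeroed += k
        plan = build_pruning_plan(net, threshold=1e-9)
        pruned = apply_pruning(net, plan)
        assert plan.n_pruned() >= 1
        assert pruned.num_params() < net.num_params()
        for s in range(20):
            x = np.random.default_rng(100 + s).standard_normal(
                (1, 3, 32, 32)).astype(np.float32)
            diff = np.abs(_forward(net, x) - _forward(pruned, x)).max()
            assert diff < 1e-5

    def test_params_strictly_decrease(self):
        net = randomize_bn_stats(make_compact_net(seed=3), seed=4)
        for _, bn in prunable_bns(net):
            bn.gamma.data = np.random.default_rng(0).uniform(
                0.05, 1.5, bn.channels).astype(np.float32)
        plan = build_pruning_plan(net, 0.4)
        assert plan.n_pruned() > 0
        pruned = apply_pruning(net, plan)
        assert pruned.num_params() < net.num_params()
        x = np.zeros((1, 3, 32, 32), dtype=np.float32)
        _forward(pruned, x)  # still forward-evaluable

    def test_threshold_replay_is_idempotent(self):
        net = randomize_bn_stats(make_compact_net(seed=5), seed=6)
        for _, bn in prunable_bns(net):
            bn.gamma.data = np.random.default_rng(1).uniform(
                0.05, 1.5, bn.channels).astype(np.float32)
        plan = build_pruning_plan(net, 0.5)
        pruned = apply_pruning(net, plan)
        replay = build_pruning_plan(pruned, threshold=plan.threshold)
        assert replay.n_pruned() == 0

    def test_detector_pruning_preserves_interface(self):
        model = build_model("pest-smoke", seed=2)
        for _, bn in prunable_bns(model):
            bn.gamma.data = np.random.default_rng(3).uniform(
                0.05, 1.5, bn.channels).astype(np.float32)
        plan = build_pruning_plan(model, 0.5, max_layer_prune=0.5)
        pruned = apply_pruning(model, plan)
        assert pruned.num_params() < model.num_params()
        pruned.eval()
        with no_grad():
            outs = pruned(Tensor(np.zeros((1, 3, 256, 256), dtype=np.float32)))
        assert [o.shape for o in outs] == [
            (1, 7, 32, 32), (1, 7, 16, 16), (1, 7, 8, 8)]

    def test_mismatched_plan_rejected(self):
        a = make_compact_net(seed=1)
        plan = build_pruning_plan(a, 0.0)
        plan.keep_masks["nonexistent.bn"] = np.ones(4, dtype=bool)
        with pytest.raises(ValueError):
            apply_pruning(a, plan)


def _sparsity_items(n=6, size=128):
    from pestdet.synth_fixtures import SceneSpec, generate_scene
    return [generate_scene(SceneSpec(size=size, n_larvae=1, seed=400 + i))
            for i in range(n)]


class TestSparsityTraining:
    def test_l1_reduces_median_gamma_vs_unpenalized(self):
        """Same seed, same data: the only difference between the runs is the
        L1 subgradient on BN scales, so |gamma| must shrink relative to the
        unpenalized twin."""
        from pestdet.detector import get_config
        items = _sparsity_items()
        medians = {}
        for lam in (0.0, 0.001):
            model = build_model(get_config("pest-smoke", input_size=128), seed=7)
            sparsity_train(model, items,
                           SparsityConfig(penalty=lam, epochs=3, batch_size=3),
                           seed=21)
            gam = np.concatenate([np.abs(bn.gamma.data)
                                  for _, bn in prunable_bns(model)])
            medians[lam] = np.median(gam)
        assert medians[0.001] < medians[0.0]

    def test_finetune_zero_epochs_identity(self):
        net = make_compact_net(seed=8)
        model = build_model("pest-smoke", seed=8)
        before = model.state_dict()
        finetune(model, _sparsity_items(2), epochs=0)
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_finetune_warmup_starts_below_peak(self):
        from pestdet.sparsity_pruning import cosine_lr
        # reproduce the schedule: lr at step 0 must be < peak
        peak = 0.01
        warm = max(1, int(0.1 * 100))
        lr0 = peak * 1 / (warm + 1)
        assert lr0 < peak

    def test_finetune_reduces_loss(self):
        from pestdet.detector import get_config
        model = build_model(get_config("pest-smoke", input_size=128), seed=9)
        model.head.init_priors()
        items = _sparsity_items(6)
        _, hist = finetune(model, items, epochs=4, batch_size=3, peak_lr=0.02,
                           seed=5)
        assert hist[-1]["total"] <= hist[0]["total"]
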