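"""Geometry and non-maximum-suppression tests, including independent oracles
(rasterized IoU; a direct sequential transcription of the soft-decay rule)."""

import math

import numpy as np
import pytest

from pestdet.postprocess import (Box, Detection, NmsConfig, decode_predictions,
                                 diou, hard_nms, iou, read_detections_tsv,
                                 soft_diou_nms, write_detections_tsv)

# ---------------------------------------------------------------------------
# independent oracles (deliberately different machinery from the library)
# ---------------------------------------------------------------------------


def raster_iou(a: Box, b: Box, cells=400):
    """IoU by counting sub-pixel raster cells over the joint extent."""
    x0 = min(a.x1, b.x1); x1 = max(a.x2, b.x2)
    y0 = min(a.y1, b.y1); y1 = max(a.y2, b.y2)
    xs = np.linspace(x0, x1, cells, endpoint=False) + (x1 - x0) / cells / 2
    ys = np.linspace(y0, y1, cells, endpoint=False) + (y1 - y0) / cells / 2
    gx, gy = np.meshgrid(xs, ys)
    in_a = (gx >= a.x1) & (gx < a.x2) & (gy >= a.y1) & (gy < a.y2)
    in_b = (gx >= b.x1) & (gx < b.x2) & (gy >= b.y1) & (gy < b.y2)
    union = (in_a | in_b).sum()
    return (in_a & in_b).sum() / union if union else 0.0


def oracle_diou(a: Box, b: Box, cells=400):
    cax, cay = (a.x1 + a.x2) / 2, (a.y1 + a.y2) / 2
    cbx, cby = (b.x1 + b.x2) / 2, (b.y1 + b.y2) / 2
    rho2 = (cax - cbx) ** 2 + (cay - cby) ** 2
    c2 = ((max(a.x2, b.x2) - min(a.x1, b.x1)) ** 2
          + (max(a.y2, b.y2) - min(a.y1, b.y1)) ** 2)
    return raster_iou(a, b, cells) - rho2 / c2


def oracle_soft_diou_nms(dets, nt, sigma, floor):
    """Direct sequential transcription of the decay rule: repeatedly take the
    highest-scoring remaining box; every other box with DIoU >= nt gets its
    score multiplied by exp(-DIoU^2/sigma); finally drop scores < floor."""
    def d_iou(e, f):
        ix = min(e.x2, f.x2) - max(e.x1, f.x1)
        iy = min(e.y2, f.y2) - max(e.y1, f.y1)
        inter = max(ix, 0) * max(iy, 0)
        ua = ((e.x2 - e.x1) * (e.y2 - e.y1) + (f.x2 - f.x1) * (f.y2 - f.y1)
              - inter)
        i = inter / ua
        rho2 = (((e.x1 + e.x2) - (f.x1 + f.x2)) ** 2
                + ((e.y1 + e.y2) - (f.y1 + f.y2)) ** 2) / 4.0
        c2 = ((max(e.x2, f.x2) - min(e.x1, f.x1)) ** 2
              + (max(e.y2, f.y2) - min(e.y1, f.y1)) ** 2)
        return i - rho2 / c2

    out = []
    for cid in {d.class_id for d in dets}:
        live = [[d.box, d.score] for d in dets if d.class_id == cid]
        live.sort(key=lambda r: (-r[1], r[0].x1, r[0].y1, r[0].x2, r[0].y2))
        done = []
        while live:
            m = max(range(len(live)), key=lambda i: (live[i][1], -i))
            box, sc = live.pop(m)
            done.append((box, sc))
            for r in live:
                d = d_iou(box, r[0])
                if d >= nt:
                    r[1] *= math.exp(-d * d / sigma)
        out += [(b, s, cid) for b, s in done if s >= floor]
    return sorted(out, key=lambda r: (-r[1], r[0].x1, r[0].y1, r[0].x2,
                                      r[0].y2, r[2]))


def random_detections(rng, n, classes=1):
    dets = []
    for _ in range(n):
        x1, y1 = rng.uniform(0, 60, 2)
        w, h = rng.uniform(5, 40, 2)
        dets.append(Detection(Box(x1, y1, x1 + w, y1 + h),
                              float(np.round(rng.uniform(0.05, 1.0), 4)),
                              int(rng.integers(classes))))
    return dets


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestIouDiou:
    def test_identical_boxes(self):
        b = Box(1, 2, 4, 7)
        assert iou(b, b) == 1.0
        assert diou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 1, 1), Box(5, 5, 6, 6)) == 0.0

    def test_reference_overlap(self):
        e, f = Box(0, 0, 2, 2), Box(1, 1, 3, 3)
        assert iou(e, f) == pytest.approx(1 / 7)
        assert diou(e, f) == pytest.approx(1 / 7 - 2 / 18)

    @pytest.mark.parametrize("seed", range(12))
    def test_agreement_with_rasterization_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_detections(rng, 1)[0].box
        b = random_detections(rng, 1)[0].box
        assert iou(a, b) == pytest.approx(raster_iou(a, b), abs=1e-2)
        assert diou(a, b) == pytest.approx(oracle_diou(a, b), abs=1e-2)

    def test_diou_limit_for_distant_boxes(self):
        base = Box(0, 0, 2, 2)
        vals = [diou(base, Box(d, 0, d + 2, 2)) for d in (10, 100, 1000)]
        assert vals[0] > vals[1] > vals[2] > -1.0
        assert vals[2] == pytest.approx(-1.0, abs=0.02)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(3, 0, 3, 2)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

class TestDecode:
    def _empty_maps(self, ncls=2, sizes=((8, 8), (4, 4), (2, 2))):
        return [np.full((5 + ncls, h, w), -20.0, dtype=np.float32)
                for h, w in sizes]

    def test_all_objectness_low_gives_empty(self):
        assert decode_predictions(self._empty_maps()) == []

    def test_single_peak_decodes_to_one_box(self):
        maps = self._empty_maps()
        m = maps[1]  # stride 16
        m[4, 2, 3] = 20.0          # objectness logit
        m[5 + 1, 2, 3] = 20.0      # class 1
        m[0, 2, 3] = 0.5           # dx
        m[1, 2, 3] = 0.0           # dy
        m[2, 2, 3] = math.log(2.0)  # w = 2*stride
        m[3, 2, 3] = 0.0            # h = stride
        dets = decode_predictions(maps, score_threshold=0.5)
        assert len(dets) == 1
        d = dets[0]
        assert d.class_id == 1
        assert d.box.center == pytest.approx((3.5 * 16, 2.0 * 16))
        assert (d.box.x2 - d.box.x1, d.box.y2 - d.box.y1) == pytest.approx((32, 16))
        assert d.score == pytest.approx(1.0, abs=1e-6)

    def test_score_is_product_of_obj_and_class(self):
        maps = self._empty_maps()
        maps[0][4, 1, 1] = 0.0      # sigmoid = 0.5
        maps[0][5, 1, 1] = 0.0      # sigmoid = 0.5
        maps[0][2:4, 1, 1] = 0.0
        dets = decode_predictions(maps, score_threshold=0.2)
        assert len(dets) == 1
        assert dets[0].score == pytest.approx(0.25, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_predictions([np.zeros((3, 4, 4), dtype=np.float32)] * 3)


# ---------------------------------------------------------------------------
# suppression
# ---------------------------------------------------------------------------

class TestSoftDiouNms:
    def test_single_detection_unchanged(self):
        d = [Detection(Box(0, 0, 10, 10), 0.7)]
        out = soft_diou_nms(d, NmsConfig())
        assert len(out) == 1 and out[0].score == 0.7

    def test_below_threshold_pair_keeps_scores(self):
        dets = [Detection(Box(0, 0, 10, 10), 0.9),
                Detection(Box(30, 30, 40, 40), 0.8)]
        out = soft_diou_nms(dets, NmsConfig())
        assert sorted(d.score for d in out) == [0.8, 0.9]

    def test_three_box_decay_matches_hand_computation(self):
        cfg = NmsConfig(threshold=0.5, sigma=0.5)
        b1 = Box(0, 0, 10, 10)
        b2 = Box(1, 1, 11, 11)   # heavy overlap with b1
        b3 = Box(40, 0, 50, 10)  # far away
        dets = [Detection(b1, 0.9), Detection(b2, 0.8), Detection(b3, 0.7)]
        out = {round(d.box.x1): d.score for d in soft_diou_nms(dets, cfg)}
        d12 = diou(b1, b2)
        assert d12 >= 0.5
        assert out[0] == 0.9
        assert out[1] == pytest.approx(0.8 * math.exp(-d12 ** 2 / 0.5), rel=1e-9)
        assert out[40] == 0.7

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_sequential_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        dets = random_detections(rng, int(rng.integers(1, 11)), classes=2)
        cfg = NmsConfig(threshold=0.5, sigma=0.5, score_floor=1e-3)
        got = soft_diou_nms(dets, cfg)
        want = oracle_soft_diou_nms(dets, 0.5, 0.5, 1e-3)
        assert len(got) == len(want)
        for g, (box, score, cid) in zip(got, want):
            assert g.box == box and g.class_id == cid
            assert g.score == pytest.approx(score, rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_scores_never_increase(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, 8)
        before = {(d.box, d.class_id): d.score for d in dets}
        for d in soft_diou_nms(dets, NmsConfig()):
            assert d.score <= before[(d.box, d.class_id)] + 1e-12

    @pytest.mark.parametrize("seed", range(20))
    def test_sigma_to_zero_recovers_hard_diou(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, 9)
        cfg_soft = NmsConfig(threshold=0.5, sigma=1e-12, score_floor=1e-3)
        cfg_hard = NmsConfig(method="hard_diou", threshold=0.5)
        soft_boxes = {(d.box, d.class_id) for d in soft_diou_nms(dets, cfg_soft)}
        hard_boxes = {(d.box, d.class_id) for d in hard_nms(dets, cfg_hard)}
        assert soft_boxes == hard_boxes

    @pytest.mark.parametrize("seed", range(10))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        dets = random_detections(rng, 7)
        ref = soft_diou_nms(dets, NmsConfig())
        perm = [dets[i] for i in rng.permutation(len(dets))]
        got = soft_diou_nms(perm, NmsConfig())
        assert [(d.box, round(d.score, 9)) for d in ref] \
            == [(d.box, round(d.score, 9)) for d in got]

    def test_class_locality(self):
        # same geometry, different classes: no interaction
        dets = [Detection(Box(0, 0, 10, 10), 0.9, 0),
                Detection(Box(0.5, 0.5, 10.5, 10.5), 0.8, 1)]
        out = soft_diou_nms(dets, NmsConfig())
        assert sorted(d.score for d in out) == [0.8, 0.9]

    def test_empty_input(self):
        assert soft_diou_nms([], NmsConfig()) == []


class TestHardNms:
    def test_duplicate_pair_one_survivor(self):
        dets = [Detection(Box(0, 0, 10, 10), 0.9),
                Detection(Box(0, 0, 10, 10.0001), 0.8)]
        assert len(hard_nms(dets, NmsConfig(method="hard_iou"))) == 1

    def test_measure_choice_matters_for_offset_centers(self):
        # construct a pair with IoU >= 0.5 but DIoU < 0.5
        e = Box(0, 0, 10, 10)
        f = Box(3.2, 0, 13.2, 10)
        assert iou(e, f) >= 0.5 > diou(e, f)
        dets = [Detection(e, 0.9), Detection(f, 0.8)]
        kept_iou = hard_nms(dets, NmsConfig(method="hard_iou"))
        kept_diou = hard_nms(dets, NmsConfig(method="hard_diou"))
        assert len(kept_iou) == 1 and len(kept_diou) == 2

    def test_empty_input(self):
        assert hard_nms([], NmsConfig(method="hard_iou")) == []


def test_detections_tsv_round_trip(tmp_path):
    dets = [Detection(Box(1.25, 2.5, 10.75, 20.0), 0.625, 1, "img_3")]
    path = tmp_path / "dets.tsv"
    write_detections_tsv(path, dets)
    back = read_detections_tsv(path)
    assert len(back) == 1
    assert back[0].image_id == "img_3" and back[0].class_id == 1
    assert back[0].score == pytest.approx(0.625)
    assert back[0].box == Box(1.25, 2.5, 10.75, 20.0)


def test_nms_config_validation():
    with pytest.raises(ValueError):
        NmsConfig(threshold=0.0)
    with pytest.raises(ValueError):
        NmsConfig(sigma=0.0)
    with pytest.raises(ValueError):
        NmsConfig(method="matrix")
    with pytest.raises(ValueError):
        Detection(Box(0, 0, 1, 1), 1.5)
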