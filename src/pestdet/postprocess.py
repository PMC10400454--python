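"""Prediction decoding and non-maximum suppression.

Boxes use continuous corner coordinates (x1, y1, x2, y2), origin at the
top-left, so areas are exact products.  Suppression is class-local and offers
three methods: classical greedy NMS with either IoU or DIoU as the overlap
measure, and the soft variant that decays scores by exp(-DIoU^2 / sigma)
instead of deleting overlapping boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box", "Detection", "NmsConfig",
    "iou", "diou", "decode_predictions", "soft_diou_nms", "hard_nms", "run_nms",
    "write_detections_tsv", "read_detections_tsv",
]


@dataclass(frozen=True)
class Box:
    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if not (self.x2 > self.x1 and self.y2 > self.y1):
            raise ValueError(f"degenerate box {(self.x1, self.y1, self.x2, self.y2)}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)


@dataclass
class Detection:
    box: Box
    score: float
    class_id: int = 0
    image_id: str = ""

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class NmsConfig:
    method: str = "soft_diou"       # hard_iou | hard_diou | soft_diou
    threshold: float = 0.5          # N_t
    sigma: float = 0.5              # decay coefficient of the soft branch
    score_floor: float = 1e-3       # final pruning of decayed scores

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.method not in ("hard_iou", "hard_diou", "soft_diou"):
            raise ValueError(f"unknown NMS method {self.method!r}")


def iou(e: Box, f: Box) -> float:
    """Intersection-over-union of two boxes; in [0, 1]."""
    ix = min(e.x2, f.x2) - max(e.x1, f.x1)
    iy = min(e.y2, f.y2) - max(e.y1, f.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (e.area + f.area - inter)


def diou(e: Box, f: Box) -> float:
    """Distance-IoU: IoU minus squared center distance over squared enclosing
    diagonal; in (-1, 1]."""
    (ex, ey), (fx, fy) = e.center, f.center
    rho2 = (ex - fx) ** 2 + (ey - fy) ** 2
    cx = max(e.x2, f.x2) - min(e.x1, f.x1)
    cy = max(e.y2, f.y2) - min(e.y1, f.y1)
    c2 = cx * cx + cy * cy
    return iou(e, f) - rho2 / c2


def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))


def decode_predictions(head_outputs, strides=(8, 16, 32), score_threshold: float = 0.05,
                       image_id: str = "") -> list[Detection]:
    """Decode raw anchor-free head maps into detections for one image.

    Each map is (5+C, H, W) (or (1, 5+C, H, W)) with channels
    [dx, dy, log w, log h, objectness, class logits...].  Cell (i, j) at
    stride s yields center ((j + dx)*s, (i + dy)*s) and size (e^w * s,
    e^h * s).  Score is sigmoid(obj) * max_c sigmoid(cls_c); detections below
    `score_threshold` are dropped.
    """
    if len(head_outputs) != len(strides):
        raise ValueError("one output map per stride expected")
    dets: list[Detection] = []
    for out, stride in zip(head_outputs, strides):
        arr = np.asarray(getattr(out, "data", out), dtype=np.float64)
        if arr.ndim == 4:
            if arr.shape[0] != 1:
                raise ValueError("decode_predictions handles one image at a time")
            arr = arr[0]
        if arr.ndim != 3 or arr.shape[0] < 6:
            raise ValueError(f"bad head output shape {arr.shape}")
        _, h, w = arr.shape
        obj = _sigmoid(arr[4])
        cls = _sigmoid(arr[5:])
        best_c = cls.argmax(axis=0)
        score = obj * np.take_along_axis(cls, best_c[None], axis=0)[0]
        ii, jj = np.nonzero(score >= score_threshold)
        for i, j in zip(ii, jj):
            cx = (j + arr[0, i, j]) * stride
            cy = (i + arr[1, i, j]) * stride
            bw = math.exp(min(arr[2, i, j], 12.0)) * stride
            bh = math.exp(min(arr[3, i, j], 12.0)) * stride
            if bw <= 0 or bh <= 0:
                continue
            dets.append(Detection(
                Box(cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2),
                float(min(score[i, j], 1.0)), int(best_c[i, j]), image_id))
    return dets


def _canonical_order(dets):
    """Deterministic, permutation-invariant ordering: score desc, then box
    coordinates and class lexicographically."""
    return sorted(range(len(dets)), key=lambda i: (
        -dets[i].score, dets[i].box.x1, dets[i].box.y1,
        dets[i].box.x2, dets[i].box.y2, dets[i].class_id))


def soft_diou_nms(dets: list[Detection], cfg: NmsConfig | None = None) -> list[Detection]:
    """Soft DIoU-NMS, per class.

    Repeatedly selects the highest-scoring remaining box M; every other box b
    with DIoU(M, b) >= N_t has its score multiplied by exp(-DIoU^2 / sigma)
    (compounding across iterations), boxes below N_t keep their score.  After
    all boxes have been selected, those whose decayed score fell below
    `score_floor` are dropped; survivors are returned sorted by final score.
    """
    cfg = cfg or NmsConfig()
    out: list[Detection] = []
    for cid in sorted({d.class_id for d in dets}):
        group = [d for d in dets if d.class_id == cid]
        order = _canonical_order(group)
        scores = [group[i].score for i in order]
        boxes = [group[i].box for i in order]
        meta = [group[i] for i in order]
        remaining = list(range(len(order)))
        finals: list[tuple[int, float]] = []
        while remaining:
            m = max(remaining, key=lambda i: (scores[i], -i))
            remaining.remove(m)
            finals.append((m, scores[m]))
            for i in remaining:
                d = diou(boxes[m], boxes[i])
                if d >= cfg.threshold:
                    scores[i] *= math.exp(-(d * d) / cfg.sigma)
        for i, s in finals:
            if s >= cfg.score_floor:
                out.append(Detection(boxes[i], s, cid, meta[i].image_id))
    out.sort(key=lambda d: (-d.score, d.box.x1, d.box.y1, d.box.x2, d.box.y2, d.class_id))
    return out


def hard_nms(dets: list[Detection], cfg: NmsConfig | None = None) -> list[Detection]:
    """Classical greedy suppression with the configured overlap measure
    (IoU for method 'hard_iou', DIoU for 'hard_diou'/'soft_diou')."""
    cfg = cfg or NmsConfig(method="hard_diou")
    measure = iou if cfg.method == "hard_iou" else diou
    out: list[Detection] = []
    for cid in sorted({d.class_id for d in dets}):
        group = [d for d in dets if d.class_id == cid]
        order = _canonical_order(group)
        kept_boxes: list[Box] = []
        for i in order:
            if all(measure(kb, group[i].box) < cfg.threshold for kb in kept_boxes):
                kept_boxes.append(group[i].box)
                out.append(group[i])
    out.sort(key=lambda d: (-d.score, d.box.x1, d.box.y1, d.box.x2, d.box.y2, d.class_id))
    return out


def run_nms(dets: list[Detection], cfg: NmsConfig) -> list[Detection]:
    if cfg.method == "soft_diou":
        return soft_diou_nms(dets, cfg)
    return hard_nms(dets, cfg)


def write_detections_tsv(path, dets: list[Detection]):
    with open(path, "w") as fh:
        fh.write("image_id\tclass\tscore\tx1\ty1\tx2\ty2\n")
        for d in dets:
            fh.write(f"{d.image_id}\t{d.class_id}\t{d.score:.6f}"
                     f"\t{d.box.x1:.2f}\t{d.box.y1:.2f}\t{d.box.x2:.2f}\t{d.box.y2:.2f}\n")


def read_detections_tsv(path) -> list[Detection]:
    dets = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("image_id"):
            raise ValueError("not a detections TSV (missing header)")
        for line in fh:
            img, cid, s, x1, y1, x2, y2 = line.rstrip("\n").split("\t")
            dets.append(Detection(Box(float(x1), float(y1), float(x2), float(y2)),
                                  float(s), int(cid), img))
    return dets
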