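"""Detection evaluation: greedy matching, precision/recall/F1, average
precision as the area under the precision-recall curve, mAP and throughput.

AP uses all-point interpolation by default (the integral form of the PR
area); 11-point interpolation is available as an option.  Matching IoU
threshold defaults to 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .postprocess import Box, Detection, iou

__all__ = [
    "MatchConfig", "EvalResult", "ThroughputStat",
    "match_detections", "precision", "recall", "f1",
    "average_precision", "mean_ap", "fps", "evaluate", "write_eval_json",
]


@dataclass(frozen=True)
class MatchConfig:
    iou_threshold: float = 0.5
    interpolation: str = "all_point"   # all_point | eleven_point

    def __post_init__(self):
        if not (0.0 < self.iou_threshold < 1.0):
            raise ValueError("iou_threshold must lie in (0, 1)")
        if self.interpolation not in ("all_point", "eleven_point"):
            raise ValueError("interpolation must be all_point or eleven_point")


@dataclass
class ThroughputStat:
    n_images: int
    total_seconds: float

    @property
    def fps(self) -> float:
        return fps(self.n_images, self.total_seconds)


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ap_per_class: dict
    map: float

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "precision": self.precision, "recall": self.recall, "F1": self.f1,
            "AP": {str(k): (None if v is None or math.isnan(v) else v)
                   for k, v in self.ap_per_class.items()},
            "mAP": self.map,
        }


def match_detections(dets: list[Detection], truths: list[tuple[int, Box]],
                     cfg: MatchConfig | None = None):
    """Greedy matching of score-sorted detections to ground truths.

    Each detection (in descending-score order) is matched to the unmatched
    same-class truth of highest IoU >= threshold (TP) else counted FP.
    Returns (flags aligned with the score-sorted detections, sorted
    detections, FN count).
    """
    cfg = cfg or MatchConfig()
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    used = [False] * len(truths)
    flags = []
    for i in order:
        d = dets[i]
        best, best_iou = -1, cfg.iou_threshold
        for t, (cid, tb) in enumerate(truths):
            if used[t] or cid != d.class_id:
                continue
            v = iou(d.box, tb)
            if v >= best_iou:
                best, best_iou = t, v
        if best >= 0:
            used[best] = True
            flags.append(True)
        else:
            flags.append(False)
    fn = used.count(False)
    return flags, [dets[i] for i in order], fn


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); 0/0 defined as 0."""
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); 0/0 defined as 0."""
    return tp / (tp + fn) if tp + fn else 0.0


def f1(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    return 2 * p * r / (p + r) if p + r else 0.0


def average_precision(flags, n_truths: int, interpolation: str = "all_point") -> float:
    """Area under the precision-envelope vs recall curve.

    `flags` are TP/FP indicators in descending-score order.  Returns NaN when
    there is no ground truth (AP undefined).
    """
    if n_truths == 0:
        return float("nan")
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    rec = tp / n_truths
    prec = tp / (tp + fp)
    # precision envelope: running max from the right
    env = np.maximum.accumulate(prec[::-1])[::-1]
    if interpolation == "eleven_point":
        pts = []
        for r in np.linspace(0, 1, 11):
            mask = rec >= r - 1e-12
            pts.append(env[mask].max() if mask.any() else 0.0)
        return float(np.mean(pts))
    r_prev = 0.0
    area = 0.0
    for i in range(len(rec)):
        if rec[i] > r_prev:
            area += (rec[i] - r_prev) * env[i]
            r_prev = rec[i]
    return float(area)


def mean_ap(aps) -> float:
    """Unweighted mean over classes with defined AP (NaN entries skipped)."""
    vals = [a for a in (aps.values() if isinstance(aps, dict) else aps)
            if a is not None and not math.isnan(a)]
    if not vals:
        raise ValueError("no class has a defined AP")
    return float(np.mean(vals))


def fps(n_images: int, total_seconds: float) -> float:
    if total_seconds <= 0:
        raise ValueError("total time must be > 0")
    return n_images / total_seconds


def evaluate(dets_by_image: dict, truths_by_image: dict,
             class_ids=(0, 1), cfg: MatchConfig | None = None) -> EvalResult:
    """Full evaluation over an image set.

    dets_by_image: image_id -> list[Detection]; truths_by_image:
    image_id -> list[(class_id, Box)].  AP is computed per class from the
    whole-dataset ranking; precision/recall/F1 from the pooled TP/FP/FN counts.
    """
    cfg = cfg or MatchConfig()
    total_tp = total_fp = total_fn = 0
    scored: dict = {c: [] for c in class_ids}   # (score, is_tp) per class
    truth_counts = {c: 0 for c in class_ids}
    for img in sorted(truths_by_image):
        truths = truths_by_image[img]
        dets = dets_by_image.get(img, [])
        flags, sdets, fn = match_detections(dets, truths, cfg)
        total_tp += sum(flags)
        total_fp += len(flags) - sum(flags)
        total_fn += fn
        for fl, d in zip(flags, sdets):
            if d.class_id in scored:
                scored[d.class_id].append((d.score, fl))
        for cid, _ in truths:
            if cid in truth_counts:
                truth_counts[cid] += 1
    aps = {}
    for c in class_ids:
        ranked = sorted(scored[c], key=lambda t: -t[0])
        aps[c] = average_precision([fl for _, fl in ranked], truth_counts[c],
                                   cfg.interpolation)
    p = precision(total_tp, total_fp)
    r = recall(total_tp, total_fn)
    return EvalResult(total_tp, total_fp, total_fn, p, r, f1(p, r), aps,
                      mean_ap(aps))


def write_eval_json(path, result: EvalResult, extra: dict | None = None):
    d = result.to_dict()
    if extra:
        d.update(extra)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
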