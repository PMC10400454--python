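"""Seeded generator of orchard-like scenes with larva proxies.

Scenes emulate the conditions the detector is meant for: textured foliage
background, one or more curved-capsule larvae of two visually distinct
classes ("young": brown, mottled; "old": green, smooth, with small head
protrusions), leaf-shaped occluders drawn over larvae to a requested covered
fraction, and front/side/back lighting transforms.  Ground truth is emitted
as VOC annotations with per-object occlusion metadata, so every downstream
module is testable without any external download.

The renderer is parametric and fully deterministic per seed; it makes no
attempt at photorealism (see docs/methods.md for what that implies for
transfer of test results to field imagery).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .postprocess import Box
from .voc_data import Annotation, VocObject, write_voc_tree

__all__ = ["SceneSpec", "generate_scene", "generate_dataset",
           "generate_from_manifest", "LIGHTING_MODES"]

LIGHTING_MODES = ("front", "side", "back")


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic scene."""
    size: int = 256
    n_larvae: int = 2
    young_fraction: float = 0.5
    occlusion_target: float = 0.0
    lighting: str = "front"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.occlusion_target < 1.0):
            raise ValueError("occlusion target must lie in [0, 1)")
        if self.n_larvae < 0:
            raise ValueError("n_larvae must be >= 0")
        if self.lighting not in LIGHTING_MODES:
            raise ValueError(f"lighting must be one of {LIGHTING_MODES}")


# ---------------------------------------------------------------------------
# drawing primitives
# ---------------------------------------------------------------------------

def _ellipse_mask(size, cy, cx, ry, rx, theta):
    y0 = max(0, int(cy - max(ry, rx) - 2))
    y1 = min(size, int(cy + max(ry, rx) + 3))
    x0 = max(0, int(cx - max(ry, rx) - 2))
    x1 = min(size, int(cx + max(ry, rx) + 3))
    if y0 >= y1 or x0 >= x1:
        return None, None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    c, s = np.cos(theta), np.sin(theta)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    m = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    return (slice(y0, y1), slice(x0, x1)), m


def _smooth_noise(rng, size, cells, lo, hi):
    g = rng.normal(0, 1, (cells, cells))
    up = np.kron(g, np.ones((size // cells + 1, size // cells + 1)))[:size, :size]
    up = ndimage.gaussian_filter(up, size / cells / 2)
    up -= up.min()
    if up.max() > 0:
        up /= up.max()
    return lo + (hi - lo) * up


def _background(rng, size):
    img = np.zeros((size, size, 3), dtype=np.float64)
    base = np.array([52.0, 96.0, 44.0])
    shade = _smooth_noise(rng, size, 8, 0.75, 1.25)
    img[:] = base
    # foliage blobs
    for _ in range(24):
        cy, cx = rng.uniform(0, size, 2)
        ry, rx = rng.uniform(size / 16, size / 5, 2)
        theta = rng.uniform(0, np.pi)
        sl, m = _ellipse_mask(size, cy, cx, ry, rx, theta)
        if sl is None:
            continue
        tint = base * rng.uniform(0.7, 1.35) + rng.normal(0, 6, 3)
        img[sl][m] = 0.55 * img[sl][m] + 0.45 * tint
    img *= shade[..., None]
    img += rng.normal(0, 3.0, img.shape)  # sensor speckle
    return img


def _bezier_spine(rng, size, length):
    margin = length * 0.6 + 8
    p0 = rng.uniform(margin, size - margin, 2)
    angle = rng.uniform(0, 2 * np.pi)
    d = np.array([np.cos(angle), np.sin(angle)])
    p2 = p0 + d * length
    perp = np.array([-d[1], d[0]])
    p1 = (p0 + p2) / 2 + perp * rng.uniform(-0.3, 0.3) * length
    t = np.linspace(0, 1, 64)[:, None]
    return ((1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2), t[:, 0]


def _draw_larva(rng, img, cls: str, occupied: np.ndarray):
    """Draw one larva; returns its pixel mask, or None if no free spot."""
    size = img.shape[0]
    for _ in range(25):
        length = rng.uniform(0.22, 0.38) * size
        r0 = length * rng.uniform(0.16, 0.22)
        spine, ts = _bezier_spine(rng, size, length)
        if spine.min() < r0 + 2 or spine.max() > size - r0 - 2:
            continue
        mask = np.zeros((size, size), dtype=bool)
        radii = r0 * (0.45 + 0.55 * np.sqrt(1 - (2 * ts - 1) ** 2))
        for (cy, cx), r in zip(spine, radii):
            sl, m = _ellipse_mask(size, cy, cx, r, r, 0.0)
            if sl is not None:
                mask[sl] |= m
        if (mask & occupied).sum() < 0.05 * mask.sum():
            break
    else:
        return None

    if cls == "young":
        base = np.array([118.0, 74.0, 40.0])   # brown, bird-dropping mottle
        mottle = _smooth_noise(rng, size, 32, 0.55, 1.45)
        color = base[None, None] * mottle[..., None]
        color += rng.normal(0, 10, color.shape)
    else:
        base = np.array([96.0, 176.0, 72.0])   # green, smooth
        grad = _smooth_noise(rng, size, 4, 0.9, 1.12)
        color = base[None, None] * grad[..., None]
    img[mask] = color[mask]

    if cls == "old":  # odoriferous horn protrusions near the head
        head, head_t = spine[-1], spine[-1] - spine[-8]
        perp = np.array([-head_t[1], head_t[0]])
        perp = perp / (np.linalg.norm(perp) + 1e-9)
        for sign in (-1, 1):
            c = head + sign * perp * radii[-1] * 0.8
            sl, m = _ellipse_mask(size, c[0], c[1], r0 * 0.22, r0 * 0.22, 0.0)
            if sl is not None:
                img[sl][m] = np.array([205.0, 130.0, 45.0])
                mask[sl] |= m
    occupied |= mask
    return mask


def _draw_leaf(rng, img, cy, cx, area):
    """Occluding leaf: darker green rotated ellipse with a vein line."""
    size = img.shape[0]
    aspect = rng.uniform(1.8, 2.6)
    rx = max(2.5, np.sqrt(area / (np.pi * aspect)))
    ry = rx * aspect
    theta = rng.uniform(0, np.pi)
    sl, m = _ellipse_mask(size, cy, cx, ry, rx, theta)
    if sl is None:
        return np.zeros(img.shape[:2], dtype=bool)
    tint = np.array([38.0, 82.0, 36.0]) * rng.uniform(0.85, 1.15)
    img[sl][m] = tint
    leaf = np.zeros(img.shape[:2], dtype=bool)
    leaf[sl] = m
    # vein: thin inner ellipse, lighter
    sl2, m2 = _ellipse_mask(size, cy, cx, ry * 0.85, rx * 0.12, theta)
    if sl2 is not None:
        img[sl2][m2] = tint * 1.45
    return leaf


def _apply_lighting(img, mode):
    size = img.shape[0]
    if mode == "front":
        out = img * 1.05 + 5.0
    elif mode == "side":
        omega = np.linspace(1.25, 0.7, size)[None, :, None]
        out = img * omega
    else:  # back-lighting: dim, washed out, desaturated
        gray = img.mean(axis=2, keepdims=True)
        out = (0.6 * img + 0.4 * gray) * 0.55 - 15.0
    return out


def generate_scene(spec: SceneSpec, return_masks: bool = False):
    """Render one scene; returns (uint8 image, Annotation) and optionally the
    per-larva and occluder masks used for the occlusion bookkeeping."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    img = _background(rng, size)
    occupied = np.zeros((size, size), dtype=bool)
    larvae = []  # (cls, mask)
    for _ in range(spec.n_larvae):
        cls = "young" if rng.uniform() < spec.young_fraction else "old"
        mask = _draw_larva(rng, img, cls, occupied)
        if mask is not None:
            larvae.append((cls, mask))

    occluders = np.zeros((size, size), dtype=bool)
    if spec.occlusion_target > 0:
        for cls, mask in larvae:
            area = mask.sum()
            for _ in range(40):
                covered = (mask & occluders).sum() / area
                if covered >= spec.occlusion_target - 0.04:
                    break
                need = (spec.occlusion_target - covered) * area
                free = np.argwhere(mask & ~occluders)
                if not len(free):
                    break
                cy, cx = free[rng.integers(len(free))]
                occluders |= _draw_leaf(rng, img, cy, cx, min(need * 1.2, area * 0.35))

    img = _apply_lighting(img, spec.lighting)
    img = np.clip(img + 0.5, 0, 255).astype(np.uint8)

    objects = []
    for cls, mask in larvae:
        ys, xs = np.nonzero(mask)
        occ = float((mask & occluders).sum() / mask.sum())
        objects.append(VocObject(cls, Box(float(xs.min()), float(ys.min()),
                                          float(xs.max() + 1), float(ys.max() + 1)),
                                 round(occ, 4)))
    ann = Annotation(f"scene_{spec.seed:08d}", size, size, objects)
    if return_masks:
        return img, ann, {"larvae": [m for _, m in larvae], "occluders": occluders}
    return img, ann


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def _specs_for_dataset(n_images, size, n_range, young_fraction,
                       occlusion_range, seed):
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_images):
        specs.append(SceneSpec(
            size=size,
            n_larvae=int(rng.integers(n_range[0], n_range[1] + 1)),
            young_fraction=young_fraction,
            occlusion_target=float(np.round(rng.uniform(*occlusion_range), 3)),
            lighting=LIGHTING_MODES[i % len(LIGHTING_MODES)],
            seed=int(rng.integers(0, 2 ** 31 - 1))))
    return specs


def generate_dataset(out_dir, n_images: int, size: int = 256,
                     n_range=(1, 3), young_fraction: float = 0.5,
                     occlusion_range=(0.0, 0.6), seed: int = 0,
                     force: bool = False) -> dict:
    """Render `n_images` scenes into a VOC directory tree plus manifest.json.

    Refuses a non-empty target directory unless `force` is set.  Returns the
    manifest (also written to disk) whose spec list replays byte-identically
    through :func:`generate_from_manifest`.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = str(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"target directory {out_dir} is not empty")
    specs = _specs_for_dataset(n_images, size, n_range, young_fraction,
                               occlusion_range, seed)
    items = [generate_scene(s) for s in specs]
    # unique image ids even if scene seeds collide
    for i, (img, ann) in enumerate(items):
        items[i] = (img, Annotation(f"scene_{i:04d}_{specs[i].seed:08d}",
                                    ann.width, ann.height, ann.objects))
    write_voc_tree(out_dir, items)
    manifest = {"n_images": n_images, "seed": seed, "size": size,
                "specs": [asdict(s) for s in specs]}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def generate_from_manifest(manifest: dict) -> list:
    """Replay a manifest into the identical list of (image, Annotation)."""
    items = []
    for i, sd in enumerate(manifest["specs"]):
        spec = SceneSpec(**sd)
        img, ann = generate_scene(spec)
        items.append((img, Annotation(f"scene_{i:04d}_{spec.seed:08d}",
                                      ann.width, ann.height, ann.objects)))
    return items
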