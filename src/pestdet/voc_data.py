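"""PASCAL VOC I/O, dataset splitting with occlusion stratification, and the
offline augmentation pipeline (5x expansion with photometric and geometric
transforms).

Coordinate convention: VOC stores 1-based inclusive pixel corners; internally
boxes are continuous corners with origin 0, mapped on read by subtracting 1
from all four values (VOC xmin=1 -> 0.0, box width = xmax - xmin) and mapped
back on write.  Occlusion fractions ride along in a non-standard
``<occlusion>`` element (absent means 0).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from lxml import etree
from PIL import Image
from scipy import ndimage

from .postprocess import Box

__all__ = [
    "CLASSES", "VocObject", "Annotation", "AugmentParams", "SplitSpec",
    "read_voc_xml", "write_voc_xml", "brightness_contrast",
    "expand_dataset", "split_dataset", "write_voc_tree", "load_voc_tree",
]

CLASSES = ("young", "old")


@dataclass
class VocObject:
    cls: str
    box: Box
    occlusion: float = 0.0

    def __post_init__(self):
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}; expected one of {CLASSES}")
        if not (0.0 <= self.occlusion <= 1.0):
            raise ValueError("occlusion fraction must lie in [0, 1]")


@dataclass
class Annotation:
    image_id: str
    width: int
    height: int
    objects: list = field(default_factory=list)

    def __post_init__(self):
        for o in self.objects:
            b = o.box
            if b.x1 < -1e-6 or b.y1 < -1e-6 or b.x2 > self.width + 1e-6 or b.y2 > self.height + 1e-6:
                raise ValueError(
                    f"bndbox {(b.x1, b.y1, b.x2, b.y2)} outside image "
                    f"{self.width}x{self.height} in {self.image_id}")

    @property
    def mean_occlusion(self) -> float:
        if not self.objects:
            return 0.0
        return float(np.mean([o.occlusion for o in self.objects]))


# ---------------------------------------------------------------------------
# XML I/O
# ---------------------------------------------------------------------------

def read_voc_xml(path) -> Annotation:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"malformed VOC XML {path}: {e}") from e
    root = tree.getroot()

    def _req(parent, tag):
        el = parent.find(tag)
        if el is None or el.text is None:
            raise ValueError(f"VOC XML {path}: missing field <{tag}>")
        return el.text.strip()

    size = root.find("size")
    if size is None:
        raise ValueError(f"VOC XML {path}: missing field <size>")
    width = int(_req(size, "width"))
    height = int(_req(size, "height"))
    image_id = os.path.splitext(os.path.basename(
        root.findtext("filename", default=os.path.basename(str(path)))))[0]
    objects = []
    for obj in root.findall("object"):
        cls = _req(obj, "name")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"VOC XML {path}: object missing <bndbox>")
        xmin = float(_req(bnd, "xmin")) - 1.0
        ymin = float(_req(bnd, "ymin")) - 1.0
        xmax = float(_req(bnd, "xmax")) - 1.0
        ymax = float(_req(bnd, "ymax")) - 1.0
        occ = float(obj.findtext("occlusion", default="0"))
        objects.append(VocObject(cls, Box(xmin, ymin, xmax, ymax), occ))
    return Annotation(image_id, width, height, objects)


def write_voc_xml(ann: Annotation, path):
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = ann.image_id + ".png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for o in ann.objects:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = o.cls
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = f"{o.box.x1 + 1:.2f}".rstrip("0").rstrip(".")
        etree.SubElement(bnd, "ymin").text = f"{o.box.y1 + 1:.2f}".rstrip("0").rstrip(".")
        etree.SubElement(bnd, "xmax").text = f"{o.box.x2 + 1:.2f}".rstrip("0").rstrip(".")
        etree.SubElement(bnd, "ymax").text = f"{o.box.y2 + 1:.2f}".rstrip("0").rstrip(".")
        etree.SubElement(obj, "occlusion").text = f"{o.occlusion:.4f}"
    etree.ElementTree(root).write(str(path), pretty_print=True)


# ---------------------------------------------------------------------------
# photometric and geometric augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentParams:
    """Sampling ranges for the offline 5x expansion."""
    omega_range: tuple = (0.6, 1.4)     # contrast factor
    psi_range: tuple = (-30.0, 30.0)    # brightness offset (intensity units)
    translate: bool = True
    blur: bool = True
    affine: bool = True
    rotate: bool = True
    flip: bool = True
    splice: bool = True

    def enabled_ops(self):
        ops = []
        for name in ("translate", "blur", "affine", "rotate", "flip", "splice"):
            if getattr(self, name):
                ops.append(name)
        return ops


def brightness_contrast(image: np.ndarray, omega: float, psi: float) -> np.ndarray:
    """Per-pixel x*omega + psi, clipped to [0, 255], rounded half-up."""
    if omega <= 0:
        raise ValueError("contrast factor omega must be > 0")
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("brightness_contrast expects an 8-bit image")
    out = np.floor(img.astype(np.float64) * omega + psi + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def _transform_boxes(objects, matrix, offset, width, height):
    """Map boxes through the inverse of an ndimage affine (output<-input),
    re-axis-align via corner hulls, clip to bounds, drop degenerates."""
    inv = np.linalg.inv(matrix)
    out = []
    for o in objects:
        b = o.box
        corners = np.array([[b.y1, b.x1], [b.y1, b.x2], [b.y2, b.x1], [b.y2, b.x2]])
        # ndimage: input_coord = matrix @ output_coord + offset
        mapped = (inv @ (corners - offset).T).T
        y1, x1 = mapped.min(axis=0)
        y2, x2 = mapped.max(axis=0)
        x1, x2 = max(0.0, x1), min(float(width), x2)
        y1, y2 = max(0.0, y1), min(float(height), y2)
        if x2 - x1 >= 2.0 and y2 - y1 >= 2.0:
            out.append(replace(o, box=Box(x1, y1, x2, y2)))
    return out


def _affine_image(img, matrix, offset):
    chans = [ndimage.affine_transform(img[..., c].astype(np.float32), matrix,
                                      offset=offset, order=1, mode="nearest")
             for c in range(img.shape[2])]
    return np.clip(np.stack(chans, axis=-1) + 0.5, 0, 255).astype(np.uint8)


def _augment_one(img, ann, op, rng, params):
    h, w = img.shape[:2]
    if op == "flip":
        out = img[:, ::-1].copy()
        objs = [replace(o, box=Box(w - o.box.x2, o.box.y1, w - o.box.x1, o.box.y2))
                for o in ann.objects]
        return out, objs
    if op == "blur":
        sigma = rng.uniform(0.6, 1.6)
        out = np.stack([ndimage.gaussian_filter(img[..., c].astype(np.float32), sigma)
                        for c in range(3)], axis=-1)
        return np.clip(out + 0.5, 0, 255).astype(np.uint8), list(ann.objects)
    if op == "translate":
        dy, dx = rng.integers(-h // 8, h // 8 + 1), rng.integers(-w // 8, w // 8 + 1)
        matrix = np.eye(2)
        offset = np.array([-dy, -dx], dtype=float)
    elif op == "rotate":
        theta = np.deg2rad(rng.uniform(-20, 20))
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        center = np.array([h / 2, w / 2])
        matrix = rot
        offset = center - rot @ center
    elif op == "affine":
        sy, sx = rng.uniform(0.85, 1.2, size=2)
        shear = rng.uniform(-0.15, 0.15)
        matrix = np.array([[1 / sy, shear], [0.0, 1 / sx]])
        center = np.array([h / 2, w / 2])
        offset = center - matrix @ center
    else:
        raise ValueError(f"unknown op {op!r}")
    out = _affine_image(img, matrix, offset)
    return out, _transform_boxes(ann.objects, matrix, offset, w, h)


def _splice(items, idxs, rng):
    """2x2 mosaic of four images, each downscaled by 2, boxes remapped."""
    img0, _ = items[idxs[0]]
    h, w = img0.shape[:2]
    canvas = np.zeros((h, w, 3), dtype=np.uint8)
    objs = []
    for q, idx in enumerate(idxs):
        img, ann = items[idx]
        small = np.asarray(Image.fromarray(img).resize((w // 2, h // 2), Image.BILINEAR))
        oy, ox = (q // 2) * (h // 2), (q % 2) * (w // 2)
        canvas[oy:oy + h // 2, ox:ox + w // 2] = small
        for o in ann.objects:
            b = o.box
            nb = Box(b.x1 / 2 + ox, b.y1 / 2 + oy, b.x2 / 2 + ox, b.y2 / 2 + oy)
            if nb.x2 - nb.x1 >= 2 and nb.y2 - nb.y1 >= 2:
                objs.append(replace(o, box=nb))
    return canvas, objs


def expand_dataset(items: list, seed: int = 0,
                   params: AugmentParams | None = None) -> list:
    """5x offline expansion: every (image, Annotation) yields itself plus four
    augmented variants (a random enabled geometric op followed by the
    photometric brightness/contrast transform)."""
    if not items:
        raise ValueError("empty dataset")
    params = params or AugmentParams()
    ops = params.enabled_ops()
    rng = np.random.default_rng(seed)
    out = list(items)
    for base_idx, (img, ann) in enumerate(items):
        for v in range(4):
            op = ops[rng.integers(len(ops))]
            if op == "splice":
                idxs = [base_idx] + list(rng.integers(len(items), size=3))
                aug, objs = _splice(items, idxs, rng)
            else:
                aug, objs = _augment_one(img, ann, op, rng, params)
            omega = rng.uniform(*params.omega_range)
            psi = rng.uniform(*params.psi_range)
            aug = brightness_contrast(aug, omega, psi)
            out.append((aug, Annotation(f"{ann.image_id}_aug{v}",
                                        ann.width, ann.height, objs)))
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple = (0.7, 0.2, 0.1)     # train, test, val
    occlusion_cut: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def split_dataset(items: list, spec: SplitSpec | None = None) -> dict:
    """Seeded random partition into train/test/val plus occlusion subsets.

    Returns {"train": [...], "test": [...], "val": [...], "test_A": [...],
    "test_B": [...]} of dataset indices; a test image joins A when its mean
    object occlusion is below the cut, B otherwise.
    """
    spec = spec or SplitSpec()
    n = len(items)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = round(spec.ratios[0] * n)
    n_test = round(spec.ratios[1] * n)
    train = sorted(order[:n_train].tolist())
    test = sorted(order[n_train:n_train + n_test].tolist())
    val = sorted(order[n_train + n_test:].tolist())
    test_a, test_b = [], []
    for i in test:
        ann = items[i][1] if isinstance(items[i], tuple) else items[i]
        if ann.mean_occlusion < spec.occlusion_cut:
            test_a.append(i)
        else:
            test_b.append(i)
    return {"train": train, "test": test, "val": val,
            "test_A": test_a, "test_B": test_b}


# ---------------------------------------------------------------------------
# directory layout
# ---------------------------------------------------------------------------

def write_voc_tree(root_dir, items: list, splits: dict | None = None):
    """Write JPEGImages/ (PNG files), Annotations/ and ImageSets/Main lists."""
    root_dir = str(root_dir)
    img_dir = os.path.join(root_dir, "JPEGImages")
    ann_dir = os.path.join(root_dir, "Annotations")
    set_dir = os.path.join(root_dir, "ImageSets", "Main")
    for d in (img_dir, ann_dir, set_dir):
        os.makedirs(d, exist_ok=True)
    for img, ann in items:
        Image.fromarray(img).save(os.path.join(img_dir, ann.image_id + ".png"))
        write_voc_xml(ann, os.path.join(ann_dir, ann.image_id + ".xml"))
    if splits:
        for name, idxs in splits.items():
            with open(os.path.join(set_dir, name + ".txt"), "w") as fh:
                for i in idxs:
                    fh.write(items[i][1].image_id + "\n")


def load_voc_tree(root_dir, subset: str | None = None) -> list:
    """Load (image, Annotation) pairs; `subset` names an ImageSets/Main list."""
    root_dir = str(root_dir)
    ann_dir = os.path.join(root_dir, "Annotations")
    img_dir = os.path.join(root_dir, "JPEGImages")
    if subset:
        lst = os.path.join(root_dir, "ImageSets", "Main", subset + ".txt")
        if not os.path.exists(lst):
            raise FileNotFoundError(f"no such subset list: {lst}")
        with open(lst) as fh:
            ids = [ln.strip() for ln in fh if ln.strip()]
    else:
        ids = sorted(os.path.splitext(f)[0] for f in os.listdir(ann_dir)
                     if f.endswith(".xml"))
    items = []
    for iid in ids:
        ann = read_voc_xml(os.path.join(ann_dir, iid + ".xml"))
        img = np.asarray(Image.open(os.path.join(img_dir, iid + ".png")).convert("RGB"))
        items.append((img, ann))
    return items
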