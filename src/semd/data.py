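"""Image/mask I/O, augmentation, resizing, overlays, and dataset layout.

Masks travel as single-channel PASCAL-VOC palette PNGs (pixel value = class
index, the standard VOC colormap as palette).  Polygon annotations come from
LabelMe JSON; a polygon covers a pixel iff the pixel's center lies inside
it, so axis-aligned integer rectangles rasterize to exact areas.

Dataset directory layout::

    root/
      images/<id>.png
      masks/<id>.png
      lists/train.txt
      lists/val.txt
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image
from skimage import measure

# per-channel normalization constants for network input (images scaled to [0,1])
NORM_MEAN = np.array([0.5, 0.5, 0.5], dtype=np.float32)
NORM_STD = np.array([0.5, 0.5, 0.5], dtype=np.float32)

PAPER_SIZES = (512, 415, 321)


@dataclass
class AnnotatedSample:
    """An RGB image with its per-pixel integer class mask."""

    image: np.ndarray  # H×W×3 uint8
    mask: np.ndarray   # H×W integer class indices
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.uint8)
        self.mask = np.asarray(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(f"image {self.image.shape[:2]} and mask "
                             f"{self.mask.shape} dimensions differ")


@dataclass(frozen=True)
class AugmentationSpec:
    """One random geometric transform, fully determined by `seed`.

    Rotation is drawn uniformly from ±`rotation_range` degrees; horizontal
    and vertical flips are independent fair coin flips.  The identical
    transform is applied to image (bilinear) and mask (nearest-neighbor).
    """

    rotation_range: float = 15.0
    hflip: bool = True
    vflip: bool = True
    seed: int = 0


# ---- VOC palette masks -------------------------------------------------------

def voc_colormap(n: int = 256) -> np.ndarray:
    """The PASCAL VOC colormap: class index → RGB, by bit interleaving."""
    cmap = np.zeros((n, 3), dtype=np.uint8)
    for i in range(n):
        r = g = b = 0
        cid = i
        for j in range(8):
            r |= ((cid >> 0) & 1) << (7 - j)
            g |= ((cid >> 1) & 1) << (7 - j)
            b |= ((cid >> 2) & 1) << (7 - j)
            cid >>= 3
        cmap[i] = (r, g, b)
    return cmap


def write_voc_mask(mask: np.ndarray, path: Union[str, Path]) -> None:
    """Write an integer mask as a single-channel VOC palette PNG."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask values must fit in a palette PNG (0..255)")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    img.putpalette(voc_colormap().ravel().tolist())
    img.save(path, format="PNG")


def read_voc_mask(path: Union[str, Path]) -> np.ndarray:
    """Read a palette PNG mask back to integer class indices."""
    with Image.open(path) as img:
        if img.mode != "P":
            img = img.convert("P")
        return np.array(img, dtype=np.uint8)


def write_image(image: np.ndarray, path: Union[str, Path]) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_image(path: Union[str, Path]) -> np.ndarray:
    with Image.open(path) as img:
        return np.array(img.convert("RGB"), dtype=np.uint8)


# ---- polygons ----------------------------------------------------------------

def rasterize_polygon(points: Sequence[Sequence[float]], shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the (x, y) polygon."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) points")
    h, w = shape
    xmin = max(int(np.floor(pts[:, 0].min())), 0)
    xmax = min(int(np.ceil(pts[:, 0].max())), w)
    ymin = max(int(np.floor(pts[:, 1].min())), 0)
    ymax = min(int(np.ceil(pts[:, 1].max())), h)
    out = np.zeros(shape, dtype=bool)
    if xmin >= xmax or ymin >= ymax:
        return out
    ys, xs = np.mgrid[ymin:ymax, xmin:xmax]
    centers = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5])
    inside = MplPath(pts).contains_points(centers)
    out[ymin:ymax, xmin:xmax] = inside.reshape(ys.shape)
    return out


def labelme_to_mask(annotation: Union[str, Path, dict],
                    class_map: dict[str, int],
                    shape: Optional[tuple[int, int]] = None) -> AnnotatedSample:
    """Rasterize a LabelMe JSON document to an integer class mask.

    Later polygons overwrite earlier ones; unannotated pixels are background
    (class 0).  The returned sample's image is the embedded/linked image if
    resolvable, else a black canvas of the right size.
    """
    if isinstance(annotation, (str, Path)):
        with open(annotation) as fh:
            doc = json.load(fh)
    else:
        doc = annotation
    if shape is None:
        try:
            shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
        except KeyError as exc:
            raise ValueError("annotation lacks imageHeight/imageWidth; pass shape=") from exc
    mask = np.zeros(shape, dtype=np.uint8)
    for sh in doc.get("shapes", []):
        if sh.get("shape_type", "polygon") != "polygon":
            continue
        label = sh["label"]
        if label not in class_map:
            raise KeyError(f"unknown class label {label!r}")
        mask[rasterize_polygon(sh["points"], shape)] = class_map[label]
    image = np.zeros((*shape, 3), dtype=np.uint8)
    return AnnotatedSample(image=image, mask=mask,
                           source_id=str(doc.get("imagePath", "")))


def mask_to_polygons(mask: np.ndarray, class_id: int = 1) -> list[list[list[float]]]:
    """Polygons (x, y) outlining the regions of `class_id` in a mask.

    Connected regions that exactly fill their bounding box (axis-aligned
    rectangles) are emitted as exact 4-point polygons, so
    ``labelme_to_mask(mask_to_polygons(m))`` round-trips them losslessly;
    other shapes fall back to marching-squares contours (approximate).
    """
    binary = np.asarray(mask) == class_id
    labels = measure.label(binary, connectivity=1)
    polys: list[list[list[float]]] = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        if region.area == (r1 - r0) * (c1 - c0):
            polys.append([[float(c0), float(r0)], [float(c1), float(r0)],
                          [float(c1), float(r1)], [float(c0), float(r1)]])
        else:
            padded = np.pad(labels == region.label, 1).astype(float)
            for contour in measure.find_contours(padded, 0.5):
                polys.append([[float(c - 1), float(r - 1)] for r, c in contour])
    return polys


# ---- geometry ----------------------------------------------------------------

def pad_to_square(sample: AnnotatedSample) -> AnnotatedSample:
    """Symmetric zero-pad to a square canvas (background class outside)."""
    h, w = sample.mask.shape
    if h == w:
        return sample
    side = max(h, w)
    top, left = (side - h) // 2, (side - w) // 2
    image = np.zeros((side, side, 3), dtype=np.uint8)
    mask = np.zeros((side, side), dtype=sample.mask.dtype)
    image[top:top + h, left:left + w] = sample.image
    mask[top:top + h, left:left + w] = sample.mask
    return AnnotatedSample(image, mask, sample.source_id)


def resize_sample(sample: AnnotatedSample, size: int) -> AnnotatedSample:
    """Resize to size×size: bilinear for the image, nearest for the mask.

    Non-square sources are symmetrically zero-padded to square first.
    """
    if size < 1:
        raise ValueError("size must be positive")
    sample = pad_to_square(sample)
    img = Image.fromarray(sample.image).resize((size, size), Image.BILINEAR)
    msk = Image.fromarray(sample.mask.astype(np.uint8)).resize((size, size), Image.NEAREST)
    return AnnotatedSample(np.array(img), np.array(msk), sample.source_id)


def augment(sample: AnnotatedSample, spec: AugmentationSpec) -> AnnotatedSample:
    """Apply the seeded rotation/flip transform to image and mask alike."""
    rng = np.random.default_rng(spec.seed)
    angle = float(rng.uniform(-spec.rotation_range, spec.rotation_range))
    do_h = bool(spec.hflip and rng.random() < 0.5)
    do_v = bool(spec.vflip and rng.random() < 0.5)
    image, mask = sample.image, sample.mask.astype(np.uint8)
    if angle != 0.0:
        image = np.array(Image.fromarray(image).rotate(
            angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0)))
        mask = np.array(Image.fromarray(mask).rotate(
            angle, resample=Image.NEAREST, fillcolor=0))
    if do_h:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if do_v:
        image, mask = image[::-1], mask[::-1]
    return AnnotatedSample(np.ascontiguousarray(image), np.ascontiguousarray(mask),
                           sample.source_id)


def flip(sample: AnnotatedSample, *, horizontal: bool = False,
         vertical: bool = False) -> AnnotatedSample:
    """Deterministic mirror; applying the same flip twice is the identity."""
    image, mask = sample.image, sample.mask
    if horizontal:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if vertical:
        image, mask = image[::-1], mask[::-1]
    return AnnotatedSample(np.ascontiguousarray(image), np.ascontiguousarray(mask),
                           sample.source_id)


def overlay(image: np.ndarray, mask: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend class colors over the image; background pixels untouched."""
    image = np.asarray(image, dtype=np.uint8)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    colors = voc_colormap()
    out = image.astype(np.float64)
    fg = mask > 0
    out[fg] = (1 - alpha) * out[fg] + alpha * colors[mask[fg]]
    return np.round(out).astype(np.uint8)


# ---- network input conversion ------------------------------------------------

def normalize_image(image: np.ndarray) -> np.ndarray:
    """H×W×3 uint8 → 3×H×W float32, scaled to [0,1] then standardized."""
    x = np.asarray(image, dtype=np.float32) / 255.0
    x = (x - NORM_MEAN) / NORM_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def batch_from_samples(samples: Sequence[AnnotatedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into a normalized image batch and an integer mask batch."""
    images = np.stack([normalize_image(s.image) for s in samples])
    masks = np.stack([s.mask.astype(np.int64) for s in samples])
    return images, masks


# ---- dataset directories -----------------------------------------------------

class SegDataset:
    """Reader for the images/ masks/ lists/ directory layout."""

    def __init__(self, root: Union[str, Path], split: str = "train"):
        self.root = Path(root)
        list_file = self.root / "lists" / f"{split}.txt"
        if not list_file.exists():
            raise FileNotFoundError(f"missing split list {list_file}")
        self.ids = [line.strip() for line in list_file.read_text().splitlines()
                    if line.strip()]
        if not self.ids:
            raise ValueError(f"split {split!r} in {root} is empty")
        self.split = split

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> AnnotatedSample:
        sid = self.ids[i]
        image = read_image(self.root / "images" / f"{sid}.png")
        mask_path = self.root / "masks" / f"{sid}.png"
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for sample {sid}")
        mask = read_voc_mask(mask_path)
        return AnnotatedSample(image, mask, sid)

    def samples(self) -> list[AnnotatedSample]:
        return [self[i] for i in range(len(self))]


def write_dataset_layout(root: Union[str, Path]) -> dict[str, Path]:
    root = Path(root)
    dirs = {name: root / name for name in ("images", "masks", "lists")}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    return dirs
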