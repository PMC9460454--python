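"""Procedural standing-tree scenes with pixel-exact ground-truth masks.

Real standing-tree photographs fall into four strata — single or multiple
tree subjects against a simple (sky/soil) or complex (grass, bushes, green
clutter) background.  The generator emulates those strata: every scene is a
sky-gradient canvas with a ground band, one or more trees built from a
tapered trunk polygon plus a canopy of overlapping elliptical blobs, and —
for complex backgrounds — green-hued non-tree clutter that a segmenter can
confuse with canopy.  The class-1 mask is derived from the very same
geometry, so ground truth is exact by construction, and a fixed
``SceneSpec`` yields bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np

from .data import (AnnotatedSample, rasterize_polygon, write_dataset_layout,
                   write_image, write_voc_mask)

STRATA = ("single_simple", "single_complex", "multi_simple", "multi_complex")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    trunk_width_frac and canopy_radius_frac are fractions of the canvas
    side; clutter_density scales the number of confusable green blobs in
    complex backgrounds (ignored for simple ones).
    """

    n_trees: int = 1
    background: str = "simple"
    canvas: int = 128
    seed: int = 0
    trunk_width_frac: float = 0.055
    canopy_radius_frac: float = 0.16
    clutter_density: float = 1.0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.background not in ("simple", "complex"):
            raise ValueError("background must be 'simple' or 'complex'")
        if not (0 < self.trunk_width_frac < 1 and 0 < self.canopy_radius_frac < 1):
            raise ValueError("trunk/canopy fractions must lie in (0, 1)")
        if self.clutter_density < 0:
            raise ValueError("clutter_density must be >= 0")


def _ellipse_mask(n: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    ys, xs = np.mgrid[0:n, 0:n]
    return ((xs + 0.5 - cx) / rx) ** 2 + ((ys + 0.5 - cy) / ry) ** 2 <= 1.0


def _paint_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.canvas
    img = np.zeros((n, n, 3), dtype=np.float64)
    # vertical sky gradient, light blue to pale near the horizon
    t = (np.arange(n) / max(n - 1, 1))[:, None]
    sky_top = np.array([135.0, 175.0, 230.0]) + rng.uniform(-12, 12, 3)
    sky_bot = np.array([215.0, 222.0, 238.0]) + rng.uniform(-8, 8, 3)
    img[:] = sky_top + (sky_bot - sky_top) * t[..., None]
    # ground band: brownish soil (red-dominant, never green-hued)
    horizon = int(n * rng.uniform(0.78, 0.86))
    soil = np.array([150.0, 126.0, 100.0]) + rng.uniform(-10, 10, 3)
    img[horizon:] = soil
    if spec.background == "complex":
        # grass band on top of the soil: green-dominant texture
        grass_h = max(2, int(n * 0.06))
        grass = np.array([96.0, 150.0, 60.0])
        img[horizon:horizon + grass_h] = grass + rng.uniform(-15, 15, (grass_h, n, 3))
        # scattered green clutter blobs (bushes) the model may confuse with canopy
        n_blobs = max(1, int(round(3 * spec.clutter_density)))
        for _ in range(n_blobs):
            cx = rng.uniform(0, n)
            cy = rng.uniform(horizon - n * 0.08, horizon + n * 0.02)
            r = n * rng.uniform(0.03, 0.07)
            blob = _ellipse_mask(n, cx, cy, r, 0.7 * r)
            color = np.array([80.0, 135.0, 55.0]) + rng.uniform(-20, 20, 3)
            img[blob] = color
        # a few soil patches / rocks
        for _ in range(max(0, int(round(2 * spec.clutter_density)))):
            cx, cy = rng.uniform(0, n), rng.uniform(horizon, n)
            r = n * rng.uniform(0.02, 0.05)
            img[_ellipse_mask(n, cx, cy, r, 0.5 * r)] = (
                np.array([120.0, 104.0, 88.0]) + rng.uniform(-15, 15, 3))
    return img


def _tree_geometry(spec: SceneSpec, rng: np.random.Generator,
                   base_x: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (trunk polygon, canopy blob union) of one tree."""
    n = spec.canvas
    ground_y = n * rng.uniform(0.82, 0.9)
    top_y = n * rng.uniform(0.32, 0.45)
    w_base = n * spec.trunk_width_frac * rng.uniform(0.85, 1.15)
    w_top = w_base * 0.6
    lean = n * rng.uniform(-0.02, 0.02)
    trunk = rasterize_polygon(
        [[base_x - w_base / 2, ground_y], [base_x + w_base / 2, ground_y],
         [base_x + lean + w_top / 2, top_y], [base_x + lean - w_top / 2, top_y]],
        (n, n))
    canopy = np.zeros((n, n), dtype=bool)
    r0 = n * spec.canopy_radius_frac
    cx0, cy0 = base_x + lean, top_y - 0.3 * r0
    for _ in range(rng.integers(5, 9)):
        dx = rng.uniform(-0.8, 0.8) * r0
        dy = rng.uniform(-0.7, 0.5) * r0
        r = r0 * rng.uniform(0.45, 0.8)
        canopy |= _ellipse_mask(n, cx0 + dx, cy0 + dy, r, r * rng.uniform(0.7, 1.0))
    return trunk, canopy


def generate_scene(spec: SceneSpec) -> AnnotatedSample:
    """Render one scene; repeated calls with the same spec are bit-identical."""
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas
    img = _paint_background(spec, rng)
    mask = np.zeros((n, n), dtype=np.uint8)

    # spread tree bases over the canvas width, one slot per tree
    slots = np.linspace(0.15, 0.85, spec.n_trees)
    for k in range(spec.n_trees):
        base_x = n * (slots[k] + rng.uniform(-0.05, 0.05))
        trunk = canopy = None
        for _ in range(5):  # bounded retries if the tree clips to nothing
            trunk, canopy = _tree_geometry(spec, rng, base_x)
            if (trunk | canopy).any():
                break
            base_x = n * rng.uniform(0.2, 0.8)
        if trunk is None or not (trunk | canopy).any():
            raise RuntimeError("failed to place a tree with nonzero area")
        # paint: trunk brown with vertical bark streaks, canopy leafy green
        trunk_color = np.array([104.0, 72.0, 44.0]) + rng.uniform(-12, 12, 3)
        canopy_color = np.array([52.0, 110.0, 38.0]) + rng.uniform(-15, 15, 3)
        ys, xs = np.nonzero(trunk & ~canopy)
        img[ys, xs] = trunk_color + 10.0 * np.sin(xs * 1.3)[:, None]
        img[canopy] = canopy_color
        mask[trunk | canopy] = 1

    img += rng.normal(0, 3.0, img.shape)  # sensor-like noise, image only
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return AnnotatedSample(image, mask, f"scene_{spec.background}_{spec.seed}")


def stratum_spec(stratum: str, canvas: int, seed: int) -> SceneSpec:
    """A SceneSpec for one of the four dataset strata."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    single = stratum.startswith("single")
    background = "simple" if stratum.endswith("simple") else "complex"
    rng = np.random.default_rng(seed)
    n_trees = 1 if single else int(rng.integers(2, 5))
    return SceneSpec(n_trees=n_trees, background=background, canvas=canvas, seed=seed)


def generate_dataset(n_per_stratum: int, canvas: int, seed: int,
                     out_dir: Union[str, Path],
                     val_fraction: float = 0.1) -> dict:
    """Write a stratified synthetic dataset in the standard layout.

    Four strata (single/multiple trees × simple/complex background), each
    split 90/10 into train/val (at least one validation sample per stratum).
    Regeneration with the same arguments is byte-identical.
    """
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    out_dir = Path(out_dir)
    dirs = write_dataset_layout(out_dir)
    master = np.random.default_rng(seed)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for stratum in STRATA:
        ids = []
        for j in range(n_per_stratum):
            scene_seed = int(master.integers(2 ** 31))
            spec = stratum_spec(stratum, canvas, scene_seed)
            sample = generate_scene(spec)
            sid = f"{stratum}_{j:04d}"
            write_image(sample.image, dirs["images"] / f"{sid}.png")
            write_voc_mask(sample.mask, dirs["masks"] / f"{sid}.png")
            ids.append(sid)
        n_val = max(1, int(round(val_fraction * n_per_stratum)))
        order = master.permutation(len(ids))
        val_ids += [ids[i] for i in order[:n_val]]
        train_ids += [ids[i] for i in order[n_val:]]
    (dirs["lists"] / "train.txt").write_text("\n".join(sorted(train_ids)) + "\n")
    (dirs["lists"] / "val.txt").write_text("\n".join(sorted(val_ids)) + "\n")
    return {"train": sorted(train_ids), "val": sorted(val_ids),
            "n_total": 4 * n_per_stratum}


def dataset_digest(root: Union[str, Path]) -> str:
    """SHA-256 over all dataset files (sorted paths) — regeneration check."""
    root = Path(root)
    h = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file():
            h.update(path.relative_to(root).as_posix().encode())
            h.update(path.read_bytes())
    return h.hexdigest()


def green_fraction(image: np.ndarray, mask: np.ndarray, margin: int = 10) -> float:
    """Fraction of non-tree pixels that are green-hued (G exceeds R and B by
    `margin`) — used to verify that complex backgrounds contain confusable
    clutter and simple ones do not."""
    img = np.asarray(image, dtype=np.int32)
    bg = np.asarray(mask) == 0
    green = (img[..., 1] > img[..., 0] + margin) & (img[..., 1] > img[..., 2] + margin)
    return float((green & bg).sum() / max(bg.sum(), 1))
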