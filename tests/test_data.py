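"""I/O and geometry: VOC palette masks, LabelMe polygon rasterization,
resizing, augmentation, overlays."""

import json

import numpy as np
import pytest

from semd import (AnnotatedSample, AugmentationSpec, augment, flip,
                  labelme_to_mask, mask_to_polygons, normalize_image, overlay,
                  rasterize_polygon, read_voc_mask, resize_sample,
                  voc_colormap, write_voc_mask)
from semd.data import pad_to_square


# ---- VOC palette masks -------------------------------------------------------

def test_voc_mask_round_trip_bit_exact(tmp_path, rng):
    mask = rng.integers(0, 4, (37, 53)).astype(np.uint8)
    path = tmp_path / "m.png"
    write_voc_mask(mask, path)
    np.testing.assert_array_equal(read_voc_mask(path), mask)


def test_voc_colormap_known_entries():
    cmap = voc_colormap()
    np.testing.assert_array_equal(cmap[0], [0, 0, 0])        # background black
    np.testing.assert_array_equal(cmap[1], [128, 0, 0])      # class 1 maroon


# ---- LabelMe polygons --------------------------------------------------------

def make_labelme(shapes, h=100, w=100):
    return {"imageHeight": h, "imageWidth": w, "imagePath": "x.png",
            "shapes": [{"label": lab, "shape_type": "polygon", "points": pts}
                       for lab, pts in shapes]}


def test_square_polygon_covers_exact_quarter():
    doc = make_labelme([("tree", [[0, 0], [50, 0], [50, 50], [0, 50]])])
    sample = labelme_to_mask(doc, {"tree": 1})
    assert int((sample.mask == 1).sum()) == 2500


def test_empty_annotation_is_all_background():
    sample = labelme_to_mask(make_labelme([]), {"tree": 1})
    assert sample.mask.max() == 0


def test_overlapping_polygons_later_wins():
    square = [[10, 10], [40, 10], [40, 40], [10, 40]]
    doc = make_labelme([("tree", square), ("shrub", square)])
    sample = labelme_to_mask(doc, {"tree": 1, "shrub": 2})
    assert set(np.unique(sample.mask)) == {0, 2}


def test_unknown_label_raises():
    doc = make_labelme([("rock", [[0, 0], [5, 0], [5, 5]])])
    with pytest.raises(KeyError):
        labelme_to_mask(doc, {"tree": 1})


def test_labelme_json_file_and_voc_round_trip(tmp_path):
    """LabelMe JSON → mask → VOC PNG → mask is lossless."""
    doc = make_labelme([("tree", [[5, 5], [30, 5], [30, 60], [5, 60]]),
                        ("tree", [[50, 20], [80, 20], [80, 90], [50, 90]])])
    jpath = tmp_path / "ann.json"
    jpath.write_text(json.dumps(doc))
    sample = labelme_to_mask(jpath, {"tree": 1})
    write_voc_mask(sample.mask, tmp_path / "m.png")
    np.testing.assert_array_equal(read_voc_mask(tmp_path / "m.png"), sample.mask)


def test_rectangle_mask_polygon_round_trip():
    mask = np.zeros((60, 60), np.uint8)
    mask[10:30, 20:45] = 1
    polys = mask_to_polygons(mask, 1)
    doc = make_labelme([("tree", p) for p in polys], 60, 60)
    back = labelme_to_mask(doc, {"tree": 1})
    np.testing.assert_array_equal(back.mask, mask)


def test_rasterize_polygon_clips_to_canvas():
    out = rasterize_polygon([[-10, -10], [5, -10], [5, 5], [-10, 5]], (8, 8))
    assert out[:5, :5].all() and not out[5:, :].any()


# ---- resizing ----------------------------------------------------------------

def test_resize_identity_preserves_mask(sample_scene):
    size = sample_scene.mask.shape[0]
    out = resize_sample(sample_scene, size)
    np.testing.assert_array_equal(out.mask, sample_scene.mask)


@pytest.mark.parametrize("size", [512, 415, 321, 48])
def test_resize_to_paper_sizes(sample_scene, size):
    out = resize_sample(sample_scene, size)
    assert out.image.shape == (size, size, 3)
    assert out.mask.shape == (size, size)
    assert set(np.unique(out.mask)) <= set(np.unique(sample_scene.mask))


def test_non_square_input_padded_symmetrically():
    image = np.full((40, 60, 3), 200, np.uint8)
    mask = np.ones((40, 60), np.uint8)
    padded = pad_to_square(AnnotatedSample(image, mask))
    assert padded.mask.shape == (60, 60)
    assert padded.mask[:10].sum() == 0 and padded.mask[10:50].all()


# ---- augmentation ------------------------------------------------------------

def test_flip_is_involution(sample_scene):
    twice = flip(flip(sample_scene, horizontal=True), horizontal=True)
    np.testing.assert_array_equal(twice.image, sample_scene.image)
    np.testing.assert_array_equal(twice.mask, sample_scene.mask)


def test_flips_preserve_tree_pixel_count(sample_scene):
    n = int((sample_scene.mask > 0).sum())
    for kw in ({"horizontal": True}, {"vertical": True}):
        assert int((flip(sample_scene, **kw).mask > 0).sum()) == n


def test_zero_rotation_no_flip_is_identity(sample_scene):
    spec = AugmentationSpec(rotation_range=0.0, hflip=False, vflip=False, seed=0)
    out = augment(sample_scene, spec)
    np.testing.assert_array_equal(out.image, sample_scene.image)
    np.testing.assert_array_equal(out.mask, sample_scene.mask)


def test_augmentation_is_deterministic_and_bounded(sample_scene):
    spec = AugmentationSpec(seed=3)
    a = augment(sample_scene, spec)
    b = augment(sample_scene, spec)
    np.testing.assert_array_equal(a.mask, b.mask)
    # ≤15° rotation changes the tree-pixel count by < 2 %
    n0 = (sample_scene.mask > 0).sum()
    n1 = (a.mask > 0).sum()
    assert abs(int(n1) - int(n0)) / n0 < 0.02
    assert set(np.unique(a.mask)) == set(np.unique(sample_scene.mask))


# ---- overlay / normalization -------------------------------------------------

def test_overlay_alpha_extremes(sample_scene):
    img, mask = sample_scene.image, sample_scene.mask
    np.testing.assert_array_equal(overlay(img, mask, 0.0), img)
    full = overlay(img, mask, 1.0)
    color = voc_colormap()[1]
    assert np.all(full[mask == 1] == color)
    np.testing.assert_array_equal(full[mask == 0], img[mask == 0])
    np.testing.assert_array_equal(
        overlay(img, np.zeros_like(mask), 0.7), img)


def test_normalize_image_range_and_layout():
    img = np.zeros((5, 4, 3), np.uint8)
    img[..., 0] = 255
    x = normalize_image(img)
    assert x.shape == (3, 5, 4)
    assert x[0].max() == pytest.approx(1.0)   # (1.0 - 0.5) / 0.5
    assert x[1].min() == pytest.approx(-1.0)
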