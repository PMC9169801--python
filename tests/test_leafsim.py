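"""Simulator contracts: determinism, exact masks, annotations, splits."""

import numpy as np
import pytest

from xleaf import leafsim
from xleaf.leafsim import (SceneConfig, add_transparent_circles,
                           annotation_from_background,
                           annotation_from_bounding_rect,
                           annotation_from_circles, build_dataset,
                           build_watermark_dataset, generate_leaf_scene,
                           load_dataset, save_dataset)


def test_scene_generation_is_deterministic(small_scene_cfg):
    a_img, a_fg = generate_leaf_scene(small_scene_cfg, seed=5)
    b_img, b_fg = generate_leaf_scene(small_scene_cfg, seed=5)
    assert np.array_equal(a_img, b_img)
    assert np.array_equal(a_fg, b_fg)
    c_img, _ = generate_leaf_scene(small_scene_cfg, seed=6)
    assert not np.array_equal(a_img, c_img)


def test_scene_values_in_unit_interval(small_scene_cfg):
    img, fg = generate_leaf_scene(small_scene_cfg, seed=0)
    assert img.shape == (32, 32, 3)
    assert img.min() >= 0.0 and img.max() <= 1.0
    assert np.isfinite(img).all()
    assert set(np.unique(fg)) <= {0, 1}


def test_image_size_below_minimum_rejected():
    with pytest.raises(ValueError):
        SceneConfig(image_size=(16, 16)).validate()


def test_foreground_coverage_in_expected_band():
    """Default leaf silhouettes cover between 20% and 80% of the frame."""
    cfg = SceneConfig(image_size=(64, 64))
    fracs = [generate_leaf_scene(cfg, seed=s)[1].mean() for s in range(200)]
    assert 0.2 < min(fracs) and max(fracs) < 0.8


def test_no_circles_is_identity(small_scene_cfg):
    img, _ = generate_leaf_scene(small_scene_cfg, seed=1)
    cfg = SceneConfig(image_size=(32, 32), n_circles_range=(0, 0))
    out, region = add_transparent_circles(img, cfg, seed=1)
    assert np.array_equal(out, img)
    assert region.sum() == 0


def test_single_circle_matches_per_pixel_disk_rule():
    """The rasterized region equals the brute-force distance test."""
    cfg = SceneConfig(image_size=(40, 40), n_circles_range=(1, 1),
                      radius_range=(0.2, 0.2), alpha_range=(0.5, 0.5))
    img = np.full((40, 40, 3), 0.5, dtype=np.float32)
    out, region = add_transparent_circles(img, cfg, seed=3)
    # recover the circle centre/radius from the same RNG stream
    r = leafsim._rng(3, leafsim._T_CIRCLES)
    r.integers(1, 2)  # number of circles
    cy, cx = r.uniform(0, 39), r.uniform(0, 39)
    rad = r.uniform(0.2, 0.2) * 40
    brute = np.zeros((40, 40), dtype=np.uint8)
    for i in range(40):
        for j in range(40):
            brute[i, j] = (i - cy) ** 2 + (j - cx) ** 2 <= rad ** 2
    assert np.array_equal(region, brute)


def test_full_opacity_circle_equals_background_color():
    cfg = SceneConfig(image_size=(32, 32), n_circles_range=(1, 1),
                      alpha_range=(1.0, 1.0))
    img = np.full((32, 32, 3), 0.3, dtype=np.float32)
    out, region = add_transparent_circles(img, cfg, seed=9)
    assert region.sum() > 0
    inside = out[region.astype(bool)]
    want = np.broadcast_to(np.array(cfg.background_color, dtype=np.float32),
                           inside.shape)
    np.testing.assert_allclose(inside, want, atol=1e-6)


def test_changed_pixels_subset_of_circle_region(small_scene_cfg):
    img, fg = generate_leaf_scene(small_scene_cfg, seed=11)
    out, region = add_transparent_circles(img, small_scene_cfg, seed=11,
                                          foreground=fg)
    changed = np.any(out != img, axis=2)
    assert not np.any(changed & (region == 0))


def test_circle_annotation_is_complement():
    region = np.zeros((8, 8), dtype=np.uint8)
    region[2:4, 2:4] = 1
    ann = annotation_from_circles(region)
    assert np.array_equal(ann + region, np.ones((8, 8), dtype=np.uint8))
    assert annotation_from_circles(np.zeros((4, 4), np.uint8)).all()
    assert not annotation_from_circles(np.ones((4, 4), np.uint8)).any()


def test_background_annotation_is_complement_of_foreground():
    fg = (np.indices((6, 6)).sum(axis=0) % 2).astype(np.uint8)  # checkerboard
    ann = annotation_from_background(fg)
    assert np.array_equal(ann, 1 - fg)


def test_background_annotation_matches_generator_truth(small_scene_cfg):
    img, fg = generate_leaf_scene(small_scene_cfg, seed=2)
    assert np.array_equal(annotation_from_background(fg), 1 - fg)


def test_bounding_rect_annotation_hand_example():
    fg = np.zeros((6, 6), dtype=np.uint8)
    fg[1, 1] = fg[3, 4] = 1
    ann = annotation_from_bounding_rect(fg)
    # rectangle rows 1-3, cols 1-4 -> 12 zeros, 24 ones
    assert ann.sum() == 24
    assert not ann[1:4, 1:5].any()
    assert ann[0].all() and ann[:, 0].all()


def test_bounding_rect_edge_cases():
    one = np.zeros((5, 5), dtype=np.uint8)
    one[2, 3] = 1
    ann = annotation_from_bounding_rect(one)
    assert ann.sum() == 24 and ann[2, 3] == 0
    assert not annotation_from_bounding_rect(np.ones((4, 4), np.uint8)).any()
    with pytest.raises(ValueError):
        annotation_from_bounding_rect(np.zeros((4, 4), np.uint8))


@pytest.mark.parametrize("task", ["fake_vs_real", "diseased_vs_healthy",
                                  "species"])
def test_dataset_structure_and_determinism(task, small_scene_cfg):
    ds1 = build_dataset(task, small_scene_cfg, 30, (0.6, 0.2, 0.2), seed=3)
    ds2 = build_dataset(task, small_scene_cfg, 30, (0.6, 0.2, 0.2), seed=3)
    # bit-identical regeneration
    for a, b in zip(ds1.samples, ds2.samples):
        assert np.array_equal(a.image, b.image)
        assert a.label == b.label
        assert np.array_equal(a.annotation, b.annotation)
    # splits partition the indices
    all_idx = np.concatenate([ds1.splits[s] for s in
                              ("train", "validation", "test")])
    assert sorted(all_idx.tolist()) == list(range(30))
    # partition invariant: annotation + assessment = 1 everywhere
    for s in ds1.samples:
        assert np.array_equal(s.annotation + s.assessment,
                              np.ones_like(s.annotation))


def test_split_sizes_and_class_balance(small_scene_cfg):
    ds = build_dataset("fake_vs_real", small_scene_cfg, 100,
                       (0.6, 0.2, 0.2), seed=1)
    assert [len(ds.splits[s]) for s in ("train", "validation", "test")] \
        == [60, 20, 20]
    labels = np.array([s.label for s in ds.samples])
    assert (labels == 0).sum() == 50 and (labels == 1).sum() == 50
    for name, idx in ds.splits.items():
        counts = np.bincount(labels[idx], minlength=2)
        assert abs(int(counts[0]) - int(counts[1])) <= 1


def test_species_classes_balanced(small_scene_cfg):
    ds = build_dataset("species", small_scene_cfg, 30, seed=2)
    labels = np.bincount([s.label for s in ds.samples])
    assert len(labels) == 3 and labels.min() == labels.max() == 10


def test_bad_split_fractions_rejected(small_scene_cfg):
    with pytest.raises(ValueError):
        build_dataset("fake_vs_real", small_scene_cfg, 20, (0.5, 0.2, 0.2),
                      seed=0)


def test_watermark_dataset_marks_corner_in_train_only():
    ds = build_watermark_dataset(n_samples=40, seed=4, patch=6)
    train = set(ds.splits["train"].tolist())
    test = set(ds.splits["test"].tolist())
    for i in train:
        s = ds.samples[i]
        assert s.annotation[:6, :6].all() and s.annotation.sum() == 36
        if s.label == 1:
            assert (s.image[:6, :6] == 1.0).all()
    for i in test:
        s = ds.samples[i]
        assert s.annotation.sum() == 0
        assert not (s.image[:6, :6] == 1.0).all()


def test_png_manifest_roundtrip(tmp_path, small_scene_cfg):
    ds = build_dataset("fake_vs_real", small_scene_cfg, 12, seed=5)
    manifest = save_dataset(ds, tmp_path)
    back = load_dataset(manifest)
    assert len(back) == 12
    assert back.class_names == ds.class_names
    for a, b in zip(ds.samples, back.samples):
        assert a.label == b.label
        assert np.array_equal(a.annotation, b.annotation)
        # images survive 8-bit quantization
        assert np.abs(a.image - b.image).max() <= 1.0 / 255.0 + 1e-6
    for split in ("train", "validation", "test"):
        assert np.array_equal(ds.splits[split], back.splits[split])
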