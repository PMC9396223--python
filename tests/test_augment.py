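"""Box-aware augmentation: geometry against a pixel-mask oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

from litchidet.augment import (COMBOS, augment_training_set, brightness,
                               equalize_hist, gaussian_noise, hflip, mosaic,
                               random_crop, rotate, salt_pepper,
                               scale_translate, vflip)
from litchidet.records import Box, ImageRecord


def _img(rng, w=64, h=64):
    return rng.integers(0, 255, (h, w, 3), dtype=np.uint8)


def _boxes_close(a, b, tol=1e-9):
    return (abs(a.x_min - b.x_min) < tol and abs(a.y_min - b.y_min) < tol
            and abs(a.x_max - b.x_max) < tol and abs(a.y_max - b.y_max) < tol)


class TestFlips:
    def test_hflip_is_an_involution(self, rng):
        img = _img(rng)
        boxes = [Box(3, 7, 20, 30), Box(40, 10, 60, 25, "raw_litchi")]
        img2, boxes2 = hflip(*hflip(img, boxes))
        assert np.array_equal(img, img2)
        assert all(_boxes_close(a, b) for a, b in zip(boxes, boxes2))

    def test_corner_arithmetic(self, rng):
        img = _img(rng, w=100, h=50)
        _, out = hflip(img, [Box(10, 20, 30, 40)])
        assert (out[0].x_min, out[0].y_min, out[0].x_max, out[0].y_max) == (70, 20, 90, 40)

    def test_centered_box_is_fixed(self, rng):
        img = _img(rng, w=100, h=100)
        box = Box(40, 30, 60, 70)
        _, out_h = hflip(img, [box])
        _, out_v = vflip(img, [box])
        assert _boxes_close(out_h[0], box) and _boxes_close(out_v[0], box)


class TestCrop:
    def test_zero_fraction_is_identity(self, rng):
        img = _img(rng)
        boxes = [Box(5, 5, 20, 20)]
        out, oboxes = random_crop(img, boxes, rng, frac_range=(0.0, 0.0))
        assert np.array_equal(out, img) and _boxes_close(oboxes[0], boxes[0])

    def test_box_inside_removed_strip_is_dropped(self, rng):
        img = _img(rng, w=100, h=100)
        boxes = [Box(2, 40, 15, 60), Box(50, 40, 80, 60)]
        # crop away the left 20% deterministically
        out, oboxes = random_crop(img[:, 20:], boxes, rng, frac_range=(0.0, 0.0))
        from litchidet.augment import _map_boxes
        mapped = _map_boxes(boxes, lambda p: p - [20, 0], 80, 100)
        assert len(mapped) == 1 and mapped[0].label == boxes[1].label

    @given(seed=st.integers(0, 200))
    def test_surviving_boxes_lie_inside_new_bounds(self, seed):
        rng = np.random.default_rng(seed)
        img = _img(rng, w=80, h=60)
        boxes = []
        for _ in range(5):
            x0, x1 = sorted(rng.uniform(0, 80, 2))
            y0, y1 = sorted(rng.uniform(0, 60, 2))
            if x1 - x0 > 1 and y1 - y0 > 1:
                boxes.append(Box(x0, y0, x1, y1))
        out, oboxes = random_crop(img, boxes, rng)
        h, w = out.shape[:2]
        for b in oboxes:
            assert 0 <= b.x_min < b.x_max <= w
            assert 0 <= b.y_min < b.y_max <= h


class TestRotate:
    def test_zero_angle_is_identity_on_boxes(self, rng):
        img = _img(rng)
        box = Box(10, 10, 30, 25)
        _, out = rotate(img, [box], 0.0)
        assert _boxes_close(out[0], box, tol=1e-6)

    def test_unit_square_at_45_degrees_has_sqrt2_hull(self, rng):
        img = _img(rng, w=100, h=100)
        box = Box(49.5, 49.5, 50.5, 50.5)  # unit square at the centre
        _, out = rotate(img, [box], 45.0)
        assert out[0].width == pytest.approx(np.sqrt(2), abs=1e-9)
        assert out[0].height == pytest.approx(np.sqrt(2), abs=1e-9)

    @given(angle=st.floats(-45, 45))
    def test_hull_area_never_below_box_area(self, angle):
        # small centred box: its rotated hull never leaves the canvas,
        # so the axis-aligned hull property holds without clipping
        img = np.zeros((200, 200, 3), dtype=np.uint8)
        box = Box(90, 85, 110, 115)
        _, out = rotate(img, [box], angle, min_visibility=0.0)
        assert out[0].area >= box.area - 1e-6


class TestPhotometric:
    def test_boxes_unchanged_by_any_photometric_op(self, rng):
        img = _img(rng)
        for op in (lambda im: equalize_hist(im),
                   lambda im: salt_pepper(im, rng),
                   lambda im: brightness(im, 1.3),
                   lambda im: gaussian_noise(im, rng, 10.0)):
            out = op(img)
            assert out.shape == img.shape and out.dtype == np.uint8

    def test_brightness_factor_one_is_identity(self, rng):
        img = _img(rng)
        assert np.array_equal(brightness(img, 1.0), img)

    def test_salt_pepper_corrupts_two_percent(self, rng):
        img = np.full((100, 100, 3), 128, dtype=np.uint8)
        out = salt_pepper(img, rng, 0.02)
        changed = (out != img).any(axis=2).sum()
        assert changed == 200  # every chosen pixel differs from gray 128


class TestScaleTranslate:
    def test_identity_parameters(self, rng):
        img = _img(rng)
        box = Box(10, 10, 30, 30)
        out, oboxes = scale_translate(img, [box], 1.0, 0.0, 0.0)
        assert _boxes_close(oboxes[0], box, tol=1e-9)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_half_scale_halves_box_dimensions(self, rng):
        img = _img(rng, w=200, h=200)
        box = Box(80, 80, 120, 140)
        _, oboxes = scale_translate(img, [box], 0.5, 0.0, 0.0)
        assert oboxes[0].width == pytest.approx(box.width / 2)
        assert oboxes[0].height == pytest.approx(box.height / 2)

    def test_scale_then_translate_composition_order(self, rng):
        img = _img(rng, w=100, h=100)
        box = Box(40, 40, 60, 60)  # centred: scaling fixes it, shift moves it
        _, oboxes = scale_translate(img, [box], 0.8, 0.1, 0.0)
        assert oboxes[0].center[0] == pytest.approx(60.0)  # 50 + 0.1*100
        assert oboxes[0].center[1] == pytest.approx(50.0)


class TestMaskOracle:
    """Transformed box == tight bounds of the transformed pixel mask."""

    @pytest.mark.parametrize("angle", [0.0, 10.0, 30.0])
    def test_rotation_box_matches_rasterized_mask_bounds(self, angle):
        w = h = 120
        box = Box(40, 50, 80, 78)
        mask = np.zeros((h, w), dtype=np.float64)
        mask[int(box.y_min):int(box.y_max), int(box.x_min):int(box.x_max)] = 1.0
        rotated_mask = ndimage.rotate(mask, angle, reshape=False, order=1)
        ys, xs = np.nonzero(rotated_mask > 0.5)
        img = np.zeros((h, w, 3), dtype=np.uint8)
        _, out = rotate(img, [box], angle, min_visibility=0.0)
        b = out[0]
        assert b.x_min == pytest.approx(xs.min(), abs=1.5)
        assert b.x_max == pytest.approx(xs.max() + 1, abs=1.5)
        assert b.y_min == pytest.approx(ys.min(), abs=1.5)
        assert b.y_max == pytest.approx(ys.max() + 1, abs=1.5)

    def test_flip_box_matches_flipped_mask_bounds(self):
        w, h = 90, 70
        box = Box(12, 20, 40, 33)
        mask = np.zeros((h, w))
        mask[int(box.y_min):int(box.y_max), int(box.x_min):int(box.x_max)] = 1
        _, out = hflip(np.zeros((h, w, 3), dtype=np.uint8), [box])
        ys, xs = np.nonzero(mask[:, ::-1])
        assert out[0].x_min == xs.min() and out[0].x_max == xs.max() + 1


class TestComboPipeline:
    def test_six_fold_enlargement_and_deterministic_labels(self, tmp_path, voc_corpus):
        voc_dir, records = voc_corpus
        out1 = augment_training_set(records[:2], tmp_path / "a", seed=7)
        out2 = augment_training_set(records[:2], tmp_path / "b", seed=7)
        assert len(out1) == 12  # 2 originals x (1 + 5 combos)
        label_files1 = sorted((tmp_path / "a").glob("*.txt"))
        label_files2 = sorted((tmp_path / "b").glob("*.txt"))
        for f1, f2 in zip(label_files1, label_files2):
            assert f1.read_text() == f2.read_text()

    def test_class_labels_never_change(self, voc_corpus, rng, tmp_path):
        _, records = voc_corpus
        rec = records[0]
        from litchidet.augment import load_image
        img = load_image(rec.image_path)
        for combo in COMBOS:
            _, boxes = combo.transform(img, list(rec.boxes),
                                       np.random.default_rng(0))
            assert {b.label for b in boxes} <= {b.label for b in rec.boxes}


class TestMosaic:
    def test_needs_exactly_four(self, rng):
        with pytest.raises(ValueError):
            mosaic([_img(rng)], [None], 128)

    def test_boxes_inside_canvas_and_counts(self, easy_pairs):
        images = [p[0] for p in easy_pairs[:4]]
        records = [p[1] for p in easy_pairs[:4]]
        canvas, rec = mosaic(images, records, 256, center=(128, 128))
        assert canvas.shape == (256, 256, 3)
        total_in = sum(len(r.boxes) for r in records)
        assert 0 < len(rec.boxes) <= total_in
        for b in rec.boxes:
            assert 0 <= b.x_min < b.x_max <= 256
            assert 0 <= b.y_min < b.y_max <= 256

    def test_centered_split_scales_each_quadrant_deterministically(self, easy_pairs):
        images = [p[0] for p in easy_pairs[:4]]
        records = [p[1] for p in easy_pairs[:4]]
        canvas, rec = mosaic(images, records, 384, center=(192, 192))
        # first record's boxes scale by 192/192=1.0 into the top-left quadrant
        h, w = images[0].shape[:2]
        b0 = records[0].boxes[0]
        expect = (b0.x_min * 192 / w, b0.y_min * 192 / h)
        found = min(rec.boxes, key=lambda b: (b.x_min - expect[0]) ** 2
                    + (b.y_min - expect[1]) ** 2)
        assert found.x_min == pytest.approx(expect[0], abs=1e-6)
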