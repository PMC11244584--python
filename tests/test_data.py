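import numpy as np
import pytest

from safi.data import (CLASS_NAMES, SceneObject, SceneSpec, augment,
                       box_to_yolo_line, generate_scene, mosaic, read_voc_xml,
                       read_yolo_txt, rotate_image_and_boxes, split_dataset,
                       write_voc_xml, write_yolo_txt, yolo_line_to_box,
                       _apply_brightness_saturation)
from safi.losses import BoundingBox


class TestGenerateScene:
    def test_empty_scene(self):
        img, labels = generate_scene(SceneSpec(image_size=(64, 64), objects=()))
        assert img.shape == (64, 64, 3) and labels == []

    def test_determinism_same_seed(self):
        spec = SceneSpec.random(seed=42, n_objects=3)
        a_img, a_lab = generate_scene(spec)
        b_img, b_lab = generate_scene(spec)
        assert np.array_equal(a_img, b_img)
        assert a_lab == b_lab

    def test_high_occlusion_excluded_from_labels(self):
        visible = SceneObject(0, 60.0, 60.0, 20.0, 15.0, 0.3, occlusion_fraction=0.2)
        hidden = SceneObject(1, 200.0, 200.0, 20.0, 15.0, 0.3, occlusion_fraction=0.9)
        spec = SceneSpec(image_size=(320, 320), objects=(visible, hidden))
        img, labels = generate_scene(spec)
        assert len(labels) == 1
        assert labels[0].class_id == 0
        # the occluded object is still drawn: pixels near it differ from a
        # scene rendered without it
        spec_wo = SceneSpec(image_size=(320, 320), objects=(visible,))
        img_wo, _ = generate_scene(spec_wo)
        assert not np.array_equal(img[180:220, 180:220], img_wo[180:220, 180:220])

    def test_occlusion_fraction_validated(self):
        with pytest.raises(ValueError):
            SceneObject(0, 10, 10, 5, 5, 0.0, occlusion_fraction=1.2)

    def test_labels_inside_image(self):
        for seed in range(5):
            spec = SceneSpec.random(seed=seed, n_objects=4, image_size=(160, 160))
            _, labels = generate_scene(spec)
            for b in labels:
                assert 0 <= b.x1 < b.x2 <= 160
                assert 0 <= b.y1 < b.y2 <= 160


class TestSplit:
    def test_paper_counts_6500(self):
        tr, va, te = split_dataset(range(6500), (7, 2, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (4550, 1300, 650)

    def test_ten_items(self):
        tr, va, te = split_dataset(range(10), (7, 2, 1), seed=3)
        assert (len(tr), len(va), len(te)) == (7, 2, 1)

    def test_empty(self):
        assert split_dataset([], (7, 2, 1), seed=0) == ([], [], [])

    def test_partition_property_100_sizes(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 500))
            items = list(range(n))
            tr, va, te = split_dataset(items, (7, 2, 1), seed=int(rng.integers(1e6)))
            assert sorted(tr + va + te) == items
            assert not (set(tr) & set(va)) and not (set(va) & set(te))
            assert not (set(tr) & set(te))

    def test_remainder_goes_to_train(self):
        tr, va, te = split_dataset(range(11), (7, 2, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (8, 2, 1)

    def test_bad_ratios(self):
        with pytest.raises(ValueError):
            split_dataset(range(5), (7, 0, 1), seed=0)

    def test_deterministic(self):
        a = split_dataset(range(50), seed=9)
        b = split_dataset(range(50), seed=9)
        assert a == b


class TestAugment:
    def test_identity_ops(self, rng):
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        boxes = [BoundingBox(0, 5, 5, 20, 20)]
        out_img, out_boxes = augment(img, boxes, ops=(), seed=0)
        assert np.array_equal(out_img, img)
        assert out_boxes == boxes

    def test_brightness_multiplier_one_identity(self, rng):
        img = rng.integers(10, 240, (32, 32, 3)).astype(float)
        assert np.array_equal(_apply_brightness_saturation(img, 1.0, 1.0), img)

    def test_photometric_leaves_boxes(self, rng):
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        boxes = [BoundingBox(1, 3, 4, 30, 40)]
        _, out = augment(img, boxes, ops=("brightness", "saturation",
                                          "gaussian_noise"), seed=5)
        assert out == boxes

    def test_rotation_90_centered_square_maps_to_itself(self, rng):
        img = rng.integers(0, 255, (100, 100, 3), dtype=np.uint8)
        box = BoundingBox(0, 30, 30, 70, 70)  # centred square
        _, out, dropped = rotate_image_and_boxes(img, [box], 90.0)
        assert not dropped
        assert out[0].as_array() == pytest.approx(box.as_array(), abs=1e-6)

    def test_rotation_boxes_stay_inside(self, rng):
        img = rng.integers(0, 255, (80, 80, 3), dtype=np.uint8)
        boxes = [BoundingBox(0, 0, 0, 20, 80), BoundingBox(1, 60, 60, 80, 80)]
        _, out, _ = rotate_image_and_boxes(img, boxes, 37.0)
        for b in out:
            assert 0 <= b.x1 < b.x2 <= 80 and 0 <= b.y1 < b.y2 <= 80

    def test_seeded_determinism(self, rng):
        img = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        boxes = [BoundingBox(0, 10, 10, 40, 40)]
        a = augment(img, boxes, seed=7)
        b = augment(img, boxes, seed=7)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown augment ops"):
            augment(np.zeros((8, 8, 3), dtype=np.uint8), [], ops=("cutmix",))


class TestMosaic:
    def test_solid_color_composite(self):
        imgs = [np.full((32, 32, 3), 77, dtype=np.uint8) for _ in range(4)]
        out, boxes = mosaic(imgs, [[], [], [], []], 64, seed=1)
        assert out.shape == (64, 64, 3)
        assert np.all(out == 77)
        assert boxes == []

    def test_requires_four(self):
        with pytest.raises(ValueError):
            mosaic([np.zeros((8, 8, 3), dtype=np.uint8)] * 3, [[]] * 3, 32, 0)

    def test_quadrant_affine_remap(self):
        imgs = [np.zeros((40, 40, 3), dtype=np.uint8) for _ in range(4)]
        box = BoundingBox(0, 10, 10, 20, 20)
        out, boxes = mosaic(imgs, [[box], [], [], []], 80, seed=3)
        # top-left quadrant rect is (0, 0, jx, jy); source is 40x40
        rng = np.random.default_rng(3)
        jx = int(rng.uniform(0.25, 0.75) * 80)
        jy = int(rng.uniform(0.25, 0.75) * 80)
        sx, sy = jx / 40, jy / 40
        expect = [10 * sx, 10 * sy, 20 * sx, 20 * sy]
        assert boxes[0].as_array() == pytest.approx(expect, abs=1e-9)

    def test_output_size(self):
        imgs = [np.zeros((16, 24, 3), dtype=np.uint8) for _ in range(4)]
        out, _ = mosaic(imgs, [[]] * 4, (48, 96), seed=0)
        assert out.shape == (96, 48, 3)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(min_value=0, max_value=2000), st.integers(min_value=0))
    @settings(max_examples=60, deadline=None)
    def test_split_partition_property(n, seed):
        items = list(range(n))
        tr, va, te = split_dataset(items, (7, 2, 1), seed=seed % 2**32)
        assert sorted(tr + va + te) == items
        assert len(va) == n * 2 // 10 and len(te) == n // 10
except ImportError:  # pragma: no cover
    pass


class TestLabelIO:
    def test_yolo_hand_conversion(self):
        b = yolo_line_to_box("0 0.5 0.5 0.1 0.2", (100, 100))
        assert b.as_array() == pytest.approx([45, 40, 55, 60])

    def test_yolo_round_trip(self, rng, tmp_path):
        boxes = []
        for _ in range(10):
            x1, y1 = rng.uniform(0, 60, 2)
            w, h = rng.uniform(1, 60, 2)
            boxes.append(BoundingBox(int(rng.integers(0, 2)), x1, y1,
                                     min(x1 + w, 128), min(y1 + h, 128)))
        path = tmp_path / "l.txt"
        write_yolo_txt(path, boxes, (128, 128))
        back = read_yolo_txt(path, (128, 128))
        for a, b in zip(boxes, back):
            assert a.class_id == b.class_id
            assert np.allclose(a.as_array() / 128, b.as_array() / 128, atol=1e-6)

    def test_voc_round_trip(self, rng, tmp_path):
        boxes = []
        for _ in range(8):
            x1, y1 = rng.uniform(0, 60, 2)
            w, h = rng.uniform(1, 40, 2)
            boxes.append(BoundingBox(int(rng.integers(0, 2)), x1, y1, x1 + w, y1 + h))
        path = tmp_path / "a.xml"
        write_voc_xml(path, boxes, (128, 128))
        back, size = read_voc_xml(path)
        assert size == (128, 128)
        for a, b in zip(boxes, back):
            assert a.class_id == b.class_id
            assert np.allclose(a.as_array(), b.as_array(), atol=0.01)

    def test_thin_edge_box_survives(self, tmp_path):
        b = BoundingBox(0, 126.0, 50.0, 128.0, 60.0)  # 2 px wide at the edge
        path = tmp_path / "edge.xml"
        write_voc_xml(path, [b], (128, 128))
        back, _ = read_voc_xml(path)
        assert back[0].x2 <= 128 and back[0].x2 - back[0].x1 > 0

    def test_malformed_xml_names_file(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<annotation><object>")
        with pytest.raises(ValueError, match="bad.xml"):
            read_voc_xml(path)

    def test_out_of_range_coordinates_rejected(self, tmp_path):
        path = tmp_path / "oob.xml"
        path.write_text(
            "<annotation><size><width>10</width><height>10</height></size>"
            "<object><name>Safflower-B</name><bndbox><xmin>5</xmin><ymin>5</ymin>"
            "<xmax>50</xmax><ymax>8</ymax></bndbox></object></annotation>")
        with pytest.raises(ValueError, match="out-of-range"):
            read_voc_xml(path)

    def test_bad_yolo_line_names_location(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 0.5 0.5 0.1\n")
        with pytest.raises(ValueError, match="bad.txt:1"):
            read_yolo_txt(path, (64, 64))
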