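import hashlib
import json
import math
from collections import Counter
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, strategies as st
from PIL import Image, ImageDraw

from phimprint import taxonomy
from phimprint import simulator as sim
from phimprint.backgrounds import make_synthetic_background
from phimprint.errors import ConfigError
from phimprint.simulator import (DatasetConfig, ImprintLabel,
                                 assign_image_classes, default_test_config,
                                 default_train_config, default_midi_config,
                                 detector_label_lines, place_imprints,
                                 read_labels, render_dataset, write_labels)


def small_cfg(**kw):
    params = dict(n_images=10, seed=0)
    params.update(kw)
    return default_test_config(**params)


class TestClassAssignment:
    def test_exact_allocation_at_paper_ratios(self):
        cfg = DatasetConfig(n_images=1000, phi_ratio=0.85, clean_ratio=0.05)
        classes = assign_image_classes(cfg)
        counts = Counter(classes)
        assert counts["has_phi"] == 850
        assert counts["clean"] == 50
        assert counts["nonphi_only"] == 100

    def test_all_phi(self):
        cfg = DatasetConfig(n_images=10, phi_ratio=1.0, clean_ratio=0.0)
        assert Counter(assign_image_classes(cfg))["has_phi"] == 10

    @given(st.integers(1, 500), st.floats(0, 1), st.floats(0, 1))
    def test_allocation_matches_rounding_oracle(self, n, phi, clean):
        if phi + clean > 1:
            return
        cfg = DatasetConfig(n_images=n, phi_ratio=phi, clean_ratio=clean)
        counts = Counter(assign_image_classes(cfg))
        n_phi = math.floor(phi * n + 0.5)
        n_clean = math.floor(clean * n + 0.5)
        if n - n_phi - n_clean < 0:
            return  # constructor may reject; covered below
        assert counts["has_phi"] == n_phi
        assert counts["clean"] == n_clean
        assert sum(counts.values()) == n

    def test_inconsistent_ratios_raise(self):
        with pytest.raises(ConfigError):
            DatasetConfig(n_images=10, phi_ratio=0.8, clean_ratio=0.5)

    def test_shuffle_is_seeded(self):
        cfg = DatasetConfig(n_images=50, seed=4)
        assert assign_image_classes(cfg) == assign_image_classes(cfg)


class TestPlacement:
    def _bg(self, seed=0):
        return make_synthetic_background(512, 512, seed, n_boxes=2)

    def test_clean_image_has_no_labels(self):
        record = place_imprints(self._bg(), "clean", small_cfg(), 0)
        assert record.labels == []
        assert record.image_class == "clean"

    def test_test_style_limits_and_disjointness(self):
        cfg = small_cfg()
        max_count = 0
        for seed in range(60):
            record = place_imprints(self._bg(seed), "has_phi", cfg, seed)
            assert 1 <= len(record.labels) <= 8
            max_count = max(max_count, len(record.labels))
            cats = Counter(l.sub_class for l in record.labels)
            assert max(cats.values()) <= 1
            assert any(l.phi_class for l in record.labels)
            boxes = [l.bbox for l in record.labels]
            for i, a in enumerate(boxes):
                assert 0 <= a[0] < a[2] <= 512 and 0 <= a[1] < a[3] <= 512
                for b in boxes[:i]:
                    assert (a[2] <= b[0] or b[2] <= a[0]
                            or a[3] <= b[1] or b[3] <= a[1])
        assert max_count == 8  # the budget is actually reachable

    def test_nonphi_only_excludes_phi_categories(self):
        for seed in range(20):
            record = place_imprints(self._bg(seed), "nonphi_only",
                                    small_cfg(), seed)
            assert record.labels
            assert not any(l.phi_class for l in record.labels)

    def test_phi_flag_matches_taxonomy(self):
        record = place_imprints(self._bg(3), "has_phi", small_cfg(), 3)
        for label in record.labels:
            assert label.phi_class == taxonomy.is_phi(label.sub_class)

    def test_midi_style_repeats_categories_and_exceeds_eight(self):
        cfg = default_midi_config(n_images=4, image_size=(768, 768))
        counts, any_repeat = [], False
        for seed in range(8):
            bg = make_synthetic_background(768, 768, seed)
            record = place_imprints(bg, "has_phi", cfg, seed)
            counts.append(len(record.labels))
            if max(Counter(l.sub_class for l in record.labels).values()) > 1:
                any_repeat = True
        assert all(10 <= c <= 30 for c in counts)
        assert max(counts) > 8
        assert any_repeat

    def test_rendered_text_is_burned_in(self):
        bg = make_synthetic_background(512, 512, 1, n_boxes=0)
        record = place_imprints(bg, "has_phi", small_cfg(), 1)
        for label in record.labels:
            x0, y0, x1, y1 = label.bbox
            crop = record.image.pixels[y0:y1, x0:x1]
            assert crop.std() > 0  # text pixels differ from background

    def test_label_crop_reproducible_from_render_params(self):
        """Re-rendering the stored text with the stored font parameters
        reproduces the burned-in crop (label self-consistency)."""
        bg = make_synthetic_background(512, 512, 2, n_boxes=0)
        record = place_imprints(bg, "has_phi", small_cfg(), 2)
        redraw = Image.fromarray(bg.pixels.copy())
        draw = ImageDraw.Draw(redraw)
        for label in record.labels:
            params = label.render
            font = sim._load_font(params["font_path"], params["size"])
            draw.text(tuple(params["origin"]), label.text, font=font,
                      fill=params["intensity"])
        np.testing.assert_array_equal(np.asarray(redraw), record.image.pixels)


class TestLabelFiles:
    def _labels(self):
        return [
            ImprintLabel((0, 0, 64, 32), True, "date", "DOB 01-01-2023",
                         {"size": 12}),
            ImprintLabel((10, 40, 90, 60), False, "marker", "L"),
        ]

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "labels.json"
        write_labels(self._labels(), path)
        assert read_labels(path) == self._labels()

    def test_detector_format_normalization(self):
        labels = [ImprintLabel((0, 0, 64, 32), True, "date", "x")]
        (line,) = detector_label_lines(labels, width=128, height=64)
        cls, xc, yc, w, h = line.split()
        assert int(cls) == sim.CLASS_INDEX["date"]
        assert (float(xc), float(yc), float(w), float(h)) == (0.25, 0.25, 0.5, 0.5)

    def test_empty_labels(self, tmp_path):
        write_labels([], tmp_path / "empty.json")
        assert read_labels(tmp_path / "empty.json") == []
        sim.write_detector_labels([], tmp_path / "empty.txt", 64, 64)
        assert (tmp_path / "empty.txt").read_text() == ""

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('[{"bbox": [0, 0, 4, 4]}]')
        with pytest.raises(sim.LabelParseError):
            read_labels(path)

    def test_label_rejects_inconsistent_phi_flag(self):
        with pytest.raises(ConfigError):
            ImprintLabel((0, 0, 4, 4), False, "date", "x")


class TestRenderDataset:
    def test_one_image_per_modality(self, tmp_path):
        cfg = small_cfg(n_images=4)
        manifest = render_dataset(cfg, tmp_path)
        assert Counter(e["modality"] for e in manifest["images"]) == \
            Counter({"ct": 1, "bone_scan": 1, "xray": 1, "mri": 1})
        for e in manifest["images"]:
            assert (tmp_path / "images" / f"{e['id']}.png").exists()
            assert (tmp_path / "labels" / f"{e['id']}.json").exists()
            assert (tmp_path / "labels_txt" / f"{e['id']}.txt").exists()

    def test_train_split_fractions(self, tmp_path):
        cfg = default_train_config(n_images=50)
        manifest = render_dataset(cfg, tmp_path)
        split = manifest["split"]
        assert len(split["train"]) == 40 and len(split["val"]) == 10
        assert set(split["train"]) | set(split["val"]) == \
            {e["id"] for e in manifest["images"]}

    def test_bit_identical_under_seed(self, tmp_path):
        cfg = small_cfg(n_images=6, seed=9)
        digests = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            render_dataset(cfg, out)
            h = hashlib.sha256()
            for f in sorted(out.rglob("*")):
                if f.is_file():
                    h.update(f.name.encode())
                    h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_manifest_class_consistency(self, tmp_path):
        cfg = small_cfg(n_images=12, seed=2)
        manifest = render_dataset(cfg, tmp_path)
        for e in manifest["images"]:
            labels = read_labels(tmp_path / "labels" / f"{e['id']}.json")
            has_phi = any(l.phi_class for l in labels)
            assert (e["class"] == "has_phi") == has_phi
            assert (e["class"] == "clean") == (not labels)

    def test_config_yaml_rejects_unknown_keys(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_images: 5\nbogus_key: 1\n")
        with pytest.raises(ConfigError):
            sim.config_from_yaml(path)
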