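"""Dataset simulation: burn synthetic imprints into backgrounds with ground truth.

Each image is first assigned one of three classes — ``clean`` (no imprints),
``nonphi_only``, or ``has_phi`` (at least one PHI imprint) — by an *exact*
allocation of the configured ratios, so dataset statistics are reproducible
rather than merely expected. Imprints are then composed from the taxonomy
grammars and rendered in varying fonts, sizes, intensities and positions.

Three dataset styles are supported:

``test``
    Evaluation style: at most 8 imprints per image, at most one imprint per
    category, imprint boxes never overlap.
``train``
    Detector-training style: same per-image limits but overlap between
    imprints (and with background structure) is permitted, as deliberately
    hard cases for a text localizer.
``midi``
    Viewer-overlay style: many imprints (default 10–30) with repeated
    categories, emulating DICOM-tag overlays rendered by a workstation
    viewer.

Every image gets a JSON label sidecar (boxes, PHI class, sub-class, text,
render parameters) and a detector-training text file (one normalized
``class x_center y_center width height`` line per imprint).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from PIL import Image, ImageDraw, ImageFont

from . import taxonomy
from .backgrounds import BackgroundImage, make_synthetic_background
from .errors import ConfigError, LabelParseError, PlacementError
from .taxonomy import ImprintContent, compose_imprint_text, generate_content

__all__ = [
    "ImprintLabel",
    "DatasetConfig",
    "ImageRecord",
    "assign_image_classes",
    "place_imprints",
    "render_dataset",
    "write_labels",
    "read_labels",
    "write_detector_labels",
    "detector_label_lines",
    "load_dataset",
    "default_test_config",
    "default_train_config",
    "default_midi_config",
    "CLASS_INDEX",
]

IMAGE_CLASSES = ("clean", "nonphi_only", "has_phi")

#: Stable category → detector class-index map (taxonomy order).
CLASS_INDEX = {c.id: i for i, c in enumerate(taxonomy.list_categories())}

FONT_SIZE_RANGE = (10, 28)
MIN_CONTRAST = 60
PLACEMENT_RETRIES = 50
IMAGE_REGEN_RETRIES = 20


@dataclass(frozen=True)
class ImprintLabel:
    """Ground truth for one rendered imprint.

    ``bbox`` is a 0-based half-open pixel box ``(x_min, y_min, x_max, y_max)``;
    ``phi_class`` mirrors the taxonomy PHI flag of ``sub_class``; ``render``
    records font family/size, intensity and text origin so the crop can be
    reproduced from the label alone.
    """

    bbox: tuple[int, int, int, int]
    phi_class: bool
    sub_class: str
    text: str
    render: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ConfigError(f"degenerate bbox {self.bbox}")
        if self.phi_class != taxonomy.is_phi(self.sub_class):
            raise ConfigError(
                f"phi_class {self.phi_class} inconsistent with taxonomy for "
                f"{self.sub_class!r}")


@dataclass
class DatasetConfig:
    """Simulation parameters for one dataset."""

    n_images: int = 1000
    phi_ratio: float = 0.85
    clean_ratio: float = 0.05
    max_imprints: int = 8
    min_imprints: int = 1
    max_per_category: Optional[int] = 1  # None = unlimited (midi style)
    modalities: tuple[str, ...] = ("ct", "bone_scan", "xray", "mri")
    style: str = "test"
    seed: int = 0
    force_accompanying: bool = False
    omit_accompanying_prob: float = 0.2
    image_size: tuple[int, int] = (512, 512)
    train_val_split: float = 0.8

    def __post_init__(self):
        if self.n_images < 1:
            raise ConfigError("n_images must be positive")
        if not (0 <= self.phi_ratio <= 1 and 0 <= self.clean_ratio <= 1):
            raise ConfigError("ratios must lie in [0, 1]")
        if self.phi_ratio + self.clean_ratio > 1 + 1e-12:
            raise ConfigError("phi_ratio + clean_ratio must not exceed 1")
        if self.max_imprints < 1 or self.min_imprints < 1:
            raise ConfigError("imprint counts must be at least 1")
        if self.min_imprints > self.max_imprints:
            raise ConfigError("min_imprints must not exceed max_imprints")
        if self.style not in ("train", "test", "midi"):
            raise ConfigError(f"unknown style {self.style!r}")
        if not self.modalities:
            raise ConfigError("at least one modality tag is required")
        self.modalities = tuple(self.modalities)
        self.image_size = tuple(self.image_size)

    @property
    def allows_overlap(self) -> bool:
        # evaluation style guarantees disjoint ground-truth boxes
        return self.style != "test"


def default_test_config(seed: int = 0, **overrides) -> DatasetConfig:
    """The evaluation split: 1000 images, 4 modalities, 85% with PHI."""
    return DatasetConfig(seed=seed, **overrides)


def default_train_config(seed: int = 0, **overrides) -> DatasetConfig:
    """Detector-training split: 6000 images incl. synthetic-canvas style,
    80–20 train/validation split, overlap permitted."""
    params = dict(n_images=6000, style="train",
                  modalities=("ct", "bone_scan", "xray", "synthetic"),
                  seed=seed)
    params.update(overrides)
    return DatasetConfig(**params)


def default_midi_config(seed: int = 0, **overrides) -> DatasetConfig:
    """Viewer-overlay style: many imprints with repeated categories."""
    params = dict(n_images=550, style="midi", min_imprints=10, max_imprints=30,
                  max_per_category=None, phi_ratio=0.8, clean_ratio=0.05,
                  image_size=(768, 768), seed=seed)
    params.update(overrides)
    return DatasetConfig(**params)


@dataclass
class ImageRecord:
    """One simulated image with its ground truth."""

    image: BackgroundImage
    labels: list[ImprintLabel]
    modality_tag: str
    image_class: str
    image_id: str = ""

    def __post_init__(self):
        has_phi = any(l.phi_class for l in self.labels)
        if self.image_class == "has_phi" and not has_phi:
            raise ConfigError("has_phi image must contain a PHI imprint")
        if self.image_class == "clean" and self.labels:
            raise ConfigError("clean image must have no labels")
        if self.image_class == "nonphi_only" and has_phi:
            raise ConfigError("nonphi_only image must not contain PHI")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def assign_image_classes(config: DatasetConfig,
                         rng: np.random.Generator | None = None) -> list[str]:
    """Exact class allocation: ``round(phi_ratio·n)`` images ``has_phi``,
    ``round(clean_ratio·n)`` ``clean``, the remainder ``nonphi_only``;
    order shuffled by the config seed (rounding is half-up)."""
    n = config.n_images
    n_phi = _round_half_up(config.phi_ratio * n)
    n_clean = _round_half_up(config.clean_ratio * n)
    n_nonphi = n - n_phi - n_clean
    if n_nonphi < 0:
        raise ConfigError(
            f"ratios allocate {n_phi}+{n_clean} images out of {n}")
    classes = (["has_phi"] * n_phi + ["clean"] * n_clean
               + ["nonphi_only"] * n_nonphi)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rng.shuffle(classes)
    return classes


# ---------------------------------------------------------------------------
# text rendering
# ---------------------------------------------------------------------------

_FONT_FILES: list[str] = []


def _discover_fonts() -> list[str]:
    """Scalable fonts available at run time (DejaVu family bundled with
    matplotlib); empty if none are importable."""
    if _FONT_FILES:
        return _FONT_FILES
    try:
        import matplotlib
        ttf_dir = Path(matplotlib.get_data_path()) / "fonts" / "ttf"
        for name in ("DejaVuSans.ttf", "DejaVuSansMono.ttf", "DejaVuSerif.ttf"):
            p = ttf_dir / name
            if p.exists():
                _FONT_FILES.append(str(p))
    except Exception:
        pass
    return _FONT_FILES


@lru_cache(maxsize=256)
def _load_font(family: str, size: int) -> ImageFont.ImageFont:
    if family == "default":
        return ImageFont.load_default(size=size)
    return ImageFont.truetype(family, size=size)


def _render_text(draw: ImageDraw.ImageDraw, text: str, x: int, y: int,
                 font, intensity: int) -> tuple[int, int, int, int]:
    draw.text((x, y), text, font=font, fill=intensity)
    x0, y0, x1, y1 = draw.textbbox((x, y), text, font=font)
    return int(x0), int(y0), int(x1), int(y1)


def _choose_intensity(pixels: np.ndarray, box: tuple[int, int, int, int],
                      rng: np.random.Generator) -> int:
    """Pick a text intensity with at least MIN_CONTRAST against the local
    mean background under the candidate box."""
    x0, y0, x1, y1 = box
    region = pixels[max(0, y0):max(1, y1), max(0, x0):max(1, x1)]
    mean = float(region.mean()) if region.size else 128.0
    dark_room = mean - MIN_CONTRAST
    light_room = 255 - (mean + MIN_CONTRAST)
    go_dark = dark_room >= 0 and (light_room < 0 or rng.random() < 0.5)
    if go_dark:
        return int(rng.integers(0, int(dark_room) + 1))
    return int(rng.integers(int(math.ceil(mean + MIN_CONTRAST)), 256))


def _boxes_overlap(a, b) -> bool:
    return not (a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1])


def _sample_categories(image_class: str, config: DatasetConfig,
                       rng: np.random.Generator) -> list[str]:
    """Draw the category sequence for one image, honoring the image class,
    the per-image imprint budget and the per-category limit."""
    cats = taxonomy.list_categories()
    phi_ids = [c.id for c in cats if c.is_phi]
    nonphi_ids = [c.id for c in cats if not c.is_phi]
    if image_class == "clean":
        return []
    pool = nonphi_ids if image_class == "nonphi_only" else [c.id for c in cats]
    count = int(rng.integers(config.min_imprints, config.max_imprints + 1))
    if config.max_per_category == 1:
        count = min(count, len(pool))
        idx = rng.choice(len(pool), size=count, replace=False)
        chosen = [pool[int(i)] for i in idx]
        if image_class == "has_phi" and not any(c in phi_ids for c in chosen):
            # force at least one PHI imprint by swapping a random slot
            slot = int(rng.integers(len(chosen)))
            chosen[slot] = phi_ids[int(rng.integers(len(phi_ids)))]
        return chosen
    chosen = [pool[int(i)] for i in rng.integers(0, len(pool), size=count)]
    if image_class == "has_phi" and not any(c in phi_ids for c in chosen):
        chosen[int(rng.integers(len(chosen)))] = \
            phi_ids[int(rng.integers(len(phi_ids)))]
    if config.max_per_category not in (None, 1):
        # clip repeats beyond the limit by resampling bounded times
        from collections import Counter
        for _ in range(100):
            counts = Counter(chosen)
            over = [c for c, k in counts.items() if k > config.max_per_category]
            if not over:
                break
            i = chosen.index(over[0])
            chosen[i] = pool[int(rng.integers(len(pool)))]
    return chosen


def place_imprints(background: BackgroundImage, image_class: str,
                   config: DatasetConfig,
                   rng: np.random.Generator | int | None = None) -> ImageRecord:
    """Render the imprints for one image and return it with ground truth.

    Placement draws a font, size, position and contrast-checked intensity per
    imprint; in ``test`` style boxes must not overlap and placement is
    retried up to PLACEMENT_RETRIES times per imprint, regenerating all
    positions (fresh draws) if a full layout cannot be found.
    """
    rng = np.random.default_rng(rng)
    if image_class not in IMAGE_CLASSES:
        raise ConfigError(f"unknown image class {image_class!r}")
    fonts = _discover_fonts() or ["default"]
    for _regen in range(IMAGE_REGEN_RETRIES):
        cat_ids = _sample_categories(image_class, config, rng)
        contents = []
        for cid in cat_ids:
            omit = 0.0 if config.force_accompanying else config.omit_accompanying_prob
            contents.append(generate_content(cid, rng, omit_accompanying_prob=omit))
        record = _try_layout(background, image_class, config, contents, fonts, rng)
        if record is not None:
            return record
    raise PlacementError(
        f"could not place {len(cat_ids)} imprints on a "
        f"{background.width}×{background.height} {config.style}-style image")


def _try_layout(background: BackgroundImage, image_class: str,
                config: DatasetConfig, contents: Sequence[ImprintContent],
                fonts: Sequence[str],
                rng: np.random.Generator) -> ImageRecord | None:
    pixels = background.pixels.copy()
    img = Image.fromarray(pixels)  # grayscale canvas
    draw = ImageDraw.Draw(img)
    labels: list[ImprintLabel] = []
    placed_boxes: list[tuple[int, int, int, int]] = []
    w, h = background.width, background.height
    for content in contents:
        text = compose_imprint_text(content)
        placed = False
        for _ in range(PLACEMENT_RETRIES):
            family = fonts[int(rng.integers(len(fonts)))]
            size = int(rng.integers(*FONT_SIZE_RANGE))
            font = _load_font(family, size)
            tx0, ty0, tx1, ty1 = draw.textbbox((0, 0), text, font=font)
            tw, th = tx1 - tx0, ty1 - ty0
            if tw < 1 or th < 1 or tw >= w or th >= h:
                continue  # try a different size
            x = int(rng.integers(0, w - tw))
            y = int(rng.integers(0, h - th))
            box = (x, y, x + tw, y + th)
            if not config.allows_overlap and any(
                    _boxes_overlap(box, b) for b in placed_boxes):
                continue
            intensity = _choose_intensity(np.asarray(img), box, rng)
            origin = (x - tx0, y - ty0)
            bx0, by0, bx1, by1 = _render_text(draw, text, origin[0], origin[1],
                                              font, intensity)
            bbox = (max(0, bx0), max(0, by0), min(w, max(bx1, bx0 + 1)),
                    min(h, max(by1, by0 + 1)))
            labels.append(ImprintLabel(
                bbox=bbox, phi_class=taxonomy.is_phi(content.category),
                sub_class=content.category, text=text,
                render={"font": Path(family).name if family != "default" else family,
                        "font_path": family, "size": size,
                        "intensity": intensity, "origin": list(origin)}))
            placed_boxes.append(bbox)
            placed = True
            break
        if not placed:
            return None
    out = BackgroundImage(np.asarray(img, dtype=np.uint8), background.modality_tag)
    return ImageRecord(image=out, labels=labels,
                       modality_tag=background.modality_tag,
                       image_class=image_class)


# ---------------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------------

def write_labels(labels: Iterable[ImprintLabel], path: Path | str) -> None:
    """Write the JSON label sidecar (lossless round-trip with read_labels)."""
    payload = [{"bbox": list(l.bbox), "phi_class": l.phi_class,
                "sub_class": l.sub_class, "text": l.text, "render": l.render}
               for l in labels]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_labels(path: Path | str) -> list[ImprintLabel]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LabelParseError(str(exc.msg), path=path, line=exc.lineno) from exc
    labels = []
    for i, d in enumerate(payload):
        try:
            labels.append(ImprintLabel(
                bbox=tuple(d["bbox"]), phi_class=bool(d["phi_class"]),
                sub_class=d["sub_class"], text=d["text"],
                render=d.get("render", {})))
        except (KeyError, TypeError, ConfigError) as exc:
            raise LabelParseError(f"bad label record {i}: {exc}",
                                  path=path, line=i + 1) from exc
    return labels


def detector_label_lines(labels: Iterable[ImprintLabel],
                         width: int, height: int) -> list[str]:
    """Detector-training lines: ``class x_center y_center w h`` normalized
    to [0, 1] (the de-facto single-line-of-text training dialect)."""
    lines = []
    for l in labels:
        x0, y0, x1, y1 = l.bbox
        xc = (x0 + x1) / 2 / width
        yc = (y0 + y1) / 2 / height
        bw = (x1 - x0) / width
        bh = (y1 - y0) / height
        cls = CLASS_INDEX[l.sub_class]
        lines.append(f"{cls} {xc:.6g} {yc:.6g} {bw:.6g} {bh:.6g}")
    return lines


def write_detector_labels(labels: Iterable[ImprintLabel], path: Path | str,
                          width: int, height: int) -> None:
    lines = detector_label_lines(labels, width, height)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# full dataset rendering
# ---------------------------------------------------------------------------

def render_dataset(config: DatasetConfig, out_dir: Path | str) -> dict:
    """Generate the full dataset under ``out_dir`` and return its manifest.

    Layout: ``images/<id>.png``, ``labels/<id>.json``,
    ``labels_txt/<id>.txt`` and ``manifest.json``. Images are partitioned
    equally (±1) across the configured modalities; everything is a pure
    function of ``(config, seed)``.
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "labels").mkdir(exist_ok=True)
        (out / "labels_txt").mkdir(exist_ok=True)
    except OSError as exc:
        raise ConfigError(f"cannot create output directory {out}: {exc}") from exc

    master = np.random.default_rng(config.seed)
    classes = assign_image_classes(config, master)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_images)
    w, h = config.image_size
    entries = []
    for i, (image_class, seq) in enumerate(zip(classes, seeds)):
        rng = np.random.default_rng(seq)
        modality = config.modalities[i % len(config.modalities)]
        n_boxes = int(rng.integers(0, 5))
        background = make_synthetic_background(w, h, rng, n_boxes=n_boxes,
                                               modality_tag=modality)
        record = place_imprints(background, image_class, config, rng)
        image_id = f"img_{i:05d}"
        record.image_id = image_id
        Image.fromarray(record.image.pixels).save(
            out / "images" / f"{image_id}.png", compress_level=1)
        write_labels(record.labels, out / "labels" / f"{image_id}.json")
        write_detector_labels(record.labels, out / "labels_txt" / f"{image_id}.txt",
                              width=w, height=h)
        entries.append({"id": image_id, "class": image_class,
                        "modality": modality, "n_imprints": len(record.labels),
                        "n_phi": sum(l.phi_class for l in record.labels)})

    manifest = {
        "config": _config_to_dict(config),
        "seed": config.seed,
        "class_index": CLASS_INDEX,
        "images": entries,
    }
    if config.style == "train":
        order = np.random.default_rng(config.seed + 1).permutation(config.n_images)
        cut = int(round(config.train_val_split * config.n_images))
        ids = [entries[int(j)]["id"] for j in order]
        manifest["split"] = {"train": sorted(ids[:cut]), "val": sorted(ids[cut:])}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _config_to_dict(config: DatasetConfig) -> dict:
    d = asdict(config)
    d["modalities"] = list(config.modalities)
    d["image_size"] = list(config.image_size)
    return d


def config_from_yaml(path: Path | str) -> DatasetConfig:
    """Load a DatasetConfig from a YAML file (keys = dataclass fields)."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: dataset config must be a mapping")
    known = DatasetConfig.__dataclass_fields__
    unknown = set(payload) - set(known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return DatasetConfig(**payload)


def load_dataset(dataset_dir: Path | str,
                 with_images: bool = False) -> tuple[dict, dict]:
    """Read a rendered dataset back: returns ``(manifest, records)`` where
    ``records`` maps image id → dict with ``labels``, ``class``, ``modality``
    and (optionally) ``pixels``."""
    root = Path(dataset_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    records = {}
    for entry in manifest["images"]:
        image_id = entry["id"]
        rec = {"labels": read_labels(root / "labels" / f"{image_id}.json"),
               "class": entry["class"], "modality": entry["modality"]}
        if with_images:
            rec["pixels"] = np.asarray(
                Image.open(root / "images" / f"{image_id}.png"))
        records[image_id] = rec
    return manifest, records
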