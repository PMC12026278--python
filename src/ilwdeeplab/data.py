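"""Reading and writing images, palette-indexed label masks, class palettes and
dataset manifests, plus the resize/scale/flip preprocessing used for training.

Mask dialect: palette-indexed PNG where the pixel value *is* the class id
(the PASCAL-VOC convention). RGB masks are accepted on read through an exact
colour -> id lookup; unknown colours are an error. Label maps are resized
with nearest-neighbour interpolation only — bilinear resampling would invent
fractional class ids.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class PaletteEntry:
    class_id: int
    name: str
    color: tuple[int, int, int]


@dataclass
class ClassPalette:
    entries: list[PaletteEntry] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.class_id for e in self.entries]
        if ids != list(range(len(ids))):
            raise ValueError("class ids must be 0..K-1 with no gaps")
        if not self.entries or self.entries[0].name != "background":
            raise ValueError("class 0 must be named 'background'")
        colors = [e.color for e in self.entries]
        if len(set(colors)) != len(colors):
            raise ValueError("palette colors must be pairwise distinct")

    @property
    def num_classes(self) -> int:
        return len(self.entries)

    @property
    def colors(self) -> list[tuple[int, int, int]]:
        return [e.color for e in self.entries]

    def color_to_id(self) -> dict[tuple[int, int, int], int]:
        return {e.color: e.class_id for e in self.entries}

    def to_json(self, path: str | Path) -> None:
        data = [{"id": e.class_id, "name": e.name, "color": list(e.color)}
                for e in self.entries]
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassPalette":
        data = json.loads(Path(path).read_text())
        return cls([PaletteEntry(d["id"], d["name"], tuple(d["color"]))
                    for d in data])


@dataclass
class SegSample:
    """An RGB image paired with an integer label map."""
    image: np.ndarray          # H x W x 3, uint8
    labels: np.ndarray         # H x W, integer class ids
    source_id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.labels.shape:
            raise ValueError("image and labels must share height/width")
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")


def read_mask(path: str | Path, palette: ClassPalette) -> np.ndarray:
    """Decode a palette-indexed or RGB mask file into an H x W class-id map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = Image.open(path)
    if img.mode == "P":
        labels = np.asarray(img, dtype=np.int64)
        if labels.max(initial=0) >= palette.num_classes:
            raise ValueError(
                f"mask contains index {labels.max()} >= K={palette.num_classes}")
        return labels
    rgb = np.asarray(img.convert("RGB"), dtype=np.uint8)
    lookup = palette.color_to_id()
    flat = rgb.reshape(-1, 3)
    colors, inverse = np.unique(flat, axis=0, return_inverse=True)
    ids = np.empty(len(colors), dtype=np.int64)
    for i, col in enumerate(colors):
        key = tuple(int(v) for v in col)
        if key not in lookup:
            raise ValueError(f"mask color {key} not in palette")
        ids[i] = lookup[key]
    return ids[inverse].reshape(rgb.shape[:2])


def write_mask(labels: np.ndarray, palette: ClassPalette,
               path: str | Path) -> None:
    """Write a class-id map as a palette-indexed PNG (exact round trip)."""
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= palette.num_classes:
        raise ValueError("label value outside 0..K-1")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = []
    for color in palette.colors:
        flat.extend(color)
    img.putpalette(flat)
    img.save(Path(path), format="PNG")


@dataclass
class DatasetManifest:
    split: str                               # "train" | "test"
    items: list[tuple[str, str]]             # (image path, mask path)
    num_classes: int

    def __post_init__(self):
        if self.split not in ("train", "test"):
            raise ValueError("split must be 'train' or 'test'")

    def validate_files(self) -> None:
        for img, msk in self.items:
            for p in (img, msk):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    def to_csv(self, path: str | Path, relative_to: str | Path | None = None
               ) -> None:
        """Write the manifest; with ``relative_to`` paths are stored relative
        to that directory (portable, reproducible trees)."""
        def fmt(p):
            if relative_to is None:
                return p
            return str(Path(p).resolve().relative_to(
                Path(relative_to).resolve()))
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["image", "mask"])
            w.writerows((fmt(i), fmt(m)) for i, m in self.items)

    @classmethod
    def from_csv(cls, path: str | Path, split: str,
                 num_classes: int) -> "DatasetManifest":
        """Relative entries are resolved against the CSV's directory."""
        base = Path(path).parent
        with open(path, newline="") as f:
            rows = list(csv.reader(f))
        if rows and rows[0] == ["image", "mask"]:
            rows = rows[1:]

        def resolve(p):
            return p if Path(p).is_absolute() else str(base / p)
        return cls(split, [(resolve(r[0]), resolve(r[1])) for r in rows],
                   num_classes)


def check_disjoint(train: DatasetManifest, test: DatasetManifest) -> None:
    overlap = ({p for p, _ in train.items} & {p for p, _ in test.items})
    if overlap:
        raise ValueError(f"paths appear in both splits: {sorted(overlap)[:3]}")


def load_sample(image_path: str | Path, mask_path: str | Path,
                palette: ClassPalette) -> SegSample:
    img = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.uint8)
    labels = read_mask(mask_path, palette)
    return SegSample(img, labels, source_id=str(image_path))


def preprocess(sample: SegSample, side: int = 512, training: bool = False,
               rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Resize to side x side (image bilinear, labels nearest), scale image to
    [0, 1], and in training mode flip both horizontally with probability 1/2.

    Returns (image CHW float32, labels HW int64).
    """
    if side <= 0:
        raise ValueError("side must be positive")
    img = Image.fromarray(sample.image).resize((side, side), Image.BILINEAR)
    lab = Image.fromarray(sample.labels.astype(np.uint8)).resize(
        (side, side), Image.NEAREST)
    image = np.asarray(img, dtype=np.float32) / 255.0
    labels = np.asarray(lab, dtype=np.int64)
    if training:
        rng = rng or np.random.default_rng(0)
        if rng.random() < 0.5:
            image = image[:, ::-1]
            labels = labels[:, ::-1]
    return np.ascontiguousarray(image.transpose(2, 0, 1)), \
        np.ascontiguousarray(labels)
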