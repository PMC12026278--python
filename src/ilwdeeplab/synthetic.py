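"""Deterministic synthetic plate scenes for end-to-end testing.

Each scene is a dark table surface carrying a bright circular plate with a
small number of elliptical food "items". Every food class has a fixed,
saturated base colour plus pixel noise, so the segmentation task is learnable
from colour and texture but not trivial. Later items occlude earlier ones
(emulating the occlusion failures real dishes produce), and class identities
are drawn from a long-tailed frequency profile (weights proportional to
1/rank by default) to mirror the imbalance of real food datasets.

Everything is reproducible from (seed, index): scenes are rendered from a
`numpy` generator seeded with a SeedSequence over those integers.
"""
from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import (ClassPalette, DatasetManifest, PaletteEntry, SegSample,
                   write_mask)
from .nutrition import CompositionRow, CompositionTable

BACKGROUND_COLOR = (20, 20, 24)
PLATE_COLOR = (235, 233, 228)


@dataclass
class SceneSpec:
    seed: int = 0
    num_classes: int = 4                   # background + K-1 foods
    items_per_scene: tuple[int, int] = (1, 3)
    class_frequency: tuple[float, ...] | None = None   # food classes 1..K-1
    canvas_side: int = 128
    plate_radius_fraction: float = 0.42
    noise_sigma: float = 9.0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need background plus at least one food class")
        if self.class_frequency is None:
            # long tail: weight of food class ranked r is 1/r
            self.class_frequency = tuple(
                1.0 / r for r in range(1, self.num_classes))
        w = np.asarray(self.class_frequency, dtype=float)
        if len(w) != self.num_classes - 1:
            raise ValueError("need one weight per food class")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        lo, hi = self.items_per_scene
        if lo < 0 or hi < lo:
            raise ValueError("invalid items_per_scene range")


def food_color(class_id: int, num_classes: int) -> tuple[int, int, int]:
    """Saturated, well-separated base colour for a food class."""
    h = (class_id - 1) / max(num_classes - 1, 1)
    r, g, b = colorsys.hsv_to_rgb(h, 0.85, 0.92)
    return (int(r * 255), int(g * 255), int(b * 255))


def build_palette(num_classes: int) -> ClassPalette:
    entries = [PaletteEntry(0, "background", BACKGROUND_COLOR)]
    entries += [PaletteEntry(k, f"food_{k}", food_color(k, num_classes))
                for k in range(1, num_classes)]
    return ClassPalette(entries)


def _scene_rng(spec: SceneSpec, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, index]))


def generate_scene_with_info(spec: SceneSpec, index: int
                             ) -> tuple[SegSample, dict]:
    rng = _scene_rng(spec, index)
    side = spec.canvas_side
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float32)
    cy = cx = side / 2.0
    plate_r = spec.plate_radius_fraction * side
    plate = (yy - cy) ** 2 + (xx - cx) ** 2 <= plate_r ** 2

    labels = np.zeros((side, side), np.int64)
    image = np.empty((side, side, 3), np.float32)
    image[...] = BACKGROUND_COLOR
    image[plate] = PLATE_COLOR

    weights = np.asarray(spec.class_frequency, float)
    probs = weights / weights.sum()
    lo, hi = spec.items_per_scene
    n_items = int(rng.integers(lo, hi + 1))
    for _ in range(n_items):
        k = int(rng.choice(np.arange(1, spec.num_classes), p=probs))
        # ellipse inside the plate
        theta = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.55 * plate_r)
        ey, ex = cy + rad * np.sin(theta), cx + rad * np.cos(theta)
        a = rng.uniform(0.16, 0.40) * plate_r
        b = rng.uniform(0.16, 0.40) * plate_r
        rot = rng.uniform(0, np.pi)
        dy, dx = yy - ey, xx - ex
        u = dx * np.cos(rot) + dy * np.sin(rot)
        v = -dx * np.sin(rot) + dy * np.cos(rot)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        inside &= plate                       # food stays on the plate
        labels[inside] = k                    # draw order resolves occlusion
        image[inside] = food_color(k, spec.num_classes)

    noise = rng.normal(0.0, spec.noise_sigma, image.shape).astype(np.float32)
    image = np.clip(image + noise, 0, 255).astype(np.uint8)

    areas = {int(k): int((labels == k).sum())
             for k in range(1, spec.num_classes) if (labels == k).any()}
    info = {"index": index, "plate_center": [cy, cx], "plate_radius": plate_r,
            "plate_area": int(plate.sum()), "class_pixel_areas": areas,
            "n_items": n_items}
    return SegSample(image, labels, source_id=f"scene_{index:05d}"), info


def generate_scene(spec: SceneSpec, index: int) -> SegSample:
    return generate_scene_with_info(spec, index)[0]


def toy_composition_table(num_classes: int) -> CompositionTable:
    """Deterministic plausible per-food reference servings and nutrients."""
    rows = []
    for k in range(1, num_classes):
        rng = np.random.default_rng(1000 + k)
        rows.append(CompositionRow(
            class_id=k, name=f"food_{k}",
            reference_serving_grams=float(rng.integers(150, 400)),
            kcal_per_100g=float(rng.integers(60, 350)),
            protein_per_100g=float(np.round(rng.uniform(1, 25), 1)),
            carb_per_100g=float(np.round(rng.uniform(2, 60), 1))))
    return CompositionTable(rows)


@dataclass
class GeneratedDataset:
    root: Path
    train: DatasetManifest
    test: DatasetManifest
    palette: ClassPalette
    composition: CompositionTable
    info_files: list[Path] = field(default_factory=list)


def generate_dataset(spec: SceneSpec, n_train: int, n_test: int,
                     out_dir: str | Path) -> GeneratedDataset:
    """Write images, masks, palette, manifests, per-scene area sidecars and a
    toy composition table under ``out_dir``. Train and test use disjoint scene
    indices (test indices start at n_train)."""
    if n_train < 0 or n_test < 0:
        raise ValueError("split sizes must be non-negative")
    root = Path(out_dir)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    palette = build_palette(spec.num_classes)
    palette.to_json(root / "palette.json")
    comp = toy_composition_table(spec.num_classes)
    comp.to_csv(root / "composition.csv")

    info_files = []

    def emit(indices, split):
        items = []
        for i in indices:
            sample, info = generate_scene_with_info(spec, i)
            img_p = root / "images" / f"{sample.source_id}.png"
            msk_p = root / "masks" / f"{sample.source_id}.png"
            Image.fromarray(sample.image).save(img_p)
            write_mask(sample.labels, palette, msk_p)
            info_p = root / "masks" / f"{sample.source_id}.json"
            info_p.write_text(json.dumps(info))
            info_files.append(info_p)
            items.append((str(img_p), str(msk_p)))
        man = DatasetManifest(split, items, spec.num_classes)
        man.to_csv(root / f"{split}.csv", relative_to=root)
        return man

    train = emit(range(n_train), "train")
    test = emit(range(n_train, n_train + n_test), "test")
    return GeneratedDataset(root, train, test, palette, comp, info_files)
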