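"""Mask-based nutrient estimation.

The chain mirrors how a dietitian-style estimate can be read off a
segmentation mask: (1) fit the smallest circle enclosing all non-background
pixels (a stand-in for the plate, slightly inflated by a margin), (2) express
each food's pixel count inside that circle as a fraction of the circle area,
(3) scale each food's reference serving weight by its area fraction and
convert grams to energy/protein/carbohydrate through per-100 g composition
values. Volume, stacking and occlusion are deliberately not modelled.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


# ---------------------------------------------------------------------------
# composition table
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CompositionRow:
    class_id: int
    name: str
    reference_serving_grams: float   # grams for a full-plate-area portion
    kcal_per_100g: float
    protein_per_100g: float
    carb_per_100g: float

    def __post_init__(self):
        vals = (self.reference_serving_grams, self.kcal_per_100g,
                self.protein_per_100g, self.carb_per_100g)
        if any(v < 0 for v in vals):
            raise ValueError("composition values must be non-negative")


@dataclass
class CompositionTable:
    rows: list[CompositionRow] = field(default_factory=list)

    def __post_init__(self):
        self._by_id = {r.class_id: r for r in self.rows}

    def get(self, class_id: int) -> CompositionRow | None:
        return self._by_id.get(class_id)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["class_id", "name", "reference_serving_grams",
                        "kcal_100g", "protein_100g", "carb_100g"])
            for r in self.rows:
                w.writerow([r.class_id, r.name, r.reference_serving_grams,
                            r.kcal_per_100g, r.protein_per_100g,
                            r.carb_per_100g])

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompositionTable":
        with open(path, newline="") as f:
            rows = list(csv.DictReader(f))
        return cls([CompositionRow(int(r["class_id"]), r["name"],
                                   float(r["reference_serving_grams"]),
                                   float(r["kcal_100g"]),
                                   float(r["protein_100g"]),
                                   float(r["carb_100g"])) for r in rows])


# ---------------------------------------------------------------------------
# smallest enclosing circle (Welzl-style incremental construction)
# ---------------------------------------------------------------------------
def _circle_from2(a, b):
    c = (a + b) / 2.0
    return c, float(np.linalg.norm(a - b) / 2.0)


def _circle_from3(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def _contains(circle, p, eps=1e-7):
    c, r = circle
    return np.linalg.norm(p - c) <= r + eps


def min_enclosing_circle(points: np.ndarray,
                         rng: np.random.Generator | None = None
                         ) -> tuple[np.ndarray, float]:
    """Smallest circle containing all 2-D points (expected linear time)."""
    pts = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    if len(pts) == 0:
        raise ValueError("no points")
    rng = rng or np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]
    circle = (pts[0], 0.0)
    for i in range(1, len(pts)):
        if _contains(circle, pts[i]):
            continue
        circle = (pts[i], 0.0)
        for j in range(i):
            if _contains(circle, pts[j]):
                continue
            circle = _circle_from2(pts[i], pts[j])
            for k in range(j):
                if _contains(circle, pts[k]):
                    continue
                c3 = _circle_from3(pts[i], pts[j], pts[k])
                if c3 is not None:
                    circle = c3
    return circle


# ---------------------------------------------------------------------------
# plate fitting and area fractions
# ---------------------------------------------------------------------------
@dataclass
class PlateRegion:
    center: tuple[float, float]      # (row, col)
    radius: float                    # pixels
    total_area: int                  # pixels inside the circle

    def __post_init__(self):
        if self.radius <= 0 or self.total_area <= 0:
            raise ValueError("degenerate plate region")


def _inside(labels_shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0:labels_shape[0], 0:labels_shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def fit_plate_circle(labels: np.ndarray, margin: float = 0.05) -> PlateRegion:
    """Minimum enclosing circle of all non-background pixels, radius inflated
    by ``margin``."""
    coords = np.argwhere(labels > 0)
    if len(coords) == 0:
        raise ValueError("mask contains no food pixels")
    if len(coords) > 2000:
        # boundary pixels suffice for the enclosing circle
        from scipy.spatial import ConvexHull
        hull = ConvexHull(coords.astype(float))
        coords = coords[hull.vertices]
    center, r = min_enclosing_circle(coords)
    r = max(r, 0.5) * (1.0 + margin)
    area = int(_inside(labels.shape, center, r).sum())
    return PlateRegion((float(center[0]), float(center[1])), float(r), area)


def area_fractions(labels: np.ndarray, plate: PlateRegion) -> dict[int, float]:
    """Per food class: (pixels of that class inside the circle) / circle area."""
    inside = _inside(labels.shape, plate.center, plate.radius)
    out = {}
    for k in np.unique(labels):
        if k == 0:
            continue
        out[int(k)] = float(((labels == k) & inside).sum() / plate.total_area)
    return out


# ---------------------------------------------------------------------------
# nutrient arithmetic
# ---------------------------------------------------------------------------
@dataclass
class FoodEstimate:
    class_id: int
    name: str
    area_fraction: float
    grams: float
    kcal: float
    protein_g: float
    carb_g: float
    known: bool = True


@dataclass
class NutrientEstimate:
    foods: list[FoodEstimate]
    total_grams: float
    total_kcal: float
    total_protein_g: float
    total_carb_g: float

    def by_class(self) -> dict[int, FoodEstimate]:
        return {f.class_id: f for f in self.foods}


def estimate_nutrients(fractions: dict[int, float],
                       table: CompositionTable) -> NutrientEstimate:
    """grams = fraction x reference serving; nutrients = grams x per100g / 100.

    Foods missing from the table are flagged unknown and excluded from the
    totals (with a warning).
    """
    foods = []
    tg = tk = tp = tc = 0.0
    for class_id, frac in sorted(fractions.items()):
        if not 0.0 <= frac <= 1.0 + 1e-9:
            raise ValueError(f"area fraction {frac} outside [0, 1]")
        row = table.get(class_id)
        if row is None:
            warnings.warn(f"class {class_id} missing from composition table; "
                          "excluded from totals")
            foods.append(FoodEstimate(class_id, f"class_{class_id}", frac,
                                      float("nan"), float("nan"),
                                      float("nan"), float("nan"), known=False))
            continue
        grams = frac * row.reference_serving_grams
        est = FoodEstimate(class_id, row.name, frac, grams,
                           grams * row.kcal_per_100g / 100.0,
                           grams * row.protein_per_100g / 100.0,
                           grams * row.carb_per_100g / 100.0)
        foods.append(est)
        tg += est.grams
        tk += est.kcal
        tp += est.protein_g
        tc += est.carb_g
    return NutrientEstimate(foods, tg, tk, tp, tc)


def estimate_from_mask(labels: np.ndarray, table: CompositionTable,
                       margin: float = 0.05) -> NutrientEstimate:
    plate = fit_plate_circle(labels, margin=margin)
    return estimate_nutrients(area_fractions(labels, plate), table)
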