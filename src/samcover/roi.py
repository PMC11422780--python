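"""Rectangular ROI geometry, landmark-relative placement, mm<->pixel conversion.

Regions of interest are axis-aligned rectangles on the image plane,
specified in the package-wide coordinate convention: 0-based ``(row, col)``
with half-open extents, so an ROI covers rows ``row0 .. row0+height_px-1``.

Physical ROI sizes are given in millimetres and converted through the cube's
pixel pitch.  The canonical cheek ROIs of the analysis — a 12 x 12 mm
reference patch and a 35 x 35 mm working region — are placed relative to the
standard 68-point facial-landmark annotation via configurable ``ROIRule``
objects; the exact anchors/offsets shipped as defaults are package
conventions, not published constants.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datacube import Datacube

__all__ = [
    "ROI",
    "LandmarkSet",
    "ROIRule",
    "mm_to_px",
    "derive_roi",
    "mirror_roi",
    "load_rules",
    "DEFAULT_RULES",
]

N_LANDMARKS = 68


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle: top-left pixel plus extent, half-open."""

    name: str
    row0: int
    col0: int
    height_px: int
    width_px: int

    def __post_init__(self) -> None:
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("ROI extents must be > 0")

    @property
    def row1(self) -> int:
        return self.row0 + self.height_px

    @property
    def col1(self) -> int:
        return self.col0 + self.width_px

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    @property
    def n_pixels(self) -> int:
        return self.height_px * self.width_px

    def center(self) -> tuple[float, float]:
        """ROI centre in (row, col), possibly half-integer."""
        return (self.row0 + self.height_px / 2.0, self.col0 + self.width_px / 2.0)

    def contains(self, other: "ROI") -> bool:
        return (
            self.row0 <= other.row0
            and self.col0 <= other.col0
            and self.row1 >= other.row1
            and self.col1 >= other.col1
        )

    def check_inside(self, shape: tuple[int, ...]) -> None:
        """Raise if the ROI is not fully inside an image of ``shape``."""
        h, w = shape[0], shape[1]
        if self.row0 < 0 or self.col0 < 0 or self.row1 > h or self.col1 > w:
            raise ValueError(
                f"ROI {self.name!r} [{self.row0}:{self.row1}, "
                f"{self.col0}:{self.col1}] lies outside the {h}x{w} image; "
                f"clip to [0:{h}, 0:{w}] or move the anchor"
            )


@dataclass(frozen=True)
class LandmarkSet:
    """The standard 68-point facial annotation, in (x, y) pixel coordinates.

    ``x`` is the column coordinate and ``y`` the row coordinate, matching the
    convention of the common landmark detectors whose output these files are.
    """

    points: np.ndarray  # (68, 2) as (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"landmark set must have exactly {N_LANDMARKS} (x, y) points; "
                f"got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def check_inside(self, shape: tuple[int, ...]) -> None:
        h, w = shape[0], shape[1]
        x, y = self.points[:, 0], self.points[:, 1]
        if np.any(x < 0) or np.any(y < 0) or np.any(x >= w) or np.any(y >= h):
            raise ValueError(f"landmarks fall outside the {h}x{w} image bounds")

    def centroid(self, indices) -> tuple[float, float]:
        """Centroid (x, y) of the selected landmark indices."""
        sel = self.points[np.asarray(indices, dtype=int)]
        return float(sel[:, 0].mean()), float(sel[:, 1].mean())

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        """Read 68 rows of ``x,y`` (an optional header row is skipped)."""
        rows = []
        with open(path, newline="") as f:
            for rec in csv.reader(f):
                if not rec:
                    continue
                try:
                    rows.append((float(rec[0]), float(rec[1])))
                except ValueError:
                    continue  # header
        return cls(np.asarray(rows))

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        data = json.loads(Path(path).read_text())
        return cls(np.asarray(data["points"] if isinstance(data, dict) else data))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["x", "y"])
            writer.writerows(self.points.tolist())


@dataclass(frozen=True)
class ROIRule:
    """Recipe for placing an ROI relative to a set of anchor landmarks.

    The ROI is centred at the anchor centroid shifted by ``offset_mm``
    (``dx`` along columns, ``dy`` along rows, in mm), with physical size
    ``size_mm = (width, height)``.
    """

    name: str
    anchor_landmarks: tuple[int, ...]
    offset_mm: tuple[float, float] = (0.0, 0.0)
    size_mm: tuple[float, float] = (12.0, 12.0)

    def __post_init__(self) -> None:
        if len(self.anchor_landmarks) == 0:
            raise ValueError("anchor landmark list must be non-empty")
        if self.size_mm[0] <= 0 or self.size_mm[1] <= 0:
            raise ValueError("size_mm entries must be > 0")
        object.__setattr__(self, "anchor_landmarks", tuple(int(i) for i in self.anchor_landmarks))


#: Default cheek rules.  Anchors: the upper right-side jaw contour (1-4) and
#: the right nostril wing (31), whose centroid sits on the right cheek.
#: These reproduce the geometry class of the analysis (a small reference
#: patch nested in a larger working region) as a documented package
#: convention.
DEFAULT_RULES: dict[str, ROIRule] = {
    "right_cheek": ROIRule(
        name="right_cheek",
        anchor_landmarks=(1, 2, 3, 4, 31),
        offset_mm=(0.0, 0.0),
        size_mm=(12.0, 12.0),
    ),
    "large_right_cheek": ROIRule(
        name="large_right_cheek",
        anchor_landmarks=(1, 2, 3, 4, 31),
        offset_mm=(0.0, 0.0),
        size_mm=(35.0, 35.0),
    ),
}


def load_rules(path) -> dict[str, ROIRule]:
    """Load ROI rules from a JSON file.

    Schema: ``{"name": {"anchor_landmarks": [...], "offset_mm": [dx, dy],
    "size_mm": [w, h]}, ...}``.
    """
    raw = json.loads(Path(path).read_text())
    rules = {}
    for name, spec in raw.items():
        rules[name] = ROIRule(
            name=name,
            anchor_landmarks=tuple(spec["anchor_landmarks"]),
            offset_mm=tuple(spec.get("offset_mm", (0.0, 0.0))),
            size_mm=tuple(spec.get("size_mm", (12.0, 12.0))),
        )
    return rules


def dump_rules(rules: dict[str, ROIRule], path) -> None:
    out = {
        name: {
            "anchor_landmarks": list(rule.anchor_landmarks),
            "offset_mm": list(rule.offset_mm),
            "size_mm": list(rule.size_mm),
        }
        for name, rule in rules.items()
    }
    Path(path).write_text(json.dumps(out, indent=2))


def mm_to_px(length_mm: float, pixel_pitch_um: float) -> int:
    """Convert a physical length to a pixel count: round(mm*1000/pitch), min 1.

    At the nominal 160 um pitch a 12 mm patch is 75 px; at 156.95 um a 35 mm
    patch is 223 px.
    """
    if length_mm <= 0 or pixel_pitch_um <= 0:
        raise ValueError("length_mm and pixel_pitch_um must both be > 0")
    return max(1, int(np.round(length_mm * 1000.0 / pixel_pitch_um)))


def derive_roi(rule: ROIRule, landmarks: LandmarkSet, cube: Datacube) -> ROI:
    """Place ``rule`` on an image: centre at anchor centroid + offset.

    The centre-to-corner conversion is ``floor(center - size/2)``;
    deterministic for fixed inputs.  Raises if the resulting ROI does not fit
    inside the cube.
    """
    landmarks.check_inside(cube.shape)
    cx, cy = landmarks.centroid(rule.anchor_landmarks)
    pitch = cube.pixel_pitch_um
    cx += rule.offset_mm[0] * 1000.0 / pitch
    cy += rule.offset_mm[1] * 1000.0 / pitch
    width = mm_to_px(rule.size_mm[0], pitch)
    height = mm_to_px(rule.size_mm[1], pitch)
    row0 = math.floor(cy - height / 2.0)
    col0 = math.floor(cx - width / 2.0)
    roi = ROI(name=rule.name, row0=row0, col0=col0, height_px=height, width_px=width)
    roi.check_inside(cube.shape)
    return roi


def mirror_roi(roi: ROI, cube: Datacube) -> ROI:
    """Reflect an ROI about the vertical midline of the image (same size)."""
    roi.check_inside(cube.shape)
    w = cube.shape[1]
    new_col0 = w - (roi.col0 + roi.width_px)
    mirrored = ROI(
        name=f"{roi.name}_mirrored" if not roi.name.endswith("_mirrored") else roi.name[: -len("_mirrored")],
        row0=roi.row0,
        col0=new_col0,
        height_px=roi.height_px,
        width_px=roi.width_px,
    )
    mirrored.check_inside(cube.shape)
    return mirrored
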