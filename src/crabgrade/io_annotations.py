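"""Reading and writing the formats the grading pipeline touches.

Polygon annotations use the Labelme JSON dialect (``shapes[].label``,
``shapes[].points``, ``imageWidth``, ``imageHeight``); masks are 0/255
PNGs; specimen metadata and grading reports are UTF-8 comma-delimited
CSV with a header row.

Coordinate convention (shared by every module downstream): x grows
rightward, y grows downward, the origin is the top-left *corner* of the
image, and pixel ``(row i, col j)`` has its center at ``(j + 0.5,
i + 0.5)``.  Rasterisation sets a pixel iff its center lies inside the
closed polygon, with centers exactly on an edge included.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "KNOWN_LABELS",
    "Sex",
    "PolygonAnnotation",
    "SpecimenRecord",
    "AnnotationFormatError",
    "ValidationError",
    "read_labelme",
    "write_labelme",
    "rasterize_polygon",
    "read_mask_png",
    "write_mask_png",
    "read_specimen_csv",
    "write_report_csv",
]

#: Annotation classes the pipeline acts on.  Unknown labels are kept
#: verbatim (forward compatibility) but trigger a warning on read.
KNOWN_LABELS = frozenset(
    {"carapace", "abdomen_male", "abdomen_female", "limb", "calibration_marker"}
)


class Sex(str, Enum):
    male = "male"
    female = "female"


class AnnotationFormatError(ValueError):
    """A file does not follow the expected dialect (names the bad key)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


@dataclass(frozen=True)
class PolygonAnnotation:
    """A labeled polygon in image pixel coordinates.

    Invariants: at least 3 points, the closed ring is simple
    (non-self-intersecting), and every vertex lies inside
    ``[0, image_width] x [0, image_height]``.
    """

    label: str
    points: tuple[tuple[float, float], ...]
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise ValidationError(
                f"polygon '{self.label}' has {len(pts)} points; need >= 3"
            )
        ring = Polygon(pts)
        if not ring.is_simple:
            raise ValidationError(f"polygon '{self.label}' self-intersects")
        for x, y in pts:
            if not (0.0 <= x <= self.image_width and 0.0 <= y <= self.image_height):
                raise ValidationError(
                    f"polygon '{self.label}' vertex ({x}, {y}) outside "
                    f"[0, {self.image_width}] x [0, {self.image_height}]"
                )

    def shapely(self) -> Polygon:
        return Polygon(self.points)


@dataclass(frozen=True)
class SpecimenRecord:
    """Per-crab metadata: id, sex, live weight (g), carapace thickness (cm)."""

    specimen_id: str
    sex: Sex
    weight_W: float  # grams
    thickness_H: float  # cm
    image_path: str = ""
    annotation_path: str = ""
    row: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        where = f" (row {self.row})" if self.row is not None else ""
        if not self.weight_W > 0:
            raise ValidationError(
                f"specimen '{self.specimen_id}'{where}: weight_W must be > 0 g, "
                f"got {self.weight_W}"
            )
        if not self.thickness_H > 0:
            raise ValidationError(
                f"specimen '{self.specimen_id}'{where}: thickness_H must be > 0 cm, "
                f"got {self.thickness_H}"
            )
        if not isinstance(self.sex, Sex):
            object.__setattr__(self, "sex", Sex(self.sex))


# ---------------------------------------------------------------------------
# Labelme JSON


def read_labelme(path: str | Path) -> list[PolygonAnnotation]:
    """Read polygon annotations from a Labelme-style JSON file.

    Coordinates are preserved bit-exact.  Shapes with labels outside
    :data:`KNOWN_LABELS` are retained verbatim with a warning.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("shapes", "imageWidth", "imageHeight"):
        if key not in doc:
            raise AnnotationFormatError(f"{path}: missing key '{key}'")
    width, height = int(doc["imageWidth"]), int(doc["imageHeight"])
    out: list[PolygonAnnotation] = []
    for k, shape in enumerate(doc["shapes"]):
        for key in ("label", "points"):
            if key not in shape:
                raise AnnotationFormatError(f"{path}: shapes[{k}] missing key '{key}'")
        label = shape["label"]
        if label not in KNOWN_LABELS:
            warnings.warn(f"{path}: unknown label '{label}' retained", stacklevel=2)
        out.append(
            PolygonAnnotation(
                label=label,
                points=tuple((p[0], p[1]) for p in shape["points"]),
                image_width=width,
                image_height=height,
            )
        )
    return out


def write_labelme(
    annotations: Sequence[PolygonAnnotation],
    image_width: int,
    image_height: int,
    path: str | Path,
) -> Path:
    """Write annotations as Labelme JSON, re-readable by :func:`read_labelme`."""
    path = Path(path)
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": a.label,
                "points": [[x, y] for x, y in a.points],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for a in annotations
        ],
        "imagePath": "",
        "imageData": None,
        "imageWidth": int(image_width),
        "imageHeight": int(image_height),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# Rasterisation and mask PNGs


def rasterize_polygon(
    annotation: PolygonAnnotation,
    image_width: int | None = None,
    image_height: int | None = None,
) -> np.ndarray:
    """Rasterise a polygon to a boolean mask of shape (height, width).

    A pixel is set iff its center ``(col + 0.5, row + 0.5)`` lies inside
    the closed polygon; centers exactly on an edge are included.
    """
    width = int(image_width if image_width is not None else annotation.image_width)
    height = int(image_height if image_height is not None else annotation.image_height)
    poly = annotation.shapely()
    if poly.area == 0:
        raise ValidationError(f"polygon '{annotation.label}' has zero area")
    mask = np.zeros((height, width), dtype=bool)
    # only pixel centers inside the polygon's bbox can be set
    xmin, ymin, xmax, ymax = poly.bounds
    c0 = max(int(np.floor(xmin - 0.5)), 0)
    c1 = min(int(np.ceil(xmax + 0.5)), width)
    r0 = max(int(np.floor(ymin - 0.5)), 0)
    r1 = min(int(np.ceil(ymax + 0.5)), height)
    if c1 <= c0 or r1 <= r0:
        return mask
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xs, ys = np.meshgrid(cols + 0.5, rows + 0.5)
    # intersects == inside-or-on-boundary for points vs a polygon
    inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    mask[r0:r1, c0:c1] = inside.reshape(len(rows), len(cols))
    return mask


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 mask PNG as a boolean array."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


# ---------------------------------------------------------------------------
# Specimen CSV and grading report

_SPECIMEN_COLUMNS = [
    "specimen_id",
    "sex",
    "weight_g",
    "thickness_cm",
    "image_path",
    "annotation_path",
]

#: Columns of the grading report CSV, fixed and versioned.
REPORT_COLUMNS = [
    "specimen_id",
    "sex",
    "sex_predicted",
    "integrity",
    "weight_g",
    "thickness_cm",
    "area_cm2",
    "length_cm",
    "width_cm",
    "K_raw",
    "K_percent",
    "grade",
    "status",
]


def read_specimen_csv(path: str | Path) -> list[SpecimenRecord]:
    """Read and validate specimen metadata.

    Raises :class:`ValidationError` naming the offending row (1-based,
    excluding the header) for non-positive weight/thickness or an
    unknown sex token.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = [c for c in _SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(f"{path}: missing columns {missing}")
    records = []
    for idx, r in df.iterrows():
        rownum = int(idx) + 1
        token = str(r["sex"]).strip().lower()
        try:
            sex = Sex(token)
        except ValueError:
            raise ValidationError(
                f"{path} row {rownum}: unknown sex '{r['sex']}'"
            ) from None
        records.append(
            SpecimenRecord(
                specimen_id=str(r["specimen_id"]),
                sex=sex,
                weight_W=float(r["weight_g"]),
                thickness_H=float(r["thickness_cm"]),
                image_path=str(r["image_path"]),
                annotation_path=str(r["annotation_path"]),
                row=rownum,
            )
        )
    return records


def write_report_csv(rows: Sequence[dict], path: str | Path) -> Path:
    """Write a grading report with the fixed :data:`REPORT_COLUMNS` schema."""
    path = Path(path)
    df = pd.DataFrame(list(rows))
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[REPORT_COLUMNS].to_csv(path, index=False)
    return path
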