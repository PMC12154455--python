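"""Calibrated carapace morphometrics from binary masks.

The measurement chain mirrors how a dorsal crab image is processed:

1. :func:`calibrate_from_marker` — turn the in-frame reference square of
   known physical side into pixel-to-metric scale factors ``S0``
   (cm²/px), ``La`` and ``Lb`` (cm/px).
2. :func:`tilt_correct` — rotate the segmented carapace so the long side
   of its minimum-area enclosing rectangle is horizontal.
3. :func:`measure` — count pixels and convert: projected area
   ``A = S0·N0``, carapace length ``L_l = L1·La`` and width
   ``L_w = L2·Lb`` from the axis-aligned pixel extents.

Axis assignment after tilt correction: the horizontal (long) extent is
the carapace *width* (medial-lateral) and the vertical extent is the
*length* (anterior-posterior) — mitten crab carapaces are wider than
long.  Extents are inclusive pixel counts (``max − min + 1``), so a
one-pixel-wide line has extent 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .io_annotations import ValidationError

__all__ = [
    "Calibration",
    "Morphometrics",
    "calibrate_from_marker",
    "tilt_correct",
    "compute_origin",
    "measure",
    "min_area_rect",
    "longest_axis_angle",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-metric scale factors.

    S0 is the physical area of one pixel (cm²/px); La and Lb are the
    physical side lengths of one pixel along x and y (cm/px).  The area
    and linear scales must be consistent: ``S0 == La·Lb`` to 1e-6
    relative.
    """

    S0: float
    La: float
    Lb: float

    def __post_init__(self) -> None:
        if not (self.S0 > 0 and self.La > 0 and self.Lb > 0):
            raise ValidationError("calibration factors must all be > 0")
        if abs(self.S0 - self.La * self.Lb) / self.S0 > 1e-6:
            raise ValidationError(
                f"inconsistent calibration: S0={self.S0} vs La*Lb={self.La * self.Lb}"
            )


@dataclass(frozen=True)
class Morphometrics:
    """Calibrated carapace measurements plus the raw pixel quantities."""

    length_Ll: float  # cm, anterior-posterior
    width_Lw: float  # cm, medial-lateral
    area_A: float  # cm²
    pixel_counts: tuple[int, int, int]  # (L1 length px, L2 width px, N0 area px)
    origin: tuple[float, float]  # (Ox, Oy), bounding-box center in pixels
    tilt_angle_deg: float  # rotation that was applied, in (-90, 90]


# ---------------------------------------------------------------------------


def calibrate_from_marker(marker_mask: np.ndarray, marker_side_cm: float) -> Calibration:
    """Derive scale factors from the segmented calibration square.

    The marker's pixel side is taken as ``sqrt(pixel count)``, which is
    robust to small boundary raggedness.  A marker bounding box with
    aspect ratio outside [0.8, 1.25] triggers a skew warning.
    """
    mask = np.asarray(marker_mask, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError("calibration marker mask is empty")
    if not marker_side_cm > 0:
        raise ValidationError("marker_side_cm must be > 0")
    rows, cols = np.nonzero(mask)
    h = rows.max() - rows.min() + 1
    w = cols.max() - cols.min() + 1
    aspect = w / h
    if not (0.8 <= aspect <= 1.25):
        warnings.warn(
            f"calibration marker bbox aspect {aspect:.3f} outside [0.8, 1.25]; "
            "skewed view suspected",
            stacklevel=2,
        )
    pixel_side = math.sqrt(n)
    La = Lb = marker_side_cm / pixel_side
    return Calibration(S0=La * Lb, La=La, Lb=Lb)


def min_area_rect(points_xy: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Minimum-area rotated enclosing rectangle of a 2-D point set.

    Returns ``(corners (4, 2), long_side, short_side, angle_deg)`` where
    ``angle_deg`` is the orientation of the long side in (-90, 90]
    (x rightward, y downward).  Degenerate (collinear) sets fall back to
    a zero-width rectangle along the principal direction.
    """
    pts = np.asarray(points_xy, float)
    try:
        hull = ConvexHull(pts)
        rect = Polygon(pts[hull.vertices]).minimum_rotated_rectangle
        corners = np.asarray(rect.exterior.coords)[:4]
    except (QhullError, AttributeError):
        # collinear: direction from PCA, zero short side
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        t = centered @ d
        p0 = pts.mean(axis=0) + t.min() * d
        p1 = pts.mean(axis=0) + t.max() * d
        corners = np.array([p0, p1, p1, p0])
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = np.hypot(*e1), np.hypot(*e2)
    long_vec, long_len, short_len = (e1, l1, l2) if l1 >= l2 else (e2, l2, l1)
    angle = math.degrees(math.atan2(long_vec[1], long_vec[0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return corners, float(long_len), float(short_len), angle


def _pixel_centers(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols + 0.5, rows + 0.5])


def longest_axis_angle(points_xy: np.ndarray) -> float:
    """Orientation (deg, in (-90, 90]) of a point set's longest axis.

    Computed from second central moments as the equivalent-ellipse major
    axis, ``0.5·atan2(2·mu11, mu20 − mu02)`` — for a carapace silhouette
    this is the direction of its longest line, and unlike an
    enclosing-rectangle orientation it stays numerically stable under
    pixelation even when the shape is nearly circular.
    """
    pts = np.asarray(points_xy, float)
    x, y = pts[:, 0] - pts[:, 0].mean(), pts[:, 1] - pts[:, 1].mean()
    mu20, mu02, mu11 = (x * x).mean(), (y * y).mean(), (x * y).mean()
    angle = math.degrees(0.5 * math.atan2(2.0 * mu11, mu20 - mu02))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


def tilt_correct(carapace_mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotate a mask so its longest axis (the carapace's longest line)
    is horizontal.

    The mask is rotated about its bounding-box center with
    nearest-neighbor resampling (masks stay binary); the canvas grows as
    needed so no pixels are clipped.  Returns the rotated mask and the
    applied rotation angle in degrees, in (-90, 90].
    """
    mask = np.asarray(carapace_mask, bool)
    if mask.sum() < 3:
        raise ValidationError("mask must contain at least 3 pixels")
    angle = longest_axis_angle(_pixel_centers(mask))
    tilt = -angle
    if tilt <= -90.0:
        tilt += 180.0
    if abs(tilt) < 1e-9:
        return mask.copy(), 0.0
    # ndi.rotate(+θ) turns the displayed image counterclockwise, i.e. a
    # feature at y-down orientation φ moves to φ − θ; θ = φ levels it.
    rotated = ndi.rotate(mask, angle, reshape=True, order=0, prefilter=False)
    return rotated.astype(bool), float(tilt)


def compute_origin(mask: np.ndarray) -> tuple[float, float]:
    """Bounding-box center of the set pixels: ``((Xmax+Xmin)/2, (Ymax+Ymin)/2)``.

    Coordinates are pixel indices (x = column, y = row).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    rows, cols = np.nonzero(mask)
    ox = (int(cols.max()) + int(cols.min())) / 2
    oy = (int(rows.max()) + int(rows.min())) / 2
    return ox, oy


def measure(carapace_mask: np.ndarray, calibration: Calibration,
            tilt_angle_deg: float = 0.0) -> Morphometrics:
    """Pixel counts and calibrated measurements of a tilt-corrected mask.

    ``N0`` is the set-pixel count; ``L2`` the horizontal extent
    (width axis) and ``L1`` the vertical extent (length axis), both
    inclusive.  Outputs: ``A = S0·N0``, ``L_l = L1·La``, ``L_w = L2·Lb``.
    """
    mask = np.asarray(carapace_mask, bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    rows, cols = np.nonzero(mask)
    n0 = int(mask.sum())
    l2 = int(cols.max() - cols.min() + 1)  # horizontal -> width
    l1 = int(rows.max() - rows.min() + 1)  # vertical -> length
    return Morphometrics(
        length_Ll=l1 * calibration.La,
        width_Lw=l2 * calibration.Lb,
        area_A=calibration.S0 * n0,
        pixel_counts=(l1, l2, n0),
        origin=compute_origin(mask),
        tilt_angle_deg=float(tilt_angle_deg),
    )
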