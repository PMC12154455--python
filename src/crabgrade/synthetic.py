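"""Seeded crab-phantom generator with analytically known morphometrics.

A phantom emulates the acquisition scene the grading pipeline expects:
a top-down crab silhouette on a uniform orange platform with an
axis-aligned calibration square of known physical side in the corner of
the frame.  The dorsal view carries an elliptical carapace (semi-axes
``a >= b`` in cm, so true width = 2a and length = 2b) with up to 10
detached capsule-shaped appendages (8 legs + 2 chelipeds); the ventral
view carries the sex-dimorphic abdominal flap — a pointed triangle for
males, a semicircle for females.

Every phantom ships its ground truth: the analytic carapace area
``pi*a*b``, length/width, sex, limb count, and a live weight
back-computed from a target percent fatness through the package's
percent mapping, so end-to-end grade recovery can be checked exactly.
All randomness derives from the spec's seed; identical specs produce
bit-identical images and annotations.

Deliberate simplifications (this is a measurement phantom, not a crab):
appendages are drawn with a small gap from the carapace so connected
components separate them, and the scene has no occlusion, shadows or
specular highlights — only optional Gaussian pixel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .grading import PERCENT_PER_K, Grade, assign_grade
from .io_annotations import (
    PolygonAnnotation,
    Sex,
    SpecimenRecord,
    ValidationError,
    rasterize_polygon,
    write_labelme,
    write_mask_png,
)
from .segmentation import DEFAULT_BACKGROUND_RGB, Integrity

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
    "CARAPACE_RGB",
    "LIMB_RGB",
    "FLAP_RGB",
    "MARKER_RGB",
]

CARAPACE_RGB = (70, 100, 60)
LIMB_RGB = (95, 85, 50)
FLAP_RGB = (205, 195, 175)
MARKER_RGB = (255, 255, 255)

_GAP_PX = 3.0  # carapace-to-limb gap so components stay separable
_LEG_LEN_CM, _LEG_W_CM = 1.6, 0.4
_CHELA_LEN_CM, _CHELA_W_CM = 1.2, 0.8
# appendage attachment angles on the ellipse (deg; 0 = +x, y down):
# 4 legs per side plus the two chelipeds at the front (top of frame)
_LIMB_ANGLES = (25.0, 55.0, 125.0, 155.0, 205.0, 235.0, 305.0, 335.0, 260.0, 280.0)
_CHELA_IDX = (8, 9)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic specimen and its imaging scene."""

    seed: int
    sex: Sex = Sex.male
    carapace_semiaxes_cm: tuple[float, float] = (3.0, 2.5)  # (a, b), a >= b
    rotation_deg: float = 0.0
    n_limbs_missing: int = 0
    thickness_H_cm: float = 2.8
    target_K_percent: float = 60.0
    marker_side_cm: float = 2.0
    image_size_px: tuple[int, int] = (480, 480)  # (width, height)
    pixels_per_cm: float = 25.0
    noise_sigma: float = 2.0
    specimen_id: str = ""

    def __post_init__(self) -> None:
        a, b = self.carapace_semiaxes_cm
        if not (a >= b > 0):
            raise ValidationError(f"need semi-axes a >= b > 0, got {(a, b)}")
        if not 0 <= self.n_limbs_missing <= 10:
            raise ValidationError("n_limbs_missing must be in [0, 10]")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not (self.thickness_H_cm > 0 and self.target_K_percent > 0):
            raise ValidationError("thickness and target fatness must be > 0")
        w, h = self.image_size_px
        ppcm = self.pixels_per_cm
        reach = a * ppcm + _GAP_PX + (_LEG_LEN_CM + _LEG_W_CM) * ppcm
        if reach > min(w, h) / 2 - 2:
            raise ValidationError(
                f"carapace with appendages (reach {reach:.0f}px) does not fit a "
                f"{w}x{h} image after rotation"
            )
        if not self.specimen_id:
            object.__setattr__(self, "specimen_id", f"phantom-{self.seed:08d}")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one phantom."""

    specimen_id: str
    sex: Sex
    area_cm2: float  # pi * a * b
    length_cm: float  # 2b, anterior-posterior
    width_cm: float  # 2a, medial-lateral
    thickness_cm: float
    weight_g: float
    K_raw: float
    K_percent: float
    grade: Grade
    limb_count: int
    integrity: Integrity
    rotation_deg: float


@dataclass(frozen=True)
class Phantom:
    spec: PhantomSpec
    dorsal_image: np.ndarray
    ventral_image: np.ndarray
    dorsal_annotations: tuple[PolygonAnnotation, ...]
    ventral_annotations: tuple[PolygonAnnotation, ...]
    record: SpecimenRecord
    truth: GroundTruth

    @property
    def carapace_mask(self) -> np.ndarray:
        ann = next(a for a in self.dorsal_annotations if a.label == "carapace")
        return rasterize_polygon(ann)


def _rot(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def _ellipse_polygon(center, a_px, b_px, rotation_deg, n=96) -> np.ndarray:
    phi = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    pts = np.column_stack([a_px * np.cos(phi), b_px * np.sin(phi)])
    return pts @ _rot(rotation_deg).T + center


def _capsule_polygon(p0, p1, width_px) -> np.ndarray:
    cap = LineString([tuple(p0), tuple(p1)]).buffer(width_px / 2.0, quad_segs=8)
    return np.asarray(cap.exterior.coords)[:-1]


def _paint(image: np.ndarray, ann: PolygonAnnotation, rgb) -> None:
    image[rasterize_polygon(ann)] = rgb


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom (dorsal + ventral views) with its ground truth."""
    width, height = spec.image_size_px
    ppcm = spec.pixels_per_cm
    a_cm, b_cm = spec.carapace_semiaxes_cm
    a_px, b_px = a_cm * ppcm, b_cm * ppcm
    center = np.array([width / 2.0, height / 2.0])
    rng = np.random.default_rng(spec.seed)

    def annot(label, pts):
        return PolygonAnnotation(
            label=label,
            points=tuple(map(tuple, pts)),
            image_width=width,
            image_height=height,
        )

    # ---- dorsal scene
    dorsal = np.empty((height, width, 3), np.float64)
    dorsal[:] = DEFAULT_BACKGROUND_RGB
    dorsal_ann: list[PolygonAnnotation] = []

    side = spec.marker_side_cm * ppcm
    marker_pts = np.array([[8, 8], [8 + side, 8], [8 + side, 8 + side], [8, 8 + side]], float)
    marker = annot("calibration_marker", marker_pts)
    _paint(dorsal, marker, MARKER_RGB)
    dorsal_ann.append(marker)

    missing = set(rng.choice(10, size=spec.n_limbs_missing, replace=False).tolist())
    R = _rot(spec.rotation_deg)
    for k, base_deg in enumerate(_LIMB_ANGLES):
        if k in missing:
            continue
        length_cm, width_cm_ = (
            (_CHELA_LEN_CM, _CHELA_W_CM) if k in _CHELA_IDX else (_LEG_LEN_CM, _LEG_W_CM)
        )
        t = math.radians(base_deg)
        edge = np.array([a_px * math.cos(t), b_px * math.sin(t)])
        out = edge / np.hypot(*edge)  # radial outward direction
        # the buffer's round cap extends w/2 behind the segment start,
        # so push the start out far enough to keep the gap clear
        p0 = edge + out * (_GAP_PX + width_cm_ * ppcm / 2.0)
        p1 = p0 + out * (length_cm - width_cm_) * ppcm
        pts = _capsule_polygon(p0 @ R.T + center, p1 @ R.T + center, width_cm_ * ppcm)
        limb = annot("limb", pts)
        _paint(dorsal, limb, LIMB_RGB)
        dorsal_ann.append(limb)

    carapace = annot("carapace", _ellipse_polygon(center, a_px, b_px, spec.rotation_deg))
    _paint(dorsal, carapace, CARAPACE_RGB)
    dorsal_ann.append(carapace)

    # ---- ventral scene (abdominal flap only)
    ventral = np.empty((height, width, 3), np.float64)
    ventral[:] = DEFAULT_BACKGROUND_RGB
    half_w = 0.55 * a_px
    if spec.sex is Sex.male:
        pts = np.array(
            [[-half_w, -0.8 * half_w], [half_w, -0.8 * half_w], [0.0, 0.8 * half_w]]
        ) + center
        flap = annot("abdomen_male", pts)
    else:
        phi = np.linspace(math.pi, 2 * math.pi, 49)  # flat top, arc below
        arc = np.column_stack([half_w * np.cos(phi), -half_w * np.sin(phi)])
        flap = annot("abdomen_female", arc + center)
    _paint(ventral, flap, FLAP_RGB)
    ventral_ann = [flap]

    if spec.noise_sigma > 0:
        dorsal += rng.normal(0.0, spec.noise_sigma, dorsal.shape)
        ventral += rng.normal(0.0, spec.noise_sigma, ventral.shape)
    dorsal_u8 = np.clip(np.rint(dorsal), 0, 255).astype(np.uint8)
    ventral_u8 = np.clip(np.rint(ventral), 0, 255).astype(np.uint8)

    # ---- analytic truth and back-computed weight
    area = math.pi * a_cm * b_cm
    k_raw = spec.target_K_percent / PERCENT_PER_K
    weight = k_raw * area * spec.thickness_H_cm / 3.0
    limb_count = 10 - spec.n_limbs_missing
    truth = GroundTruth(
        specimen_id=spec.specimen_id,
        sex=spec.sex,
        area_cm2=area,
        length_cm=2 * b_cm,
        width_cm=2 * a_cm,
        thickness_cm=spec.thickness_H_cm,
        weight_g=weight,
        K_raw=k_raw,
        K_percent=spec.target_K_percent,
        grade=assign_grade(spec.sex, spec.target_K_percent),
        limb_count=limb_count,
        integrity=Integrity.intact if limb_count >= 10 else Integrity.incomplete,
        rotation_deg=spec.rotation_deg,
    )
    record = SpecimenRecord(
        specimen_id=spec.specimen_id,
        sex=spec.sex,
        weight_W=weight,
        thickness_H=spec.thickness_H_cm,
    )
    return Phantom(
        spec=spec,
        dorsal_image=dorsal_u8,
        ventral_image=ventral_u8,
        dorsal_annotations=tuple(dorsal_ann),
        ventral_annotations=tuple(ventral_ann),
        record=record,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Cohorts

#: Per-grade sampling windows for the target percent fatness, inset from
#: the band edges so cohort members represent their grade distinctly.
_K_WINDOWS: dict[Sex, dict[Grade, tuple[float, float]]] = {
    Sex.male: {
        Grade.I: (65.5, 75.0),
        Grade.II: (62.5, 64.5),
        Grade.III: (58.5, 61.5),
        Grade.IV: (42.0, 57.5),
    },
    Sex.female: {
        Grade.I: (58.5, 66.0),
        Grade.II: (55.5, 57.5),
        Grade.III: (51.5, 54.5),
        Grade.IV: (40.0, 50.5),
    },
}

_DEFAULT_GRADE_MIX = {Grade.I: 0.25, Grade.II: 0.25, Grade.III: 0.25, Grade.IV: 0.25}


def _allocate(n: int, mix: Mapping[Grade, float]) -> list[Grade]:
    """Largest-remainder allocation of n phantoms to grades."""
    grades = list(mix)
    raw = np.array([mix[g] for g in grades], float)
    if raw.min() < 0 or abs(raw.sum() - 1.0) > 1e-9:
        raise ValidationError("grade_mix must be non-negative and sum to 1")
    exact = raw * n
    counts = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - counts))[: n - counts.sum()]:
        counts[i] += 1
    out: list[Grade] = []
    for g, c in zip(grades, counts):
        out.extend([g] * int(c))
    return out


def sample_specs(
    n: int,
    seed: int,
    sex_ratio: float = 0.5,
    grade_mix: Mapping[Grade | str, float] | None = None,
    intact_fraction: float = 0.8,
    rotation_range_deg: tuple[float, float] = (-45.0, 45.0),
    **overrides,
) -> list[PhantomSpec]:
    """Draw a reproducible stratified list of phantom specs.

    Stratified by sex (``sex_ratio`` = male fraction) and by target
    grade; morphology is drawn from market-typical ranges (carapace
    half-width 2.5-3.6 cm, thickness 2.4-3.4 cm).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    mix = {Grade(g): p for g, p in (grade_mix or _DEFAULT_GRADE_MIX).items()}
    rng = np.random.default_rng(seed)
    n_male = int(round(n * sex_ratio))
    specs: list[PhantomSpec] = []
    for sex, count, prefix in ((Sex.male, n_male, "M"), (Sex.female, n - n_male, "F")):
        grades = _allocate(count, mix)
        for i, grade in enumerate(grades, start=1):
            lo, hi = _K_WINDOWS[sex][grade]
            a = rng.uniform(2.5, 3.6)
            b = rng.uniform(0.75 * a, 0.95 * a)
            intact = rng.random() < intact_fraction
            specs.append(
                PhantomSpec(
                    seed=int(rng.integers(0, 2**31 - 1)),
                    sex=sex,
                    carapace_semiaxes_cm=(a, b),
                    rotation_deg=float(rng.uniform(*rotation_range_deg)),
                    n_limbs_missing=0 if intact else int(rng.integers(1, 4)),
                    thickness_H_cm=float(rng.uniform(2.4, 3.4)),
                    target_K_percent=float(rng.uniform(lo, hi)),
                    specimen_id=f"{prefix}-{i}",
                    **overrides,
                )
            )
    return specs


def generate_cohort(
    out_dir: str | Path,
    n: int,
    seed: int = 0,
    sex_ratio: float = 0.5,
    grade_mix: Mapping[Grade | str, float] | None = None,
    **spec_overrides,
) -> Path:
    """Write a full phantom dataset to ``out_dir``.

    Layout: ``images/*.png`` (dorsal + ventral + carapace masks),
    ``annotations/*.json`` (Labelme dialect), ``specimens.csv`` and
    ``ground_truth.csv``.  Reruns with identical arguments produce
    byte-identical CSVs.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    import imageio.v3 as iio

    spec_rows, truth_rows = [], []
    for spec in sample_specs(n, seed, sex_ratio, grade_mix, **spec_overrides):
        ph = generate_phantom(spec)
        sid = spec.specimen_id
        iio.imwrite(out / "images" / f"{sid}_dorsal.png", ph.dorsal_image)
        iio.imwrite(out / "images" / f"{sid}_ventral.png", ph.ventral_image)
        write_mask_png(ph.carapace_mask, out / "images" / f"{sid}_carapace_mask.png")
        w, h = spec.image_size_px
        write_labelme(ph.dorsal_annotations, w, h, out / "annotations" / f"{sid}_dorsal.json")
        write_labelme(ph.ventral_annotations, w, h, out / "annotations" / f"{sid}_ventral.json")
        spec_rows.append(
            {
                "specimen_id": sid,
                "sex": ph.record.sex.value,
                "weight_g": round(ph.record.weight_W, 4),
                "thickness_cm": round(ph.record.thickness_H, 4),
                "image_path": f"images/{sid}_dorsal.png",
                "annotation_path": f"annotations/{sid}_dorsal.json",
            }
        )
        t = ph.truth
        truth_rows.append(
            {
                "specimen_id": sid,
                "sex": t.sex.value,
                "area_cm2": round(t.area_cm2, 6),
                "length_cm": round(t.length_cm, 6),
                "width_cm": round(t.width_cm, 6),
                "thickness_cm": round(t.thickness_cm, 4),
                "weight_g": round(t.weight_g, 4),
                "K_raw": round(t.K_raw, 6),
                "K_percent": round(t.K_percent, 4),
                "grade": t.grade.value,
                "limb_count": t.limb_count,
                "integrity": t.integrity.value,
                "rotation_deg": round(t.rotation_deg, 4),
                "marker_side_cm": spec.marker_side_cm,
            }
        )
    pd.DataFrame(spec_rows).to_csv(out / "specimens.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    return out
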