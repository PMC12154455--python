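"""Condition factor and sex-specific quality grading.

The fatness index is a Fulton-type condition factor adapted to crabs:

    K = 3·W / (A·H)

with live weight W (g), projected carapace area A (cm²) and carapace
thickness H (cm).  Normalising weight by a volume proxy (area x
thickness) instead of length cubed makes the index track meat fullness
of a flat-bodied crustacean.

Grading uses the four-level Chinese mitten crab fatness standard, which
is expressed on a percent scale and differs by sex (females grade higher
at equal fatness because they command higher prices):

    male:   I > 65,  II (62, 65],  III (58, 62],  IV <= 58
    female: I > 58,  II (55, 58],  III [51, 55],  IV < 51

Band edges follow a half-open convention (a higher grade wins only
strictly above its threshold); the female III band is extended down to
an inclusive 51 and up to 55 so the bands partition all of K >= 0.

The percent scale of the standard is not algebraically fixed by K's
definition; this package maps K to percent with a single configurable
factor (:data:`PERCENT_PER_K`, default 20), chosen so that percent
fatness values typical of market crabs back-compute to live weights in
the observed 85-250 g range at plausible A and H.  Externally supplied
percent fatness values can be graded directly with
:func:`assign_grade`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .io_annotations import Sex, SpecimenRecord, ValidationError
from .morphometry import Morphometrics

__all__ = [
    "Grade",
    "GradeBand",
    "GradeResult",
    "ComparisonStats",
    "PERCENT_PER_K",
    "DEFAULT_GRADE_BANDS",
    "load_grade_bands",
    "condition_factor",
    "fatness_percent",
    "assign_grade",
    "grade_specimen",
    "compare_to_manual",
    "load_validation_panel",
]

#: Percent fatness per unit of K_raw (see module docstring).
PERCENT_PER_K = 20.0


class Grade(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True)
class GradeBand:
    """One band: matched when K > lower (or >= when lower_inclusive)."""

    grade: Grade
    lower: float
    lower_inclusive: bool = False


#: Sex-specific bands, checked top-down; the last band is the floor.
DEFAULT_GRADE_BANDS: dict[Sex, tuple[GradeBand, ...]] = {
    Sex.male: (
        GradeBand(Grade.I, 65.0),
        GradeBand(Grade.II, 62.0),
        GradeBand(Grade.III, 58.0),
        GradeBand(Grade.IV, float("-inf")),
    ),
    Sex.female: (
        GradeBand(Grade.I, 58.0),
        GradeBand(Grade.II, 55.0),
        GradeBand(Grade.III, 51.0, lower_inclusive=True),
        GradeBand(Grade.IV, float("-inf")),
    ),
}


def load_grade_bands(path: str | Path | None = None) -> dict[Sex, tuple[GradeBand, ...]]:
    """Load a grading threshold table from YAML (``sex -> list of bands``).

    With no path, the packaged default table is returned.
    """
    if path is None:
        source = resources.files("crabgrade.data").joinpath("grade_bands.yaml")
        doc = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    out: dict[Sex, tuple[GradeBand, ...]] = {}
    for sex_token, bands in doc.items():
        out[Sex(sex_token)] = tuple(
            GradeBand(
                grade=Grade(b["grade"]),
                lower=float(b["lower"]),
                lower_inclusive=bool(b.get("lower_inclusive", False)),
            )
            for b in bands
        )
    return out


@dataclass(frozen=True)
class GradeResult:
    """Fatness on both scales plus the assigned grade."""

    K_raw: float
    K_percent: float
    grade: Grade
    sex: Sex


# ---------------------------------------------------------------------------


def condition_factor(weight_W: float, area_A: float, thickness_H: float) -> float:
    """K = 3W/(A·H); all inputs must be strictly positive."""
    if not (weight_W > 0 and area_A > 0 and thickness_H > 0):
        raise ValidationError(
            f"condition factor needs positive W, A, H; got "
            f"W={weight_W}, A={area_A}, H={thickness_H}"
        )
    return 3.0 * weight_W / (area_A * thickness_H)


def fatness_percent(K_raw: float, percent_per_k: float = PERCENT_PER_K) -> float:
    """Map K_raw to the percent fatness scale of the grading standard."""
    return percent_per_k * K_raw


def assign_grade(
    sex: Sex | str,
    K_percent: float,
    bands: dict[Sex, tuple[GradeBand, ...]] | None = None,
) -> Grade:
    """Grade a percent-scale fatness value with the sex-specific bands."""
    if not K_percent >= 0:
        raise ValidationError(f"K_percent must be >= 0, got {K_percent}")
    sex = Sex(sex)
    table = (bands or DEFAULT_GRADE_BANDS)[sex]
    for band in table:
        if K_percent > band.lower or (band.lower_inclusive and K_percent == band.lower):
            return band.grade
    return table[-1].grade


def grade_specimen(
    record: SpecimenRecord,
    morpho: Morphometrics,
    bands: dict[Sex, tuple[GradeBand, ...]] | None = None,
    percent_per_k: float = PERCENT_PER_K,
) -> GradeResult:
    """Compose the condition factor and the band lookup for one specimen."""
    k_raw = condition_factor(record.weight_W, morpho.area_A, record.thickness_H)
    k_pct = fatness_percent(k_raw, percent_per_k)
    return GradeResult(
        K_raw=k_raw,
        K_percent=k_pct,
        grade=assign_grade(record.sex, k_pct, bands),
        sex=record.sex,
    )


# ---------------------------------------------------------------------------
# Automated-vs-manual comparison


@dataclass(frozen=True)
class ComparisonStats:
    n: int
    grade_consistency_pct: float
    max_abs_area_error: float  # cm², |A_auto − A_manual|
    max_rel_area_error_pct: float  # percent of the manual area, 1 decimal


def compare_to_manual(
    paired_rows: Sequence[tuple[float, float, Grade | str, float, float, Grade | str]],
) -> ComparisonStats:
    """Consistency and area-error statistics for paired automated/manual rows.

    Each row is ``(A_auto, K_auto, grade_auto, A_manual, K_manual,
    grade_manual)``.  Relative error is ``|ΔA|/A_manual`` in percent,
    reported to one decimal.
    """
    if len(paired_rows) == 0:
        raise ValidationError("need at least one paired row")
    agree = 0
    max_abs = 0.0
    max_rel = 0.0
    for a_auto, _, g_auto, a_man, _, g_man in paired_rows:
        if Grade(g_auto) == Grade(g_man):
            agree += 1
        abs_err = abs(a_auto - a_man)
        max_abs = max(max_abs, abs_err)
        max_rel = max(max_rel, 100.0 * abs_err / a_man)
    return ComparisonStats(
        n=len(paired_rows),
        grade_consistency_pct=100.0 * agree / len(paired_rows),
        max_abs_area_error=round(max_abs, 2),
        max_rel_area_error_pct=round(max_rel, 1),
    )


def load_validation_panel() -> pd.DataFrame:
    """The packaged 20-crab automated-vs-manual validation panel.

    Columns: specimen_id, sex, area_auto_cm2, fatness_auto_pct,
    grade_auto, area_manual_cm2, fatness_manual_pct, grade_manual.
    """
    source = resources.files("crabgrade.data").joinpath("validation_panel.csv")
    with source.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype={"specimen_id": str})
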