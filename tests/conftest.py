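"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check:
rasterisation is verified against a pure-Python point-in-polygon scan,
and average precision against a direct recall-grid interpolation.
"""

from __future__ import annotations

import numpy as np
import pytest

from crabgrade.morphometry import Calibration
from crabgrade.synthetic import PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# Oracles


def point_in_polygon(px: float, py: float, verts) -> bool:
    """Boundary-inclusive point-in-polygon by edge test + ray casting."""
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-9:
            if (
                min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
                and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9
            ):
                return True  # on an edge -> included
    inside = False
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def brute_rasterize(verts, width: int, height: int) -> np.ndarray:
    """Exhaustive pixel-center scan; independent of shapely."""
    mask = np.zeros((height, width), dtype=bool)
    for i in range(height):
        for j in range(width):
            mask[i, j] = point_in_polygon(j + 0.5, i + 0.5, verts)
    return mask


def ap_oracle(pairs, gt_count: int) -> float:
    """101-point AP by direct search: at each recall level on the grid,
    take the best precision achieved at that recall or beyond."""
    order = sorted(range(len(pairs)), key=lambda i: -pairs[i][0])
    tp = fp = 0
    prec, rec = [], []
    for i in order:
        if pairs[i][1]:
            tp += 1
        else:
            fp += 1
        prec.append(tp / (tp + fp))
        rec.append(tp / gt_count)
    total = 0.0
    for k in range(101):
        r = k / 100.0
        candidates = [p for p, rr in zip(prec, rec) if rr >= r - 1e-12]
        total += max(candidates) if candidates else 0.0
    return total / 101.0


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def unit_calibration() -> Calibration:
    """25 px/cm scale, matching the default phantom scene."""
    return Calibration(S0=(1 / 25) ** 2, La=1 / 25, Lb=1 / 25)


@pytest.fixture(scope="session")
def male_phantom():
    return generate_phantom(
        PhantomSpec(seed=101, rotation_deg=20.0, noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def female_phantom():
    from crabgrade.io_annotations import Sex

    return generate_phantom(
        PhantomSpec(
            seed=102,
            sex=Sex.female,
            carapace_semiaxes_cm=(3.2, 2.6),
            rotation_deg=-25.0,
            noise_sigma=0.0,
        )
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 12-phantom dataset on disk, shared by pipeline-level tests."""
    from crabgrade.synthetic import generate_cohort

    root = tmp_path_factory.mktemp("cohort")
    generate_cohort(root, n=12, seed=11)
    return root
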