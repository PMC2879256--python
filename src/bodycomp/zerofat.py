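"""Zero-fat analysis: minimal theoretical BMI as a function of height.

Setting FM = 0 in the covariate polynomial leaves only the intercept, age
and height terms, so FFM(0)/height^2 estimates the lowest theoretical BMI
attainable at a given stature.  These curves are claimed to be strictly
increasing and concave down in height; the shape check here is by first
and second finite differences on the sampling grid, with zero differences
counted as violations since the claim is strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .models import (HEIGHT_RANGE_CM, RaceGroup, SexCategory,
                     SubjectCovariates, mass_index, nhanes_ffm)


@dataclass(frozen=True)
class ZeroFatCurve:
    """BMI-versus-height samples at FM = 0 for one age/sex/race."""

    age_y: float
    sex: SexCategory
    race: RaceGroup
    heights_cm: np.ndarray
    bmi_kg_m2: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.heights_cm, dtype=float)
        b = np.asarray(self.bmi_kg_m2, dtype=float)
        if h.shape != b.shape or h.ndim != 1:
            raise ValidationError("samples: heights and BMI must be "
                                  "equal-length 1-D arrays")
        if np.any(np.diff(h) <= 0):
            raise ValidationError("heights_cm: must be strictly increasing")
        if np.any(b <= 0):
            raise ValidationError(
                "bmi_kg_m2: non-positive zero-fat BMI encountered (the "
                "selected coefficient row has a negative zero-fat intercept "
                "at this stature)")
        object.__setattr__(self, "heights_cm", h)
        object.__setattr__(self, "bmi_kg_m2", b)

    @property
    def samples(self) -> list[tuple[float, float]]:
        return list(zip(self.heights_cm.tolist(), self.bmi_kg_m2.tolist()))


@dataclass(frozen=True)
class ShapeReport:
    """Finite-difference shape verdict for a zero-fat curve."""

    increasing: bool
    concave_down: bool
    first_violation_height_cm: float | None


def bmi_at_zero_fat(cov: SubjectCovariates,
                    registry_variant: str | None = None) -> float:
    """Lowest theoretical BMI (kg/m^2): FFM at FM = 0 over height squared."""
    return mass_index(nhanes_ffm(0.0, cov, registry_variant), cov.height_cm)


def zero_fat_curve(age_y: float, sex: SexCategory, race: RaceGroup,
                   height_grid_cm: Sequence[float],
                   registry_variant: str | None = None) -> ZeroFatCurve:
    """Sample :func:`bmi_at_zero_fat` along a sorted height grid."""
    grid = np.asarray(height_grid_cm, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValidationError("height_grid_cm: need a non-empty 1-D grid")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("height_grid_cm: grid must be strictly "
                              "increasing")
    if grid[0] < HEIGHT_RANGE_CM[0] or grid[-1] > HEIGHT_RANGE_CM[1]:
        raise ValidationError(
            f"height_grid_cm: grid [{grid[0]}, {grid[-1]}] outside valid "
            f"height range {HEIGHT_RANGE_CM}")
    bmi = np.array([
        bmi_at_zero_fat(SubjectCovariates(age_y, float(h), sex, race),
                        registry_variant)
        for h in grid])
    return ZeroFatCurve(age_y=float(age_y), sex=sex, race=race,
                        heights_cm=grid, bmi_kg_m2=bmi)


def curve_shape_report(curve: ZeroFatCurve) -> ShapeReport:
    """Verify strict increase and strict concavity by finite differences.

    ``increasing`` holds iff every first difference is > 0 and
    ``concave_down`` iff every second difference is < 0; the height at
    which the first violation of either property occurs is reported.
    """
    h = curve.heights_cm
    b = curve.bmi_kg_m2
    if h.size < 3:
        raise ValidationError("curve: need at least 3 samples for shape "
                              "analysis")
    d1 = np.diff(b)
    d2 = np.diff(b, n=2)
    inc_viol = np.nonzero(d1 <= 0)[0]
    conc_viol = np.nonzero(d2 >= 0)[0]
    violations = []
    if inc_viol.size:
        violations.append(h[inc_viol[0] + 1])  # right end of the flat/falling step
    if conc_viol.size:
        violations.append(h[conc_viol[0] + 1])  # centre of the offending triple
    return ShapeReport(
        increasing=inc_viol.size == 0,
        concave_down=conc_viol.size == 0,
        first_violation_height_cm=float(min(violations)) if violations else None,
    )
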