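"""Core body-composition models.

Two model families relate fat-free mass (FFM, kg) to fat mass (FM, kg):

* A class of fourth-order polynomials in FM with age (A, years) and height
  (H, cm) covariates, fitted separately for the four (race, sex) groups of
  the NHANES DXA reference population.  The fixed 12-term basis is
  ``{1, F, A, H, F*A, F*H, F^2, F^2*A, F^3, F^4, F^2*H, F^3*H}``.
* The log-linear Forbes family ``FFM = slope * ln(FM) + intercept + D``,
  where the vertical translate ``D`` selects the member of the parallel
  family an individual actually travels during weight change.

Also provided: the analytic FM-derivative of the polynomial (needed by the
energy-balance reduction) and the height-normalised indices FFMI/FMI.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import DomainError, ValidationError

#: Canonical term order of the polynomial basis.  Design-matrix columns,
#: coefficient tables and fit outputs all follow this order.
BASIS_TERMS: tuple[str, ...] = (
    "1", "F", "A", "H", "FA", "FH", "F2", "F2A", "F3", "F4", "F2H", "F3H",
)

#: Valid covariate ranges.  They bracket the NHANES DXA survey population
#: (ages 8+) with margin; evaluation outside them is an error rather than a
#: warning to prevent silent quartic extrapolation.
AGE_RANGE_Y: tuple[float, float] = (8.0, 110.0)
HEIGHT_RANGE_CM: tuple[float, float] = (120.0, 220.0)


class SexCategory(enum.Enum):
    """Biological sex as recorded in the reference survey."""

    MALE = "M"
    FEMALE = "F"

    @classmethod
    def parse(cls, label: str) -> "SexCategory":
        """Parse a CSV label ("M"/"F", case-insensitive, or full words)."""
        s = str(label).strip().upper()
        if s in ("M", "MALE"):
            return cls.MALE
        if s in ("F", "FEMALE"):
            return cls.FEMALE
        raise ValidationError(f"sex: unrecognised label {label!r} (expected M or F)")


class RaceGroup(enum.Enum):
    """Race group retained in the final models.

    Only an African American indicator survived model selection; every
    other ethnic group is pooled into the non-African-American (NAA) group.
    """

    AA = "AA"
    NAA = "NAA"

    @classmethod
    def parse(cls, label: str) -> "RaceGroup":
        """Parse a race label; anything other than African American maps to NAA.

        Labels for the ethnic groups the survey distinguishes (white,
        Hispanic, Asian) coerce silently; unrecognised labels coerce to NAA
        with a warning.
        """
        s = str(label).strip().upper().replace("-", " ")
        if s in ("AA", "AFRICAN AMERICAN", "BLACK"):
            return cls.AA
        if s in ("NAA", "NON AFRICAN AMERICAN", "WHITE", "WHITE NON HISPANIC",
                 "HISPANIC", "ASIAN"):
            return cls.NAA
        warnings.warn(
            f"race: unrecognised label {label!r}; coerced to NAA",
            UserWarning,
            stacklevel=2,
        )
        return cls.NAA


def _check_finite(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise ValidationError(f"{name}: must be finite, got {value!r}")
    return v


@dataclass(frozen=True)
class SubjectCovariates:
    """Age/height/sex/race bundle entering every polynomial evaluation.

    Parameters
    ----------
    age_y : float
        Age in years, within ``AGE_RANGE_Y``.
    height_cm : float
        Standing height in centimetres, within ``HEIGHT_RANGE_CM``.
    sex, race : SexCategory, RaceGroup
        Group selectors for the coefficient registry.
    """

    age_y: float
    height_cm: float
    sex: SexCategory
    race: RaceGroup

    def __post_init__(self):
        a = _check_finite("age_y", self.age_y)
        h = _check_finite("height_cm", self.height_cm)
        if not AGE_RANGE_Y[0] <= a <= AGE_RANGE_Y[1]:
            raise ValidationError(
                f"age_y: {a} outside valid range {AGE_RANGE_Y}")
        if not HEIGHT_RANGE_CM[0] <= h <= HEIGHT_RANGE_CM[1]:
            raise ValidationError(
                f"height_cm: {h} outside valid range {HEIGHT_RANGE_CM}")
        if not isinstance(self.sex, SexCategory):
            raise ValidationError(f"sex: expected SexCategory, got {self.sex!r}")
        if not isinstance(self.race, RaceGroup):
            raise ValidationError(f"race: expected RaceGroup, got {self.race!r}")


@dataclass(frozen=True)
class BodyState:
    """Paired (FM, FFM) in kg; total mass is the exact sum of the two."""

    fm_kg: float
    ffm_kg: float

    def __post_init__(self):
        fm = _check_finite("fm_kg", self.fm_kg)
        ffm = _check_finite("ffm_kg", self.ffm_kg)
        if fm < 0:
            raise ValidationError(f"fm_kg: must be >= 0, got {fm}")
        if ffm <= 0:
            raise ValidationError(f"ffm_kg: must be > 0, got {ffm}")

    @property
    def total_kg(self) -> float:
        return self.fm_kg + self.ffm_kg


class PolynomialCoefficients:
    """The 12-term coefficient row for one (race, sex) group.

    Behaves as an immutable mapping keyed by the names in ``BASIS_TERMS``;
    a coefficient may be zero but every key must be present and finite.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float]):
        keys = set(values)
        missing = set(BASIS_TERMS) - keys
        extra = keys - set(BASIS_TERMS)
        if missing or extra:
            raise ValidationError(
                f"coefficients: missing terms {sorted(missing)}, "
                f"unknown terms {sorted(extra)}")
        vals = {}
        for t in BASIS_TERMS:
            vals[t] = _check_finite(f"coefficient[{t}]", values[t])
        object.__setattr__(self, "_values", vals)

    def __getitem__(self, term: str) -> float:
        return self._values[term]

    def __iter__(self):
        return iter(BASIS_TERMS)

    def __eq__(self, other):
        return (isinstance(other, PolynomialCoefficients)
                and self._values == other._values)

    def __repr__(self):
        return f"PolynomialCoefficients({self._values!r})"

    def items(self):
        return self._values.items()

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def as_array(self) -> np.ndarray:
        """Coefficients as a length-12 array in ``BASIS_TERMS`` order."""
        return np.array([self._values[t] for t in BASIS_TERMS], dtype=float)


def monomials(fm_kg, age_y, height_cm) -> np.ndarray:
    """Stack the 12 basis monomials; broadcasts over array-valued FM.

    Returns an array of shape ``(..., 12)`` with the last axis in
    ``BASIS_TERMS`` order.
    """
    F = np.asarray(fm_kg, dtype=float)
    A = np.asarray(age_y, dtype=float)
    H = np.asarray(height_cm, dtype=float)
    one = np.ones(np.broadcast_shapes(F.shape, A.shape, H.shape))
    F, A, H = (np.broadcast_to(x, one.shape) for x in (F, A, H))
    return np.stack(
        [one, F, A, H, F * A, F * H, F**2, F**2 * A, F**3, F**4,
         F**2 * H, F**3 * H],
        axis=-1,
    )


def evaluate_polynomial(coeffs: PolynomialCoefficients, fm_kg, age_y,
                        height_cm):
    """Evaluate a coefficient row at (F, A, H); broadcasts over arrays.

    This is the raw evaluator behind :func:`nhanes_ffm`; it performs no
    covariate validation and is what the cohort generator and curve
    samplers use on vector input.
    """
    out = monomials(fm_kg, age_y, height_cm) @ coeffs.as_array()
    return float(out) if out.ndim == 0 else out


def evaluate_polynomial_derivative(coeffs: PolynomialCoefficients, fm_kg,
                                   age_y, height_cm):
    """Analytic partial derivative of the polynomial with respect to FM."""
    F = np.asarray(fm_kg, dtype=float)
    A = np.asarray(age_y, dtype=float)
    H = np.asarray(height_cm, dtype=float)
    c = coeffs
    out = (c["F"] + c["FA"] * A + c["FH"] * H
           + 2.0 * c["F2"] * F + 2.0 * c["F2A"] * F * A
           + 3.0 * c["F3"] * F**2 + 4.0 * c["F4"] * F**3
           + 2.0 * c["F2H"] * F * H + 3.0 * c["F3H"] * F**2 * H)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def _validated_fm(fm_kg) -> float:
    fm = _check_finite("fm_kg", fm_kg)
    if fm < 0:
        raise ValidationError(f"fm_kg: must be >= 0, got {fm}")
    return fm


def nhanes_ffm(fm_kg: float, cov: SubjectCovariates,
               registry_variant: str | None = None) -> float:
    """Fat-free mass (kg) from the NHANES-derived polynomial class.

    Parameters
    ----------
    fm_kg : float
        Fat mass in kg, >= 0.
    cov : SubjectCovariates
        Age, height, sex and race selecting the coefficient row.
    registry_variant : str, optional
        ``"printed"``, ``"normalized"`` or ``"corrected"`` (default; see
        :mod:`bodycomp.registry` for what distinguishes them).

    Returns
    -------
    float
        FFM in kg.  Pure and deterministic.
    """
    from .registry import get_coefficients

    fm = _validated_fm(fm_kg)
    coeffs = get_coefficients(cov.race, cov.sex, registry_variant)
    return evaluate_polynomial(coeffs, fm, cov.age_y, cov.height_cm)


def nhanes_dffm_dfm(fm_kg: float, cov: SubjectCovariates,
                    registry_variant: str | None = None) -> float:
    """Analytic d(FFM)/d(FM) of the polynomial at the given point.

    This closed-form slope is what the energy-balance chain-rule reduction
    consumes; it agrees with a central finite difference of
    :func:`nhanes_ffm` to well below 1e-6.
    """
    from .registry import get_coefficients

    fm = _validated_fm(fm_kg)
    coeffs = get_coefficients(cov.race, cov.sex, registry_variant)
    return evaluate_polynomial_derivative(coeffs, fm, cov.age_y, cov.height_cm)


# Published Forbes constants (kg per ln-kg, kg).
FORBES_FEMALE = (10.4, 14.2)
FORBES_MALE = (13.8, 16.9)


@dataclass(frozen=True)
class ForbesModel:
    """Log-linear Forbes model ``FFM = slope*ln(FM) + intercept + D``."""

    slope: float
    intercept: float
    translate_d: float = 0.0

    def __post_init__(self):
        s = _check_finite("slope", self.slope)
        _check_finite("intercept", self.intercept)
        _check_finite("translate_d", self.translate_d)
        if s <= 0:
            raise ValidationError(f"slope: must be > 0, got {s}")

    @classmethod
    def female(cls, translate_d: float = 0.0) -> "ForbesModel":
        return cls(*FORBES_FEMALE, translate_d)

    @classmethod
    def male(cls, translate_d: float = 0.0) -> "ForbesModel":
        return cls(*FORBES_MALE, translate_d)

    @classmethod
    def for_sex(cls, sex: SexCategory, translate_d: float = 0.0) -> "ForbesModel":
        return cls.female(translate_d) if sex is SexCategory.FEMALE \
            else cls.male(translate_d)

    def with_translate(self, translate_d: float) -> "ForbesModel":
        return replace(self, translate_d=translate_d)


def forbes_ffm(fm_kg: float, model: ForbesModel) -> float:
    """Forbes-family FFM (kg); defined only for FM > 0."""
    fm = _check_finite("fm_kg", fm_kg)
    if fm <= 0:
        raise DomainError(f"fm_kg: ln(FM) undefined for FM <= 0 (got {fm})")
    return model.slope * math.log(fm) + model.intercept + model.translate_d


def forbes_slope(fm_kg: float, model: ForbesModel) -> float:
    """Tangent slope d(FFM)/d(FM) = slope/FM; independent of the translate."""
    fm = _check_finite("fm_kg", fm_kg)
    if fm <= 0:
        raise DomainError(f"fm_kg: slope undefined for FM <= 0 (got {fm})")
    return model.slope / fm


def mass_index(mass_kg: float, height_cm: float) -> float:
    """Height-normalised index mass/(height in m)^2, kg/m^2 (FFMI or FMI)."""
    m = _check_finite("mass_kg", mass_kg)
    h = _check_finite("height_cm", height_cm)
    if m < 0:
        raise ValidationError(f"mass_kg: must be >= 0, got {m}")
    if h <= 0:
        raise ValidationError(f"height_cm: must be > 0, got {h}")
    return m / (h / 100.0) ** 2
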