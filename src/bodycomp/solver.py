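"""Mass-balance inversion and longitudinal fat-free-mass prediction.

Total body mass obeys the identity ``W = FM + FFM``.  Substituting a
cross-sectional FFM(FM) model turns measurement of W alone (plus
covariates) into a one-unknown root-finding problem for FM; solving it at
a baseline and a changed weight yields the longitudinal change in FFM.
Both the covariate polynomial and the translated Forbes curve are
supported, along with the mean +/- SD error summaries used to benchmark
such predictions against measured body composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (AmbiguousRootError, DomainError, InfeasibleMassError,
                     ValidationError)
from .models import (ForbesModel, SexCategory, SubjectCovariates, forbes_ffm,
                     nhanes_ffm)
from .registry import get_coefficients
from .models import evaluate_polynomial

#: Absolute tolerance (kg) of every bracketed root search.  Chosen so that
#: two-decimal printed values are reproduced independent of solver path.
ROOT_XTOL_KG = 1e-10

_MONOTONE_SAMPLES = 512


@dataclass(frozen=True)
class WeightChangeScenario:
    """A baseline total body mass and a weight change (negative = loss)."""

    baseline_total_kg: float
    delta_total_kg: float
    cov: SubjectCovariates

    def __post_init__(self):
        if not (self.baseline_total_kg > 0):
            raise ValidationError(
                f"baseline_total_kg: must be > 0, got {self.baseline_total_kg}")
        if not (self.baseline_total_kg + self.delta_total_kg > 0):
            raise ValidationError(
                "delta_total_kg: final total mass "
                f"{self.baseline_total_kg + self.delta_total_kg} is not > 0")

    @property
    def final_total_kg(self) -> float:
        return self.baseline_total_kg + self.delta_total_kg


@dataclass(frozen=True)
class CompositionChange:
    """Baseline/final body composition and the implied changes (kg)."""

    fm_baseline_kg: float
    fm_final_kg: float
    ffm_baseline_kg: float
    ffm_final_kg: float

    @property
    def delta_fm_kg(self) -> float:
        return self.fm_final_kg - self.fm_baseline_kg

    @property
    def delta_ffm_kg(self) -> float:
        return self.ffm_final_kg - self.ffm_baseline_kg

    @property
    def delta_total_kg(self) -> float:
        return self.delta_fm_kg + self.delta_ffm_kg


@dataclass(frozen=True)
class ErrorSummary:
    """Mean and sample SD (n-1 denominator) of predicted - measured."""

    mean_error_kg: float
    sd_error_kg: float
    n: int


def zero_fat_ffm(cov: SubjectCovariates,
                 registry_variant: str | None = None) -> float:
    """FFM at FM = 0: the lower bound on feasible total body mass."""
    return nhanes_ffm(0.0, cov, registry_variant)


def solve_fm(total_kg: float, cov: SubjectCovariates,
             registry_variant: str | None = None, *,
             coefficients=None) -> float:
    """Invert ``W = FM + FFM(FM; cov)`` for FM by bracketed root search.

    The total-mass function ``g(F) = F + FFM(F)`` is sampled at 512 points
    on [0, W].  The physiological solution branch is the initial strictly
    increasing segment of g (for the shipped male rows the negative quartic
    makes g turn over near FM ~ 90 kg at tall stature; beyond that point an
    added kilogram of body mass would have to destroy more than a kilogram
    of lean tissue, i.e. the polynomial has left its fitted band).  A root
    on that branch is unique and returned.  If the branch contains no root,
    any roots beyond it are located and reported in an
    :class:`AmbiguousRootError` rather than silently picking one.

    Parameters
    ----------
    coefficients : PolynomialCoefficients, optional
        Expert hook: solve against an explicit coefficient row instead of
        the registry (coefficient editing is a data change, not a code
        change).

    Raises
    ------
    InfeasibleMassError
        If ``total_kg`` does not exceed the zero-fat FFM bound (no
        non-negative-fat solution exists), or no root lies in [0, W].
    AmbiguousRootError
        If the only roots lie beyond the increasing branch of g
        (pathological covariates or coefficient rows).
    """
    if not (isinstance(total_kg, (int, float)) and math.isfinite(total_kg)
            and total_kg > 0):
        raise ValidationError(f"total_kg: must be a positive finite number, "
                              f"got {total_kg!r}")
    coeffs = coefficients if coefficients is not None else \
        get_coefficients(cov.race, cov.sex, registry_variant)
    A, H = cov.age_y, cov.height_cm

    def g(F):
        return F + evaluate_polynomial(coeffs, F, A, H)

    ffm0 = g(0.0)
    if total_kg <= ffm0:
        raise InfeasibleMassError(
            f"total_kg={total_kg} kg does not exceed the zero-fat FFM bound "
            f"{ffm0:.4f} kg for these covariates; no non-negative-fat "
            "solution exists", zero_fat_ffm_kg=ffm0)

    grid = np.linspace(0.0, total_kg, _MONOTONE_SAMPLES + 1)
    gv = grid + evaluate_polynomial(coeffs, grid, A, H)
    h = gv - total_kg
    increases = np.diff(gv) > 0
    mono_end = int(np.argmin(increases)) if not increases.all() \
        else len(increases)
    # root inside the increasing branch: unique by monotonicity
    branch_changes = np.nonzero(np.diff(np.sign(h[:mono_end + 1])) != 0)[0]
    if branch_changes.size:
        i = int(branch_changes[0])
        return brentq(lambda F: g(F) - total_kg, grid[i], grid[i + 1],
                      xtol=ROOT_XTOL_KG)
    if mono_end == len(increases):
        raise InfeasibleMassError(
            f"no solution with non-negative lean mass: g({total_kg}) = "
            f"{gv[-1]:.4f} < {total_kg}", zero_fat_ffm_kg=ffm0)
    tail_changes = np.nonzero(np.diff(np.sign(h)) != 0)[0]
    roots = [brentq(lambda F: g(F) - total_kg, grid[i], grid[i + 1],
                    xtol=ROOT_XTOL_KG) for i in tail_changes]
    if roots:
        raise AmbiguousRootError(
            "no root on the increasing branch of the total-mass function "
            f"g(F) (branch ends near F = {grid[mono_end]:.2f} kg); roots "
            f"beyond it: {roots}", roots=roots)
    raise InfeasibleMassError(
        f"no solution with non-negative lean mass on [0, {total_kg}]",
        zero_fat_ffm_kg=ffm0)


def delta_ffm_nhanes(scenario: WeightChangeScenario,
                     registry_variant: str | None = None) -> CompositionChange:
    """Longitudinal composition change predicted by the covariate polynomial.

    FM is solved at the baseline and final total masses with identical
    covariates (age and height are frozen at baseline over the study
    interval); FFM follows from the mass-balance identity, so
    ``delta_fm + delta_ffm = delta_total`` exactly.
    """
    fm_b = solve_fm(scenario.baseline_total_kg, scenario.cov, registry_variant)
    fm_f = solve_fm(scenario.final_total_kg, scenario.cov, registry_variant)
    return CompositionChange(
        fm_baseline_kg=fm_b,
        fm_final_kg=fm_f,
        ffm_baseline_kg=scenario.baseline_total_kg - fm_b,
        ffm_final_kg=scenario.final_total_kg - fm_f,
    )


def calibrate_forbes_d(fm_baseline_kg: float, ffm_baseline_kg: float,
                       sex: SexCategory) -> float:
    """Translate D making the sex's Forbes curve pass through the baseline.

    ``D = FFM_b - slope*ln(FM_b) - intercept``; each individual simulation
    travels this vertically shifted member of the Forbes family.
    """
    if not (fm_baseline_kg > 0):
        raise DomainError(
            f"fm_baseline_kg: must be > 0 for the Forbes model, "
            f"got {fm_baseline_kg}")
    base = ForbesModel.for_sex(sex)
    return ffm_baseline_kg - base.slope * math.log(fm_baseline_kg) \
        - base.intercept


def delta_ffm_forbes(fm_baseline_kg: float, ffm_baseline_kg: float,
                     delta_total_kg: float,
                     sex: SexCategory) -> CompositionChange:
    """Composition change along the translate-calibrated Forbes curve.

    Calibrates D through the measured baseline composition, then solves
    ``F + slope*ln(F) + intercept + D = W_final`` for the final fat mass.
    Because parallel translates share secant slopes, the predicted change
    in FFM is independent of any vertical shift of the baseline point.
    """
    d = calibrate_forbes_d(fm_baseline_kg, ffm_baseline_kg, sex)
    model = ForbesModel.for_sex(sex, translate_d=d)
    w_final = fm_baseline_kg + ffm_baseline_kg + delta_total_kg

    def h(F):
        return F + model.slope * math.log(F) + model.intercept \
            + model.translate_d - w_final

    lo = 1e-12
    if h(lo) >= 0:
        raise InfeasibleMassError(
            f"final total mass {w_final} kg admits no root with FM > 0 on "
            "the translated Forbes curve", zero_fat_ffm_kg=float("-inf"))
    hi = max(fm_baseline_kg, w_final, 1.0)
    while h(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise InfeasibleMassError(
                "no finite root for the translated Forbes curve",
                zero_fat_ffm_kg=float("-inf"))
    fm_f = brentq(h, lo, hi, xtol=ROOT_XTOL_KG)
    return CompositionChange(
        fm_baseline_kg=fm_baseline_kg,
        fm_final_kg=fm_f,
        ffm_baseline_kg=ffm_baseline_kg,
        ffm_final_kg=forbes_ffm(fm_f, model),
    )


def summarize_errors(measured: Sequence[float],
                     predicted: Sequence[float]) -> ErrorSummary:
    """Mean +/- sample SD of (predicted - measured), benchmark-table style.

    The sign convention is predicted minus measured; with a single pair the
    sample SD is reported as 0.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ValidationError(
            f"measured/predicted: need equal-length 1-D sequences, got "
            f"shapes {m.shape} and {p.shape}")
    if m.size == 0:
        raise ValidationError("measured/predicted: sequences are empty")
    err = p - m
    sd = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
    return ErrorSummary(mean_error_kg=float(np.mean(err)), sd_error_kg=sd,
                        n=int(err.size))


@dataclass(frozen=True)
class FollowUpRecord:
    """Measured baseline and final body composition for one subject."""

    id: str
    cov: SubjectCovariates
    fm_baseline_kg: float
    ffm_baseline_kg: float
    fm_final_kg: float
    ffm_final_kg: float

    @property
    def baseline_total_kg(self) -> float:
        return self.fm_baseline_kg + self.ffm_baseline_kg

    @property
    def final_total_kg(self) -> float:
        return self.fm_final_kg + self.ffm_final_kg


def evaluate_models(records: Sequence[FollowUpRecord],
                    registry_variant: str | None = None
                    ) -> dict[str, ErrorSummary]:
    """Benchmark both model families against measured follow-up data.

    For each subject, predicted baseline/final FM come from inverting the
    mass-balance identity at the measured total masses (covariate
    polynomial, and the untranslated sex-specific Forbes curve); the
    predicted change in FFM additionally uses the translate-calibrated
    Forbes curve through the measured baseline composition.  Returns
    mean-error summaries keyed ``{model}_{quantity}``.
    """
    if len(records) == 0:
        raise ValidationError("records: empty follow-up cohort")
    meas: dict[str, list[float]] = {k: [] for k in (
        "fm_baseline", "fm_final", "delta_ffm")}
    pred: dict[str, list[float]] = {k: [] for k in (
        "nhanes_fm_baseline", "nhanes_fm_final", "nhanes_delta_ffm",
        "forbes_fm_baseline", "forbes_fm_final", "forbes_delta_ffm")}
    for rec in records:
        scen = WeightChangeScenario(
            rec.baseline_total_kg,
            rec.final_total_kg - rec.baseline_total_kg, rec.cov)
        nh = delta_ffm_nhanes(scen, registry_variant)
        fb_base = ForbesModel.for_sex(rec.cov.sex)
        fo_b = _solve_forbes_fm(rec.baseline_total_kg, fb_base)
        fo_f = _solve_forbes_fm(rec.final_total_kg, fb_base)
        fo = delta_ffm_forbes(rec.fm_baseline_kg, rec.ffm_baseline_kg,
                              scen.delta_total_kg, rec.cov.sex)
        meas["fm_baseline"].append(rec.fm_baseline_kg)
        meas["fm_final"].append(rec.fm_final_kg)
        meas["delta_ffm"].append(rec.ffm_final_kg - rec.ffm_baseline_kg)
        pred["nhanes_fm_baseline"].append(nh.fm_baseline_kg)
        pred["nhanes_fm_final"].append(nh.fm_final_kg)
        pred["nhanes_delta_ffm"].append(nh.delta_ffm_kg)
        pred["forbes_fm_baseline"].append(fo_b)
        pred["forbes_fm_final"].append(fo_f)
        pred["forbes_delta_ffm"].append(fo.delta_ffm_kg)
    out = {}
    for key, values in pred.items():
        quantity = key.split("_", 1)[1]
        out[key] = summarize_errors(meas[quantity], values)
    return out


def _solve_forbes_fm(total_kg: float, model: ForbesModel) -> float:
    """Fat mass solving ``F + forbes_ffm(F) = W`` on the given curve."""

    def h(F):
        return F + model.slope * math.log(F) + model.intercept \
            + model.translate_d - total_kg

    lo = 1e-12
    if h(lo) >= 0:
        raise InfeasibleMassError(
            f"total_kg={total_kg} admits no FM > 0 on the Forbes curve",
            zero_fat_ffm_kg=float("-inf"))
    hi = max(total_kg, 1.0)
    while h(hi) < 0:
        hi *= 2.0
    return brentq(h, lo, hi, xtol=ROOT_XTOL_KG)
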