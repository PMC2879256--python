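"""Synthetic cross-sectional cohorts and per-group polynomial refitting.

The generator emulates the statistical structure the regression assumes:
for each (race, sex) group it draws age uniformly, height from a truncated
normal matched to the survey's sex-specific moments, fat mass from a
moment-matched gamma (right-skewed, positive), and sets
``FFM = polynomial(FM; A, H) + N(0, noise_sd)``.  Fitting is ordinary
least squares of FFM on the fixed 12-term basis, carried out independently
per group, with normal-theory standard errors and p-values and a
significance screen at the selection threshold P < 0.001.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import FitError, ValidationError
from .models import (AGE_RANGE_Y, BASIS_TERMS, HEIGHT_RANGE_CM, BodyState,
                     PolynomialCoefficients, RaceGroup, SexCategory,
                     SubjectCovariates, evaluate_polynomial, monomials)
from .registry import get_coefficients

#: Sex-specific anthropometry defaults (survey moments): height mean/SD in
#: cm, fat-mass mean/SD in kg.
HEIGHT_MEAN_SD_CM = {SexCategory.MALE: (174.3, 7.9),
                     SexCategory.FEMALE: (160.6, 7.2)}
FM_MEAN_SD_KG = {SexCategory.MALE: (24.2, 10.4),
                 SexCategory.FEMALE: (30.6, 12.3)}


@dataclass(frozen=True)
class CohortRecord:
    """One cross-sectional observation (synthetic or user-supplied)."""

    id: str
    sex: SexCategory
    race: RaceGroup
    age_y: float
    height_cm: float
    fm_kg: float
    ffm_kg: float

    def __post_init__(self):
        # delegates range/positivity checks to the shared domain types
        self.covariates
        self.body_state

    @property
    def covariates(self) -> SubjectCovariates:
        return SubjectCovariates(self.age_y, self.height_cm, self.sex,
                                 self.race)

    @property
    def body_state(self) -> BodyState:
        return BodyState(self.fm_kg, self.ffm_kg)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for the synthetic cohort generator."""

    n_per_group: int = 2000
    age_range_y: tuple[float, float] = (18.0, 85.0)
    height_mean_sd_cm: Mapping[SexCategory, tuple[float, float]] = field(
        default_factory=lambda: dict(HEIGHT_MEAN_SD_CM))
    fm_mean_sd_kg: Mapping[SexCategory, tuple[float, float]] = field(
        default_factory=lambda: dict(FM_MEAN_SD_KG))
    noise_sd_kg: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 12:
            raise ValidationError(
                f"n_per_group: need more rows than the 12 basis terms, "
                f"got {self.n_per_group}")
        if self.noise_sd_kg < 0:
            raise ValidationError(
                f"noise_sd_kg: must be >= 0, got {self.noise_sd_kg}")
        lo, hi = self.age_range_y
        if not (AGE_RANGE_Y[0] <= lo < hi <= AGE_RANGE_Y[1]):
            raise ValidationError(
                f"age_range_y: {self.age_range_y} not inside {AGE_RANGE_Y}")


def _truncated_normal(rng, mean, sd, lo, hi, n):
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: SyntheticCohortSpec,
                    registry_variant: str | None = None
                    ) -> list[CohortRecord]:
    """Draw a synthetic cohort whose FFM follows the selected registry.

    Reproducible for a fixed ``spec.seed``; with ``noise_sd_kg = 0`` every
    record satisfies ``ffm = polynomial(fm; cov)`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CohortRecord] = []
    for race, sex in itertools.product(RaceGroup, SexCategory):
        n = spec.n_per_group
        coeffs = get_coefficients(race, sex, registry_variant)
        age = rng.uniform(*spec.age_range_y, n)
        hm, hs = spec.height_mean_sd_cm[sex]
        height = _truncated_normal(rng, hm, hs, *HEIGHT_RANGE_CM, n)
        fmean, fsd = spec.fm_mean_sd_kg[sex]
        shape = (fmean / fsd) ** 2
        scale = fsd**2 / fmean
        fm = rng.gamma(shape, scale, n)
        ffm = evaluate_polynomial(coeffs, fm, age, height)
        if spec.noise_sd_kg > 0:
            ffm = ffm + rng.normal(0.0, spec.noise_sd_kg, n)
        # redraw the (vanishingly rare) records with non-positive lean mass
        bad = ffm <= 0
        while np.any(bad):
            k = int(bad.sum())
            fm[bad] = rng.gamma(shape, scale, k)
            ffm[bad] = (evaluate_polynomial(coeffs, fm[bad], age[bad],
                                            height[bad])
                        + rng.normal(0.0, spec.noise_sd_kg, k))
            bad = ffm <= 0
        for i in range(n):
            records.append(CohortRecord(
                id=f"{race.value}-{sex.value}-{i:05d}",
                sex=sex, race=race,
                age_y=float(age[i]), height_cm=float(height[i]),
                fm_kg=float(fm[i]), ffm_kg=float(ffm[i])))
    return records


def _single_group(records: Sequence[CohortRecord]
                  ) -> tuple[RaceGroup, SexCategory]:
    if len(records) == 0:
        raise ValidationError("records: empty cohort")
    groups = {(r.race, r.sex) for r in records}
    if len(groups) != 1:
        raise ValidationError(
            "records: mixed (race, sex) groups "
            f"{sorted((r.value, s.value) for r, s in groups)}; groups are "
            "fitted separately")
    return next(iter(groups))


def build_design_matrix(records: Sequence[CohortRecord]) -> np.ndarray:
    """n x 12 design matrix with columns in ``BASIS_TERMS`` order."""
    _single_group(records)
    F = np.array([r.fm_kg for r in records])
    A = np.array([r.age_y for r in records])
    H = np.array([r.height_cm for r in records])
    return monomials(F, A, H)


@dataclass(frozen=True)
class FitResult:
    """Per-group OLS fit of FFM on the 12-term basis."""

    group: tuple[RaceGroup, SexCategory]
    coefficients: PolynomialCoefficients
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    n: int


def fit_group(records: Sequence[CohortRecord]) -> FitResult:
    """Ordinary least squares of FFM on the fixed basis for one group.

    The design is column-scaled to unit root-mean-square before the fit
    (the quartic basis spans ~8 orders of magnitude) and the estimates are
    scaled back; p-values and R^2 are invariant under this rescaling.
    """
    group = _single_group(records)
    if len(records) <= len(BASIS_TERMS):
        raise ValidationError(
            f"records: need n > {len(BASIS_TERMS)} rows, got {len(records)}")
    X = build_design_matrix(records)
    y = np.array([r.ffm_kg for r in records])
    scale = np.sqrt(np.mean(X**2, axis=0))
    if np.any(scale == 0):
        zero = [BASIS_TERMS[i] for i in np.nonzero(scale == 0)[0]]
        raise FitError(f"design matrix: all-zero columns {zero}")
    Xs = X / scale
    rank = np.linalg.matrix_rank(Xs)
    if rank < len(BASIS_TERMS):
        _, r = np.linalg.qr(Xs)
        diag = np.abs(np.diag(r))
        collinear = [BASIS_TERMS[i] for i in
                     np.nonzero(diag < 1e-10 * diag.max())[0]]
        raise FitError(
            f"design matrix is rank deficient (rank {rank} < "
            f"{len(BASIS_TERMS)}); collinear columns: {collinear}")
    res = sm.OLS(y, Xs).fit()
    params = res.params / scale
    bse = res.bse / scale
    return FitResult(
        group=group,
        coefficients=PolynomialCoefficients(dict(zip(BASIS_TERMS, params))),
        standard_errors=dict(zip(BASIS_TERMS, bse)),
        p_values=dict(zip(BASIS_TERMS, res.pvalues)),
        r_squared=float(res.rsquared),
        n=len(records),
    )


def screen_terms(fit: FitResult, alpha: float = 0.001) -> list[str]:
    """Terms with p < alpha, mirroring the P < 0.001 selection threshold."""
    return [t for t in BASIS_TERMS if fit.p_values[t] < alpha]


def backward_eliminate(records: Sequence[CohortRecord],
                       alpha: float = 0.001,
                       keep: tuple[str, ...] = ("1",)
                       ) -> tuple[list[str], FitResult]:
    """Iteratively drop the least significant term until all p < alpha.

    The intercept is retained throughout by default.  Returns the retained
    term list and a :class:`FitResult` whose dropped coefficients are zero
    with NaN standard errors/p-values.
    """
    group = _single_group(records)
    X_full = build_design_matrix(records)
    y = np.array([r.ffm_kg for r in records])
    terms = list(BASIS_TERMS)
    while True:
        idx = [BASIS_TERMS.index(t) for t in terms]
        X = X_full[:, idx]
        scale = np.sqrt(np.mean(X**2, axis=0))
        res = sm.OLS(y, X / scale).fit()
        droppable = [(res.pvalues[i], t) for i, t in enumerate(terms)
                     if t not in keep]
        worst_p, worst_t = max(droppable) if droppable else (0.0, None)
        if worst_t is None or worst_p < alpha:
            params = res.params / scale
            bse = res.bse / scale
            coeffs = {t: 0.0 for t in BASIS_TERMS}
            se = {t: float("nan") for t in BASIS_TERMS}
            pv = {t: float("nan") for t in BASIS_TERMS}
            for i, t in enumerate(terms):
                coeffs[t], se[t], pv[t] = params[i], bse[i], res.pvalues[i]
            return terms, FitResult(
                group=group,
                coefficients=PolynomialCoefficients(coeffs),
                standard_errors=se, p_values=pv,
                r_squared=float(res.rsquared), n=len(records))
        terms.remove(worst_t)
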