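"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities along paths the
implementation does not use: a name-driven term-by-term polynomial sum and
a plain 200-iteration bisection root finder.
"""

import itertools

import numpy as np
import pytest

import bodycomp as bc

#: Physiological covariate grid used by property tests (corners suffice for
#: the monotonicity/positivity claims because the polynomial is linear in A
#: and H at fixed F).
GRID_AGES = (18.0, 50.0, 85.0)
GRID_HEIGHTS = (140.0, 170.0, 200.0)
ALL_GROUPS = tuple(itertools.product(bc.RaceGroup, bc.SexCategory))


@pytest.fixture
def aa_female_34_165():
    """Covariates of the published algebraic-inversion example."""
    return bc.SubjectCovariates(34.0, 165.0, bc.SexCategory.FEMALE,
                                bc.RaceGroup.AA)


def oracle_ffm(coeffs, F, A, H):
    """Term-by-term polynomial sum keyed by basis-term names.

    Independent of the implementation's stacked-monomial matrix product.
    """
    mono = {
        "1": 1.0, "F": F, "A": A, "H": H, "FA": F * A, "FH": F * H,
        "F2": F * F, "F2A": F * F * A, "F3": F**3, "F4": F**4,
        "F2H": F * F * H, "F3H": F**3 * H,
    }
    assert set(mono) == set(bc.BASIS_TERMS)
    return sum(coeffs[t] * mono[t] for t in bc.BASIS_TERMS)


def bisect_root(fn, lo, hi, iters=200):
    """Plain bisection; fn(lo) and fn(hi) must differ in sign."""
    flo = fn(lo)
    assert flo * fn(hi) < 0, "bisection oracle: endpoints do not bracket"
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (fn(mid) < 0) == (flo < 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def random_covariates(rng):
    """Draw covariates from realistic sex-specific anthropometry."""
    race, sex = ALL_GROUPS[rng.integers(len(ALL_GROUPS))]
    mean, sd = {bc.SexCategory.MALE: (174.3, 7.9),
                bc.SexCategory.FEMALE: (160.6, 7.2)}[sex]
    height = float(np.clip(rng.normal(mean, sd), 140.0, 200.0))
    age = float(rng.uniform(18.0, 85.0))
    return bc.SubjectCovariates(age, height, sex, race)


def random_fat_mass(rng, sex):
    """Sex-specific moment-matched gamma draw, clipped to (0.1, 80]."""
    mean, sd = {bc.SexCategory.MALE: (24.2, 10.4),
                bc.SexCategory.FEMALE: (30.6, 12.3)}[sex]
    fm = rng.gamma((mean / sd) ** 2, sd**2 / mean)
    return float(np.clip(fm, 0.1, 80.0))
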