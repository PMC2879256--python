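#!/usr/bin/env python
"""Reproducible construction of the 'corrected' AA-female coefficient row.

The transcribed AA-female polynomial row cannot reproduce the published
algebraic-inversion example (FM = 27.75 kg at W = 75 kg and FM = 20.74 kg
at W = 65 kg for an African American female, age 34 y, height 165 cm), and
its 0.3*H coefficient both breaks the cross-row pattern (every other row
has 0.7*H) and makes the zero-fat fat-free mass negative at short stature.

This script rebuilds the shipped correction from first principles:

1. start from the transcribed row with the pattern-consistent 0.7*H
   restored (this fixes the zero-fat behaviour without touching any
   F-bearing term);
2. apply the minimum-relative-norm adjustment of the nine F-bearing
   coefficients subject to the two linear interpolation constraints
   FFM(27.75; 34, 165) = 47.25 and FFM(20.74; 34, 165) = 44.26.

Step 2 is a 2-constraint weighted least-norm problem (the polynomial is
linear in its coefficients): minimise sum((dc_i / c_i)^2) subject to
M (c + dc) = y, solved in closed form as dc = W M' (M W M')^-1 r with
W = diag(c_i^2).

Run from the repository root; prints the corrected row and verifies it
against the registry shipped in the package.
"""

import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import bodycomp as bc  # noqa: E402
from bodycomp.models import monomials  # noqa: E402
from bodycomp.registry import get_coefficients  # noqa: E402

AGE, HEIGHT = 34.0, 165.0
CONSTRAINTS = [(27.75, 75.0 - 27.75), (20.74, 65.0 - 20.74)]  # (FM, FFM)
F_BEARING = [i for i, t in enumerate(bc.BASIS_TERMS) if "F" in t]


def derive():
    base = get_coefficients(bc.RaceGroup.AA, bc.SexCategory.FEMALE,
                            "normalized").as_array()
    base[bc.BASIS_TERMS.index("H")] = 0.7  # cross-row pattern restored
    m = np.array([monomials(fm, AGE, HEIGHT) for fm, _ in CONSTRAINTS])
    r = np.array([ffm for _, ffm in CONSTRAINTS]) - m @ base
    w = np.diag(base[F_BEARING] ** 2)
    mi = m[:, F_BEARING]
    dc = w @ mi.T @ np.linalg.solve(mi @ w @ mi.T, r)
    corrected = base.copy()
    corrected[F_BEARING] += dc
    return corrected


def main() -> int:
    corrected = derive()
    shipped = get_coefficients(bc.RaceGroup.AA, bc.SexCategory.FEMALE,
                               "corrected").as_array()
    print("corrected AA-female row:")
    for term, value in zip(bc.BASIS_TERMS, corrected):
        print(f"  {term:>4}  {value!r}")
    m = np.array([monomials(fm, AGE, HEIGHT) for fm, _ in CONSTRAINTS])
    print("interpolation check (target 47.25, 44.26):", m @ corrected)
    if np.allclose(corrected, shipped, rtol=0, atol=1e-12):
        print("matches the registry shipped with the package")
        return 0
    print("MISMATCH with the shipped registry", file=sys.stderr)
    return 1


if __name__ == "__main__":
    raise SystemExit(main())
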