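"""Coefficient registry for the NHANES-derived polynomial class.

The registry ships as a versioned plain-text table
(``data/coefficients_v1.tsv``) holding one coefficient per line, keyed by
variant, (race, sex) group and basis term.  Three variants are provided:

``printed``
    A literal transcription of the published table, including its two
    typographical anomalies read literally: the NAA-female row carries an
    extra ``-0.002*A`` where every other row has ``-0.002*F*A`` (so its
    ``A`` coefficient is -0.042 and ``FA`` is absent), and the AA-male row
    ends in ``-0.000002*F*H`` where every other row has
    ``-0.000002*F^3*H`` (so its ``FH`` coefficient is -0.010002 and
    ``F3H`` is absent).

``normalized``
    The two anomalous terms replaced by their pattern-consistent ``F*A``
    and ``F^3*H`` forms; otherwise identical to ``printed``.

``corrected``  (package default)
    Identical to ``normalized`` except for the AA-female row, which as
    transcribed cannot reproduce the published algebraic-inversion example
    (FM = 27.75 kg at W = 75 kg and FM = 20.74 kg at W = 65 kg for an AA
    female, age 34 y, height 165 cm) and has a negative zero-fat intercept
    at short stature, contradicting the model's own nonnegativity claim.
    The corrected row restores the cross-row ``0.7*H`` pattern and applies
    the minimum-relative-norm adjustment of the nine F-bearing
    coefficients that makes the row interpolate both published inversion
    points exactly (see ``scripts/derive_corrected_coefficients.py`` for
    the reproducible construction).

Editing coefficients is a data change: point ``load_registry_table`` at an
alternative file to swap in different rows without touching any code.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

from .errors import ConfigurationError, ValidationError
from .models import BASIS_TERMS, PolynomialCoefficients, RaceGroup, SexCategory

FORMAT_VERSION = "v1"
VARIANTS = ("printed", "normalized", "corrected")
DEFAULT_VARIANT = "corrected"

_HEADER = ("variant", "race", "sex", "term", "value")


@dataclass(frozen=True)
class CoefficientRegistry:
    """All four (race, sex) coefficient rows for one variant."""

    variant: str
    groups: Mapping[tuple[RaceGroup, SexCategory], PolynomialCoefficients]

    def __post_init__(self):
        expected = {(r, s) for r in RaceGroup for s in SexCategory}
        if set(self.groups) != expected:
            missing = expected - set(self.groups)
            raise ValidationError(
                f"registry variant {self.variant!r}: missing groups "
                f"{sorted((r.value, s.value) for r, s in missing)}")

    def coefficients(self, race: RaceGroup, sex: SexCategory
                     ) -> PolynomialCoefficients:
        return self.groups[(race, sex)]


def _default_path():
    return resources.files("bodycomp").joinpath("data/coefficients_v1.tsv")


def parse_registry_table(text: str) -> dict[str, CoefficientRegistry]:
    """Parse registry-table text into one registry per variant."""
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines or tuple(lines[0].split("\t")) != _HEADER:
        raise ConfigurationError(
            f"registry table: expected header {' '.join(_HEADER)}")
    raw: dict[str, dict[tuple[RaceGroup, SexCategory], dict[str, float]]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 5:
            raise ConfigurationError(f"registry table: malformed line {ln!r}")
        variant, race_s, sex_s, term, value_s = parts
        if term not in BASIS_TERMS:
            raise ConfigurationError(f"registry table: unknown term {term!r}")
        key = (RaceGroup(race_s), SexCategory(sex_s))
        raw.setdefault(variant, {}).setdefault(key, {})[term] = float(value_s)
    return {
        variant: CoefficientRegistry(
            variant,
            {key: PolynomialCoefficients(vals) for key, vals in groups.items()},
        )
        for variant, groups in raw.items()
    }


def dump_registry_table(registries: Mapping[str, CoefficientRegistry]) -> str:
    """Serialise registries back to the plain-text table format.

    Values are written with ``repr`` so that a load/dump/load cycle is
    bit-exact.
    """
    out = [f"# bodycomp coefficient registry format={FORMAT_VERSION}",
           "\t".join(_HEADER)]
    for variant in registries:
        reg = registries[variant]
        for race in RaceGroup:
            for sex in SexCategory:
                coeffs = reg.coefficients(race, sex)
                for term in BASIS_TERMS:
                    out.append("\t".join(
                        (variant, race.value, sex.value, term,
                         repr(coeffs[term]))))
    return "\n".join(out) + "\n"


@functools.lru_cache(maxsize=8)
def _load_all(path_str: str | None) -> dict[str, CoefficientRegistry]:
    if path_str is None:
        text = _default_path().read_text(encoding="utf-8")
    else:
        with open(path_str, "r", encoding="utf-8") as fh:
            text = fh.read()
    return parse_registry_table(text)


def load_registry_table(path=None) -> dict[str, CoefficientRegistry]:
    """Load every variant from the packaged (or a user-supplied) table."""
    return _load_all(None if path is None else str(path))


def load_registry(variant: str | None = None, path=None) -> CoefficientRegistry:
    """Load a single variant; ``None`` selects the package default."""
    variant = DEFAULT_VARIANT if variant is None else variant
    table = load_registry_table(path)
    if variant not in table:
        raise ConfigurationError(
            f"unknown registry variant {variant!r}; "
            f"available: {sorted(table)}")
    return table[variant]


def get_coefficients(race: RaceGroup, sex: SexCategory,
                     variant: str | None = None) -> PolynomialCoefficients:
    """Coefficient row for a (race, sex) group under the given variant."""
    return load_registry(variant).coefficients(race, sex)


def save_registry_table(registries: Mapping[str, CoefficientRegistry],
                        path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dump_registry_table(registries))
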