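"""Elemental formulas, monoisotopic masses and ppm arithmetic.

Glucosinolates are measured as deprotonated anions [M-H]- in negative-mode
electrospray, so the central quantity everywhere in this package is the
monoisotopic m/z of an anion formula.  Two conventions exist for anion m/z:
with or without the mass of the extra electron.  The include-electron
convention is the default because it is the one that reproduces reference
values such as HSO4- at m/z 96.9601 and the glucosyl-sulfated core
[C7H11O9NS2]- at m/z 316.9881 to four decimal places.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS

__all__ = [
    "ElementalFormula",
    "FormulaError",
    "MassSplit",
    "parse_formula",
    "monoisotopic_mass",
    "anion_mz",
    "ppm_error",
    "within_tol",
    "split_mass",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown elements."""


@dataclass(frozen=True)
class ElementalFormula(Mapping[str, int]):
    """Immutable element -> count map with Hill-order string form.

    Counts are non-negative integers and at least one must be positive.
    Formulas add element-wise with ``+`` and scale with ``*``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if n < 0:
                raise FormulaError(f"negative count for element {el!r}: {n}")
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {el!r}")
        if not clean:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", dict(clean))

    # Mapping interface
    def __getitem__(self, el: str) -> int:
        return self.counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 1:
            raise FormulaError("formula multiplier must be a positive integer")
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def hill(self) -> str:
        """Canonical Hill-order string: C, H, then remaining alphabetical."""
        parts: list[str] = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-notation formula string such as ``"C7H11O9NS2"``.

    Raises :class:`FormulaError` naming the offending span on malformed
    input or an element missing from the atomic-mass table.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at {text[pos:m.start()]!r}"
            )
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Sum of per-atom monoisotopic masses in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.items()))


def anion_mz(
    formula: ElementalFormula | str,
    z: int = 1,
    include_electron: bool = True,
) -> float:
    """m/z of an anion whose formula is already the deprotonated species.

    With ``include_electron`` (default) each negative charge adds one
    electron mass: m/z = (M + z * m_e) / z.  The no-electron variant is
    exposed because some reference values (e.g. SO4- at 95.9517) follow it.
    """
    if z <= 0:
        raise ValueError(f"charge magnitude z must be positive, got {z}")
    mass = monoisotopic_mass(formula)
    if include_electron:
        mass += z * ELECTRON_MASS
    return mass / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def within_tol(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True when |ppm error| does not exceed ``tol_ppm``."""
    return abs(ppm_error(observed, theoretical)) <= tol_ppm


@dataclass(frozen=True)
class MassSplit:
    """Integer/decimal decomposition of a non-negative mass."""

    source: float
    integer_part: int
    decimal_part: float


def split_mass(mass: float) -> MassSplit:
    """Split ``mass`` into floor integer part and fractional remainder.

    Negative masses are rejected: callers subtracting a core mass must
    pre-filter negative residuals.
    """
    if mass < 0:
        raise ValueError(f"cannot split a negative mass: {mass}")
    integer = math.floor(mass)
    return MassSplit(source=mass, integer_part=integer, decimal_part=mass - integer)
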