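"""Elemental-formula arithmetic and monoisotopic ion m/z calculation.

Everything downstream (species masses, fragment predictions, MRM/PIS
method values) is built on the two primitives here: an element->count
map with additive mass, and a singly charged adduct shift.

Atomic masses are hard-coded to published monoisotopic values of the
most abundant isotope (6+ decimal places) so results are bit-stable
across environments.  All ions in scope are +1 cations; the electron
mass is subtracted in the adduct shift, which is physically correct
even though some instrument-software "exact masses" in the literature
omit it (a 0.55 mDa effect).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "Adduct",
    "ElementalFormula",
    "FormulaError",
    "PROTON",
    "SODIUM",
    "ion_mz",
    "monoisotopic_mass",
    "parse_formula",
]

#: Monoisotopic masses of the most abundant isotope, in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "Na": 22.98976928,
}

#: Electron rest mass in Da; subtracted once per positive charge.
ELECTRON_MASS = 0.00054857990907

# Hill-order output: C first, H second, then remaining symbols alphabetically.
_HILL_ORDER = ("C", "H", "N", "Na", "O", "P")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparsable formulas or invalid formula arithmetic."""


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element->count map with element-wise mass arithmetic.

    Counts are non-negative integers; subtraction that would drive any
    count negative raises :class:`FormulaError` (a fragment cannot lose
    atoms its precursor does not have).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {element} must be a non-negative integer, got {n!r}")
            if n:
                clean[element] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            remaining = merged.get(element, 0) - n
            if remaining < 0:
                raise FormulaError(
                    f"subtraction would give negative count for {element}: "
                    f"{merged.get(element, 0)} - {n}"
                )
            merged[element] = remaining
        return ElementalFormula(merged)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"multiplier must be a non-negative integer, got {k!r}")
        return ElementalFormula({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da."""
        return monoisotopic_mass(self)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Format in Hill notation (C, H, then alphabetical); parse round-trips."""
        parts = []
        for element in _HILL_ORDER:
            n = self.counts.get(element, 0)
            if n == 1:
                parts.append(element)
            elif n > 1:
                parts.append(f"{element}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style concatenated formula string, e.g. ``"C39H76NO8P"``.

    Repeated element tokens accumulate, so dot-free condensed formulas
    such as ``"H3PO4C2H4NHC6H10O5Na"`` (the sodiated glycated head
    group written out structurally) parse to the same composition as
    their Hill form.
    """
    text = text.strip()
    if not text:
        return ElementalFormula({})
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(text):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = match.group(1), match.group(2)
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass of a neutral composition, in Da."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts.items())


@dataclass(frozen=True)
class Adduct:
    """A singly charged positive-mode adduct.

    ``mass_shift`` is the m/z increment over the neutral monoisotopic
    mass: the attached cation's mass minus one electron.
    """

    name: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError("only singly charged ions are supported")


PROTON = Adduct("proton", MONOISOTOPIC_MASS["H"] - ELECTRON_MASS)
SODIUM = Adduct("sodium", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS)

_ADDUCTS = {
    "proton": PROTON,
    "h": PROTON,
    "+h": PROTON,
    "m+h": PROTON,
    "sodium": SODIUM,
    "na": SODIUM,
    "+na": SODIUM,
    "m+na": SODIUM,
}


def get_adduct(name: str | Adduct) -> Adduct:
    """Resolve an adduct by name ("proton"/"H" or "sodium"/"Na")."""
    if isinstance(name, Adduct):
        return name
    try:
        return _ADDUCTS[name.strip().lower().replace("[", "").replace("]", "").replace("+", "+")]
    except KeyError:
        raise ValueError(f"unknown adduct: {name!r} (expected proton/H or sodium/Na)") from None


def ion_mz(neutral: ElementalFormula, adduct: Adduct) -> float:
    """m/z of the [M+H]+ or [M+Na]+ ion of a neutral composition."""
    return monoisotopic_mass(neutral) + adduct.mass_shift


def cation_mz(ionic_formula: ElementalFormula) -> float:
    """m/z of a +1 cation whose formula already includes the charge carrier.

    E.g. the sodiated glycated head ion ``C8H18NO9PNa`` contains its Na;
    the only correction left is the missing electron.
    """
    return monoisotopic_mass(ionic_formula) - ELECTRON_MASS
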