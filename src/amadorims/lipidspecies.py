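"""PE and Amadori-PE molecular species: shorthand parsing, neutral
formulas, precursor m/z and the phospholipid-class mass catalog.

Species are modelled at the total-acyl-composition level (carbons:double
bonds, e.g. "34:1") because a triple quadrupole cannot distinguish
sn-positional isomers; an optional sn assignment is carried as metadata
only.  The glycated species add the Amadori increment of their sugar --
the sugar formula minus one water, C6H10O5 for glucose and C12H20O10
for lactose -- to the diacyl PE backbone.

The diacyl PE backbone formula for total composition T:D is
C(T+5) H(2T-2D+10) N O8 P: glycerophosphoethanolamine (C5H14NO6P) plus
two acyl chains totalling T carbons and D double bonds, minus two
waters of esterification.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chemcore import (
    Adduct,
    ElementalFormula,
    PROTON,
    SODIUM,
    ion_mz,
    parse_formula,
)

__all__ = [
    "AcylComposition",
    "AmadoriPESpecies",
    "SpeciesError",
    "SugarTag",
    "class_mass_catalog",
    "method_round",
    "neutral_formula",
    "parse_species",
    "precursor_mz",
]


class SpeciesError(ValueError):
    """Raised for malformed species shorthand or unsupported classes."""


_WATER = parse_formula("H2O")


@dataclass(frozen=True)
class AcylComposition:
    """Total acyl composition: carbons (T) and double bonds (D)."""

    total_carbons: int
    total_double_bonds: int
    #: optional (carbons, double bonds) per chain; metadata only
    sn_assignment: Optional[tuple[tuple[int, int], tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.total_carbons < 2:
            raise SpeciesError(f"total carbons must be >= 2, got {self.total_carbons}")
        if self.total_double_bonds < 0:
            raise SpeciesError("double-bond count cannot be negative")
        if self.total_double_bonds > self.total_carbons / 2:
            raise SpeciesError(
                f"{self.total_carbons}:{self.total_double_bonds} exceeds the "
                "maximum double-bond count for its chain length"
            )
        if self.sn_assignment is not None:
            c = sum(chain[0] for chain in self.sn_assignment)
            d = sum(chain[1] for chain in self.sn_assignment)
            if (c, d) != (self.total_carbons, self.total_double_bonds):
                raise SpeciesError(
                    f"sn assignment {self.sn_assignment} does not sum to "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )

    def __str__(self) -> str:
        return f"{self.total_carbons}:{self.total_double_bonds}"


class SugarTag(Enum):
    """Amadori sugar tag; the increment is the sugar minus one water."""

    NONE = "none"
    GLUCOSE = "glucose"
    LACTOSE = "lactose"

    @property
    def increment(self) -> ElementalFormula:
        return _SUGAR_INCREMENT[self]

    @property
    def class_prefix(self) -> str:
        return _SUGAR_PREFIX[self]


_SUGAR_INCREMENT = {
    SugarTag.NONE: ElementalFormula({}),
    SugarTag.GLUCOSE: parse_formula("C6H10O5"),
    SugarTag.LACTOSE: parse_formula("C12H20O10"),
}
_SUGAR_PREFIX = {SugarTag.NONE: "", SugarTag.GLUCOSE: "Glc-", SugarTag.LACTOSE: "Lac-"}
_PREFIX_SUGAR = {"": SugarTag.NONE, "glc": SugarTag.GLUCOSE, "lac": SugarTag.LACTOSE}


@dataclass(frozen=True)
class AmadoriPESpecies:
    """A diacyl PE species, optionally glycated with glucose or lactose."""

    acyl: AcylComposition
    sugar: SugarTag = SugarTag.NONE

    @property
    def lipid_class(self) -> str:
        return f"{self.sugar.class_prefix}PE"

    @property
    def display_name(self) -> str:
        """Name in the "36:2 Lac-PE" style."""
        return f"{self.acyl} {self.lipid_class}"

    def __str__(self) -> str:
        return self.display_name


_SPECIES_RE = re.compile(
    r"^\s*(?:(?P<cls1>(?:Glc-|Lac-)?PE)\s+(?P<cd1>\d+:\d+)"
    r"|(?P<cd2>\d+:\d+)\s+(?P<cls2>(?:Glc-|Lac-)?PE))\s*$",
    re.IGNORECASE,
)


def parse_species(text: str) -> AmadoriPESpecies:
    """Parse shorthand like ``"Lac-PE 36:2"`` or ``"36:2 Lac-PE"``."""
    match = _SPECIES_RE.match(text)
    if not match:
        raise SpeciesError(
            f"cannot parse species {text!r}; expected e.g. 'PE 34:1', "
            "'Glc-PE 36:2' or '36:2 Lac-PE'"
        )
    cls = (match.group("cls1") or match.group("cls2")).lower()
    cd = match.group("cd1") or match.group("cd2")
    prefix = cls[:-2].rstrip("-") if cls != "pe" else ""
    carbons, dbonds = (int(tok) for tok in cd.split(":"))
    return AmadoriPESpecies(AcylComposition(carbons, dbonds), _PREFIX_SUGAR[prefix])


def neutral_formula(species: AmadoriPESpecies) -> ElementalFormula:
    """Neutral elemental formula of a (glycated) diacyl PE species."""
    t, d = species.acyl.total_carbons, species.acyl.total_double_bonds
    backbone = ElementalFormula({"C": t + 5, "H": 2 * t - 2 * d + 10, "N": 1, "O": 8, "P": 1})
    return backbone + species.sugar.increment


def precursor_mz(species: AmadoriPESpecies, adduct: Adduct) -> float:
    """Exact precursor m/z of the species under the given +1 adduct."""
    return ion_mz(neutral_formula(species), adduct)


def method_round(mz: float, decimals: int = 1) -> float:
    """Round-half-up to the precision used in acquisition method tables."""
    scale = 10**decimals
    return int(mz * scale + 0.5) / scale


# --- class mass catalog -------------------------------------------------

def _class_formula(lipid_class: str, t: int, d: int) -> ElementalFormula:
    """Neutral formula of a diacyl/SM species of a supported class.

    PC is PE plus three methyls; PS is PE with serine (ethanolamine +
    CO2) as head.  SM uses a d18:1 sphingoid backbone, so its T:D count
    includes the 18:1 of sphingosine; SM(T:D) = C(T+5) H(2T-2D+13) N2 O6 P.
    """
    if lipid_class in ("PE", "Glc-PE", "Lac-PE"):
        sugar = {"PE": SugarTag.NONE, "Glc-PE": SugarTag.GLUCOSE, "Lac-PE": SugarTag.LACTOSE}[
            lipid_class
        ]
        return neutral_formula(AmadoriPESpecies(AcylComposition(t, d), sugar))
    if lipid_class == "PC":
        return ElementalFormula({"C": t + 8, "H": 2 * t - 2 * d + 16, "N": 1, "O": 8, "P": 1})
    if lipid_class == "PS":
        return ElementalFormula({"C": t + 6, "H": 2 * t - 2 * d + 10, "N": 1, "O": 10, "P": 1})
    if lipid_class == "SM":
        if t <= 18 or d < 1:
            raise SpeciesError(f"SM {t}:{d} is not representable on a d18:1 backbone")
        return ElementalFormula({"C": t + 5, "H": 2 * t - 2 * d + 13, "N": 2, "O": 6, "P": 1})
    raise SpeciesError(f"unsupported lipid class: {lipid_class!r}")


SUPPORTED_CLASSES = ("PE", "Glc-PE", "Lac-PE", "PC", "PS", "SM")

#: Compositions used throughout for the main milk species.
DEFAULT_COMPOSITIONS = ((34, 1), (36, 1), (36, 2), (36, 3))


def class_mass_catalog(
    classes: Sequence[str] = SUPPORTED_CLASSES,
    compositions: Iterable[tuple[int, int]] = DEFAULT_COMPOSITIONS,
) -> pd.DataFrame:
    """Theoretical [M+H]+ / [M+Na]+ table for spectrum annotation.

    Returns a DataFrame with columns ``species, lipid_class, composition,
    formula, neutral_mass, mz_H, mz_Na``, one row per (class, T:D).
    """
    compositions = list(compositions)
    rows = []
    for lipid_class in classes:
        if lipid_class not in SUPPORTED_CLASSES:
            raise SpeciesError(f"unsupported lipid class: {lipid_class!r}")
        for t, d in compositions:
            formula = _class_formula(lipid_class, t, d)
            mass = formula.mass
            rows.append(
                {
                    "species": f"{t}:{d} {lipid_class}",
                    "lipid_class": lipid_class,
                    "composition": f"{t}:{d}",
                    "formula": formula.hill(),
                    "neutral_mass": mass,
                    "mz_H": mass + PROTON.mass_shift,
                    "mz_Na": mass + SODIUM.mass_shift,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species", "lipid_class", "composition", "formula", "neutral_mass", "mz_H", "mz_Na"],
    )


def catalog_to_csv(catalog: pd.DataFrame) -> str:
    """Serialize a catalog deterministically (6 dp on masses)."""
    buf = io.StringIO()
    catalog.to_csv(buf, index=False, float_format="%.6f", lineterminator="\n")
    return buf.getvalue()
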