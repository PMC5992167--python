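"""CID product-ion prediction for Glc-PE / Lac-PE under [M+H]+ and [M+Na]+.

Two fragment families are modelled:

* ``dag_fragment`` -- neutral loss of the (glycated) polar head, leaving
  a diacylglycerol-type cation that retains both fatty acyls and the
  glycerol backbone.  Native PE produces the same ion by losing its
  phosphoethanolamine head (C2H8NO4P, 141.019094 Da), so it is NOT
  diagnostic for glycation.
* ``glycated_head`` -- in the presence of sodium, neutral loss of both
  acyls plus the glycerol backbone leaves the sodiated glycated head
  ion [H3PO4-CH2CH2-NH-sugar + Na]+: C8H18NO9PNa (glucose) or
  C14H28NO14PNa (lactose), plus its sequential water losses.  These
  ions are composition-invariant within a sugar class and are absent
  from native PE, which makes them the diagnostic Q3 masses for MRM
  and precursor-ion scanning.

Fragment intensities are not modelled; predictions are m/z, ionic
formula and annotation only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemcore import (
    Adduct,
    ElementalFormula,
    PROTON,
    SODIUM,
    cation_mz,
    parse_formula,
)
from .lipidspecies import AmadoriPESpecies, SugarTag, neutral_formula

__all__ = [
    "PHOSPHOETHANOLAMINE_HEAD",
    "ProductIon",
    "head_ion_formula",
    "head_ion_mz",
    "is_diagnostic",
    "predict_products",
]

#: Neutral phosphoethanolamine head lost in the DAG-fragment channel.
PHOSPHOETHANOLAMINE_HEAD = parse_formula("C2H8NO4P")

_WATER = parse_formula("H2O")

#: Number of sequential water losses observed from each sodiated head ion.
_N_WATER_LOSSES = {SugarTag.GLUCOSE: 2, SugarTag.LACTOSE: 1}

_DIAGNOSTIC_ANNOTATIONS = frozenset(
    {"glycated_head", "glycated_head_minus_1H2O", "glycated_head_minus_2H2O"}
)


@dataclass(frozen=True)
class ProductIon:
    """A predicted +1 product ion.

    ``formula`` is the ionic composition (it includes Na for sodiated
    ions and the extra proton for protonated ones); ``mz`` is its
    monoisotopic mass minus one electron.
    """

    mz: float
    formula: ElementalFormula
    annotation: str
    requires_adduct: str  # "proton" | "sodium" | "either"
    diagnostic: bool

    def __str__(self) -> str:
        return f"{self.annotation} {self.mz:.4f} ({self.formula})"


def head_ion_formula(sugar: SugarTag) -> ElementalFormula:
    """Ionic formula of the sodiated glycated head: H3PO4·C2H4·NH·sugar + Na."""
    if sugar is SugarTag.NONE:
        raise ValueError("native PE has no diagnostic glycated head ion")
    core = parse_formula("H3PO4") + parse_formula("C2H4") + parse_formula("NH")
    return core + sugar.increment + ElementalFormula({"Na": 1})


def head_ion_mz(sugar: SugarTag) -> float:
    """m/z of the sodiated glycated head ion; composition-independent.

    326.061 for glucose, 488.114 for lactose.
    """
    return cation_mz(head_ion_formula(sugar))


def _dag_fragment(species: AmadoriPESpecies, requires: str) -> ProductIon:
    # [M+H]+ minus the neutral glycated head (phosphoethanolamine + sugar).
    ionic = (
        neutral_formula(species)
        + ElementalFormula({"H": 1})
        - PHOSPHOETHANOLAMINE_HEAD
        - species.sugar.increment
    )
    return ProductIon(cation_mz(ionic), ionic, "dag_fragment", requires, diagnostic=False)


def predict_products(species: AmadoriPESpecies, adduct: Adduct) -> list[ProductIon]:
    """Predict the CID product ions of a species under the given adduct.

    Proton mode yields only the DAG fragment.  Sodium mode yields the
    sodiated glycated head ion, its water losses (two for glucose, one
    for lactose) and the DAG fragment, which is observed from sodiated
    precursors as well.  Native (unglycated) PE yields only the DAG
    fragment in either mode.
    """
    products = [_dag_fragment(species, "either")]
    if adduct.name == "sodium" and species.sugar is not SugarTag.NONE:
        head = head_ion_formula(species.sugar)
        products.append(
            ProductIon(cation_mz(head), head, "glycated_head", "sodium", diagnostic=True)
        )
        ionic = head
        for n in range(1, _N_WATER_LOSSES[species.sugar] + 1):
            ionic = ionic - _WATER
            products.append(
                ProductIon(
                    cation_mz(ionic),
                    ionic,
                    f"glycated_head_minus_{n}H2O",
                    "sodium",
                    diagnostic=True,
                )
            )
    return sorted(products, key=lambda ion: ion.mz, reverse=True)


def is_diagnostic(ion: ProductIon) -> bool:
    """True iff the ion is specific to glycated PE (the head-ion family).

    The DAG fragment is also generated by native PE through loss of its
    phosphate head group, so it is not diagnostic.
    """
    return ion.annotation in _DIAGNOSTIC_ANNOTATIONS
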