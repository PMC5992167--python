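"""MRM transition-table and precursor-ion-scan method generation.

An MRM transition pairs the sodiated precursor ([M+Na]+, Q1) of an
Amadori-PE species with its class-diagnostic sodiated head ion (Q3,
326.1 for Glc-PE, 488.1 for Lac-PE).  A PIS method fixes Q3 on the same
head ion and scans Q1 across the precursor range of the species catalog.
Method m/z values are rounded half-up to one decimal, the precision a
QQQ method editor uses.  Voltages (DP/EP/CE/CXP) are instrument tuning
values, shipped as YAML defaults and overridable per call.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .chemcore import SODIUM
from .fragmenter import head_ion_mz
from .lipidspecies import (
    AcylComposition,
    AmadoriPESpecies,
    SpeciesError,
    SugarTag,
    method_round,
    parse_species,
    precursor_mz,
)

__all__ = [
    "DEFAULT_MRM_SPECIES",
    "MRMTransition",
    "PISMethod",
    "build_mrm_table",
    "build_pis_method",
    "default_params",
    "export_method",
    "read_mrm_table",
]

#: The six quantified species, in method-table order.
DEFAULT_MRM_SPECIES: tuple[str, ...] = (
    "34:1 Glc-PE",
    "36:1 Glc-PE",
    "36:2 Glc-PE",
    "34:1 Lac-PE",
    "36:1 Lac-PE",
    "36:2 Lac-PE",
)

#: Compositions scanned in PIS mode (includes 36:3, seen but not in MRM).
DEFAULT_PIS_COMPOSITIONS: tuple[tuple[int, int], ...] = ((34, 1), (36, 1), (36, 2), (36, 3))


def default_params() -> dict:
    """Load the packaged default voltage configuration."""
    text = importlib.resources.files("amadorims").joinpath("data/mrm_params.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class MRMTransition:
    species: AmadoriPESpecies
    q1_mz: float
    q3_mz: float
    dp: int
    ep: int
    ce: int
    cxp: int

    @property
    def transition_id(self) -> str:
        return f"{self.species.display_name} {self.q1_mz:.1f}/{self.q3_mz:.1f}"

    def __post_init__(self) -> None:
        for name in ("dp", "ep", "ce", "cxp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name.upper()} must be positive")


@dataclass(frozen=True)
class PISMethod:
    sugar: SugarTag
    fixed_q3_mz: float
    q1_scan_range: tuple[float, float]
    dp: str  # opaque ramp string, e.g. "90-156"
    ep: int
    ce: int
    cxp: int


def _as_species(item: Union[str, AmadoriPESpecies]) -> AmadoriPESpecies:
    return parse_species(item) if isinstance(item, str) else item


def build_mrm_table(
    species_list: Optional[Iterable[Union[str, AmadoriPESpecies]]] = None,
    params: Optional[dict] = None,
) -> list[MRMTransition]:
    """Build an MRM table: one Q1/Q3 transition per glycated species.

    With no arguments this reproduces the default six-species method
    (Glc-PE and Lac-PE 34:1/36:1/36:2).  Species without an explicit
    voltage entry fall back to per-sugar-class defaults.  Unglycated PE
    has no diagnostic Q3 and raises :class:`SpeciesError`.
    """
    if species_list is None:
        species_list = DEFAULT_MRM_SPECIES
    config = params if params is not None else default_params()
    per_species = config.get("mrm", {})
    class_defaults = config.get("mrm_class_defaults", {})

    table = []
    for item in species_list:
        species = _as_species(item)
        if species.sugar is SugarTag.NONE:
            raise SpeciesError(
                f"{species.display_name} carries no sugar tag and has no diagnostic product ion"
            )
        volts = per_species.get(species.display_name) or class_defaults.get(species.sugar.value)
        if volts is None:
            raise SpeciesError(f"no voltage parameters configured for {species.display_name}")
        table.append(
            MRMTransition(
                species=species,
                q1_mz=method_round(precursor_mz(species, SODIUM)),
                q3_mz=method_round(head_ion_mz(species.sugar)),
                dp=int(volts["DP"]),
                ep=int(volts["EP"]),
                ce=int(volts["CE"]),
                cxp=int(volts["CXP"]),
            )
        )
    return table


def build_pis_method(
    sugar: SugarTag,
    compositions: Sequence[tuple[int, int]] = DEFAULT_PIS_COMPOSITIONS,
    params: Optional[dict] = None,
    margin: float = 5.0,
) -> PISMethod:
    """Build a PIS method for one sugar class.

    Q3 is fixed on the class head ion; the Q1 scan range spans the
    sodiated precursors of the catalog compositions plus a margin on
    each side (default 5 m/z).
    """
    if sugar is SugarTag.NONE:
        raise SpeciesError("PIS requires a glycated class (glucose or lactose)")
    if not compositions:
        raise SpeciesError("PIS catalog is empty")
    config = params if params is not None else default_params()
    volts = config["pis"][sugar.value]
    precursors = [
        precursor_mz(AmadoriPESpecies(AcylComposition(t, d), sugar), SODIUM)
        for t, d in compositions
    ]
    return PISMethod(
        sugar=sugar,
        fixed_q3_mz=method_round(head_ion_mz(sugar)),
        q1_scan_range=(
            method_round(min(precursors) - margin),
            method_round(max(precursors) + margin),
        ),
        dp=str(volts["DP"]),
        ep=int(volts["EP"]),
        ce=int(volts["CE"]),
        cxp=int(volts["CXP"]),
    )


# --- CSV export / import ------------------------------------------------

_MRM_HEADER = "species,Q1,Q3,DP,EP,CE,CXP"
_PIS_HEADER = "sugar,Q1_range,Q3,DP,EP,CE,CXP"


def export_method(
    method: Union[Sequence[MRMTransition], PISMethod],
    path: Union[str, Path, None] = None,
) -> str:
    """Serialize a method to its CSV dialect; byte-stable for equal inputs.

    MRM tables use ``species,Q1,Q3,DP,EP,CE,CXP`` rows; a PIS method is
    a single row with the Q1 range as ``"low-high"``.  Returns the CSV
    text and writes it to ``path`` when given.
    """
    if isinstance(method, PISMethod):
        lines = [
            _PIS_HEADER,
            f"{method.sugar.value},{method.q1_scan_range[0]:.1f}-{method.q1_scan_range[1]:.1f},"
            f"{method.fixed_q3_mz:.1f},{method.dp},{method.ep},{method.ce},{method.cxp}",
        ]
    else:
        lines = [_MRM_HEADER]
        for tr in method:
            lines.append(
                f"{tr.species.display_name},{tr.q1_mz:.1f},{tr.q3_mz:.1f},"
                f"{tr.dp},{tr.ep},{tr.ce},{tr.cxp}"
            )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8", newline="\n")
    return text


def read_mrm_table(path: Union[str, Path]) -> list[MRMTransition]:
    """Read an MRM table previously written by :func:`export_method`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != _MRM_HEADER:
        raise ValueError(f"{path}: not an MRM method CSV (expected header {_MRM_HEADER!r})")
    table = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(",")
        if len(fields) != 7:
            raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
        name, q1, q3, dp, ep, ce, cxp = fields
        table.append(
            MRMTransition(
                species=parse_species(name),
                q1_mz=float(q1),
                q3_mz=float(q3),
                dp=int(dp),
                ep=int(ep),
                ce=int(ce),
                cxp=int(cxp),
            )
        )
    return table
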