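"""External-calibration quantitation, unit conversion to mg/100 g and
LC-MS/MS method-validation statistics.

Calibration is unweighted ordinary least squares of peak area on amount
injected (pmol on column), as is standard for external standard curves;
a 1/x-weighted fit is available for heteroscedastic responses.  The
validation statistics follow the usual bioanalytical definitions:

* recovery%       = 100 * (spiked - blank) / spike amount
* accuracy%       = 100 * |expected - observed| / expected
* precision (CV%) = 100 * sd / mean over replicates
* matrix factor%  = 100 * response in matrix / response in neat solvent
* LOD             = amount at which predicted signal reaches 3x the
                    baseline noise (S/N = 3 convention)

Quantities outside a curve's calibrated range are returned with an
``out_of_range`` flag rather than rejected, since real samples routinely
require extrapolation or additional dilution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .chemcore import monoisotopic_mass
from .lipidspecies import AmadoriPESpecies, neutral_formula, parse_species

__all__ = [
    "CalibrationCurve",
    "DilutionChain",
    "QuantResult",
    "ValidationReport",
    "average_mass",
    "fit_calibration",
    "lod_estimate",
    "pis_total_quant",
    "quantify_amount",
    "to_mg_per_100g",
    "validation_stats",
]

#: Average (chemical) atomic masses for the optional average-mass convention.
_AVERAGE_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.973762, "Na": 22.98977}


def average_mass(species: AmadoriPESpecies) -> float:
    formula = neutral_formula(species)
    return sum(_AVERAGE_MASS[e] * n for e, n in formula)


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear external-calibration curve: response = slope*amount + intercept."""

    analyte_id: str
    amounts: tuple[float, ...]
    responses: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def invert(self, response: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("calibration slope is zero")
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class QuantResult:
    amount_pmol: float
    out_of_range: bool
    analyte_id: str = ""
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class DilutionChain:
    """Sample-preparation bookkeeping from powder to column.

    ``powder_mass_mg`` of powder ends up in ``extract_volume_mL`` of
    final extract, of which ``injection_volume_uL`` is injected;
    ``extra_dilution_factor`` covers any additional dilution step.
    The default mirrors a methanol-precipitation prep of 80 uL of a
    20 mg/mL reconstituted powder (1.6 mg) eluted in 1.5 mL with a
    10 uL injection.
    """

    powder_mass_mg: float = 1.6
    dissolution_volume_mL: float = 0.08
    extract_volume_mL: float = 1.5
    injection_volume_uL: float = 10.0
    extra_dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "powder_mass_mg",
            "dissolution_volume_mL",
            "extract_volume_mL",
            "injection_volume_uL",
            "extra_dilution_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ValidationReport:
    recovery_pct: float
    accuracy_pct: float
    precision_cv_pct: float
    matrix_factor_pct: float
    lod_fmol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.precision_cv_pct < 0:
            raise ValueError("CV cannot be negative")
        if self.matrix_factor_pct <= 0:
            raise ValueError("matrix factor must be positive")


def fit_calibration(
    points: Sequence[tuple[float, float]],
    analyte_id: str = "",
    weighting: str = "none",
) -> CalibrationCurve:
    """Fit a linear calibration curve to (amount_pmol, response) points.

    Requires at least three points with at least two distinct amounts.
    ``weighting="1/x"`` performs inverse-amount weighted least squares.
    """
    if len(points) < 3:
        raise ValueError("calibration requires at least 3 points")
    amounts = np.array([p[0] for p in points], dtype=float)
    responses = np.array([p[1] for p in points], dtype=float)
    if np.ptp(amounts) == 0:
        raise ValueError("calibration amounts have zero variance")
    if weighting == "none":
        fit = stats.linregress(amounts, responses)
        slope, intercept, rvalue = fit.slope, fit.intercept, fit.rvalue
        r_squared = float(rvalue**2)
    elif weighting == "1/x":
        if np.any(amounts <= 0):
            raise ValueError("1/x weighting requires positive amounts")
        w = 1.0 / amounts
        coeffs = np.polyfit(amounts, responses, 1, w=np.sqrt(w))
        slope, intercept = float(coeffs[0]), float(coeffs[1])
        predicted = slope * amounts + intercept
        ss_res = float(np.sum(w * (responses - predicted) ** 2))
        mean_w = float(np.sum(w * responses) / np.sum(w))
        ss_tot = float(np.sum(w * (responses - mean_w) ** 2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    return CalibrationCurve(
        analyte_id=analyte_id,
        amounts=tuple(amounts),
        responses=tuple(responses),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        valid_range=(float(amounts.min()), float(amounts.max())),
    )


def quantify_amount(area: float, curve: CalibrationCurve) -> QuantResult:
    """Invert a calibration curve; flag results outside the fitted range."""
    amount = curve.invert(area)
    lo, hi = curve.valid_range
    out = not (lo <= amount <= hi)
    notes = ()
    if out:
        notes = (
            f"{amount:.3g} pmol is outside the calibrated range "
            f"[{lo:g}, {hi:g}] pmol; value is an extrapolation",
        )
    return QuantResult(amount, out, analyte_id=curve.analyte_id, warnings=notes)


def to_mg_per_100g(
    amount_on_column_pmol: float,
    species: Union[str, AmadoriPESpecies],
    chain: DilutionChain,
    mass_convention: str = "monoisotopic",
) -> float:
    """Convert pmol on column to mg of analyte per 100 g of powder.

    Scales the injected amount back through the dilution chain, then
    converts moles to mass with the species' molecular mass
    (monoisotopic by default, ``mass_convention="average"`` optional).
    """
    if isinstance(species, str):
        species = parse_species(species)
    if mass_convention == "monoisotopic":
        mol_mass = monoisotopic_mass(neutral_formula(species))
    elif mass_convention == "average":
        mol_mass = average_mass(species)
    else:
        raise ValueError(f"unknown mass convention: {mass_convention!r}")
    pmol_in_extract = (
        amount_on_column_pmol
        * (chain.extract_volume_mL * 1000.0 / chain.injection_volume_uL)
        * chain.extra_dilution_factor
    )
    mg_analyte = pmol_in_extract * 1e-9 * mol_mass  # pmol * g/mol -> mg
    return mg_analyte / chain.powder_mass_mg * 100_000.0  # per mg powder -> per 100 g


def validation_stats(
    spiked_measured: float,
    blank_measured: float,
    spike_amount: float,
    replicate_blanks: Sequence[float],
    neat_response: float,
    matrix_response: float,
    lod_fmol: Optional[float] = None,
) -> ValidationReport:
    """Compute recovery, accuracy, precision (CV) and matrix factor.

    ``spiked_measured``/``blank_measured`` are measured concentrations
    (same unit as ``spike_amount``); accuracy compares the spiked
    measurement against blank + spike.
    """
    if spike_amount <= 0:
        raise ValueError("spike amount must be positive")
    if len(replicate_blanks) < 2:
        raise ValueError("precision requires at least 2 replicates")
    if neat_response <= 0:
        raise ValueError("neat response must be positive")
    expected = blank_measured + spike_amount
    if expected == 0:
        raise ZeroDivisionError("expected concentration is zero")
    replicates = np.asarray(replicate_blanks, dtype=float)
    mean = float(replicates.mean())
    cv = 100.0 * float(replicates.std(ddof=1)) / mean if mean != 0 else float("inf")
    return ValidationReport(
        recovery_pct=100.0 * (spiked_measured - blank_measured) / spike_amount,
        accuracy_pct=100.0 * abs(expected - spiked_measured) / expected,
        precision_cv_pct=cv,
        matrix_factor_pct=100.0 * matrix_response / neat_response,
        lod_fmol=lod_fmol,
    )


def lod_estimate(
    curve: CalibrationCurve,
    noise_sd: float,
    amount_unit_fmol: float = 1000.0,
) -> float:
    """Limit of detection in fmol at the S/N = 3 convention.

    ``noise_sd`` is the baseline noise in response units (the unit the
    curve's slope divides by amount).  ``amount_unit_fmol`` converts the
    curve's amount unit to fmol (1000 for a pmol-based curve, 1 if the
    curve is already in fmol).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if curve.slope <= 0:
        raise ValueError("LOD requires a positive calibration slope")
    return 3.0 * noise_sd / curve.slope * amount_unit_fmol


def pis_total_quant(
    pis_areas_by_class: Mapping[str, float],
    class_curves: Mapping[str, CalibrationCurve],
) -> dict[str, QuantResult]:
    """Quantify total Glc-PE / Lac-PE from PIS peak areas.

    Each class total is read off a single-species calibration curve
    (36:2 by convention, the most abundant species), so per-species
    differences in ionization efficiency bias the totals; a warning to
    that effect is attached to every result.  Use :func:`to_mg_per_100g`
    with the reference species to convert the totals to mg/100 g.
    """
    results: dict[str, QuantResult] = {}
    for class_id, area in pis_areas_by_class.items():
        curve = class_curves[class_id]
        base = quantify_amount(area, curve)
        notes = base.warnings + (
            "class total quantified against a single-species curve; per-species "
            "ionization differences bias the total",
        )
        results[class_id] = QuantResult(
            base.amount_pmol, base.out_of_range, analyte_id=class_id, warnings=notes
        )
    return results
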