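"""Calibration, quantitation, unit conversion and validation statistics."""

import numpy as np
import pytest

from amadorims import (
    DilutionChain,
    fit_calibration,
    lod_estimate,
    pis_total_quant,
    quantify_amount,
    to_mg_per_100g,
    validation_stats,
)


def test_noiseless_fit_and_round_trip():
    curve = fit_calibration([(a, 2.0 * a) for a in (0.5, 1, 2, 5, 10)])
    assert curve.slope == pytest.approx(2.0)
    assert curve.intercept == pytest.approx(0.0, abs=1e-12)
    assert curve.r_squared == pytest.approx(1.0)
    assert curve.valid_range == (0.5, 10.0)
    result = quantify_amount(curve.predict(5.0), curve)
    assert result.amount_pmol == pytest.approx(5.0, rel=1e-9)
    assert not result.out_of_range


def test_noisy_curve_stays_linear():
    rng = np.random.default_rng(11)
    points = []
    for amount in (0.5, 1, 2, 5, 10):
        for _ in range(3):
            points.append((amount, 1000.0 * amount * (1 + 0.02 * rng.standard_normal())))
    curve = fit_calibration(points)
    assert curve.r_squared > 0.99
    assert curve.slope == pytest.approx(1000.0, rel=0.03)


def test_fit_rejects_degenerate_designs():
    with pytest.raises(ValueError):
        fit_calibration([(1.0, 2.0), (2.0, 4.0)])  # < 3 points
    with pytest.raises(ValueError):
        fit_calibration([(5.0, 9.0), (5.0, 10.0), (5.0, 11.0)])  # one amount


def test_weighted_fit_matches_on_homoscedastic_data():
    points = [(a, 3.0 * a + 1.0) for a in (1, 2, 5, 10, 20)]
    w = fit_calibration(points, weighting="1/x")
    assert w.slope == pytest.approx(3.0, abs=1e-9)
    assert w.intercept == pytest.approx(1.0, abs=1e-9)


def test_out_of_range_is_flagged_not_rejected():
    curve = fit_calibration([(a, 100.0 * a) for a in (0.5, 1, 2, 5, 10)])
    high = quantify_amount(curve.predict(484.0), curve)  # far beyond the curve
    assert high.out_of_range and high.amount_pmol == pytest.approx(484.0)
    below = quantify_amount(curve.intercept - 10.0, curve)
    assert below.out_of_range and below.amount_pmol < 0


def test_mg_per_100g_conversion():
    chain = DilutionChain(powder_mass_mg=1.6, extract_volume_mL=1.5, injection_volume_uL=10.0)
    # 1 pmol on column -> 150 pmol in extract -> x 1067.65 g/mol over 1.6 mg
    value = to_mg_per_100g(1.0, "Lac-PE 36:2", chain)
    assert value == pytest.approx(10.0, rel=0.01)
    assert to_mg_per_100g(0.0, "Lac-PE 36:2", chain) == 0.0
    halved = DilutionChain(powder_mass_mg=1.6, extract_volume_mL=1.5, injection_volume_uL=20.0)
    assert to_mg_per_100g(1.0, "Lac-PE 36:2", halved) == pytest.approx(value / 2, rel=1e-9)


def test_average_mass_option_slightly_exceeds_monoisotopic():
    chain = DilutionChain()
    mono = to_mg_per_100g(1.0, "Glc-PE 34:1", chain)
    avg = to_mg_per_100g(1.0, "Glc-PE 34:1", chain, mass_convention="average")
    assert 1.0 < avg / mono < 1.01


def test_validation_stats_closed_form():
    report = validation_stats(
        spiked_measured=100.0,
        blank_measured=20.0,
        spike_amount=100.0,
        replicate_blanks=[10.0, 10.0, 10.0],
        neat_response=1000.0,
        matrix_response=970.0,
    )
    assert report.recovery_pct == pytest.approx(80.0)
    assert report.precision_cv_pct == 0.0
    assert report.matrix_factor_pct == pytest.approx(97.0)
    # expected 120, observed 100 -> |20|/120
    assert report.accuracy_pct == pytest.approx(100 * 20 / 120)


def test_validation_stats_scale_invariance():
    kwargs = dict(
        spiked_measured=90.0, blank_measured=10.0, spike_amount=100.0,
        replicate_blanks=[9.0, 10.0, 11.0], neat_response=500.0, matrix_response=480.0,
    )
    base = validation_stats(**kwargs)
    scaled = validation_stats(
        spiked_measured=90.0, blank_measured=10.0, spike_amount=100.0,
        replicate_blanks=[18.0, 20.0, 22.0], neat_response=5000.0, matrix_response=4800.0,
    )
    assert scaled.precision_cv_pct == pytest.approx(base.precision_cv_pct)
    assert scaled.matrix_factor_pct == pytest.approx(base.matrix_factor_pct)


def test_validation_stats_preconditions():
    with pytest.raises(ValueError):
        validation_stats(1, 0, 0.0, [1, 2], 1, 1)
    with pytest.raises(ValueError):
        validation_stats(1, 0, 1.0, [1], 1, 1)


def test_noisy_recovery_simulation():
    rng = np.random.default_rng(5)
    true_recovery, blanks = 0.85, []
    reports = []
    for _ in range(3):
        blank = 20.0 * (1 + 0.03 * rng.standard_normal())
        spiked = blank + true_recovery * 100.0 * (1 + 0.03 * rng.standard_normal())
        blanks.append(blank)
        reports.append(
            validation_stats(spiked, blank, 100.0, [20.0, 20.5, 19.5], 1000.0, 990.0)
        )
    mean_recovery = np.mean([r.recovery_pct for r in reports])
    assert 75.0 < mean_recovery < 95.0


def test_lod_closed_form_and_scaling():
    curve = fit_calibration([(a, 10.0 * a) for a in (1, 2, 5)], analyte_id="x")
    # slope 10 counts per fmol-equivalent unit: keep units with factor 1
    assert lod_estimate(curve, 100.0, amount_unit_fmol=1.0) == pytest.approx(30.0)
    assert lod_estimate(curve, 200.0, amount_unit_fmol=1.0) == pytest.approx(60.0)
    with pytest.raises(ValueError):
        lod_estimate(curve, 0.0)


def test_pis_total_quant_attaches_single_species_warning():
    curve = fit_calibration([(a, 50.0 * a) for a in (1, 2, 5, 10, 20)], analyte_id="Glc-PE")
    results = pis_total_quant({"Glc-PE": 50.0 * 7.5}, {"Glc-PE": curve})
    assert results["Glc-PE"].amount_pmol == pytest.approx(7.5)
    assert any("single-species" in w for w in results["Glc-PE"].warnings)
    zero = pis_total_quant({"Glc-PE": curve.intercept}, {"Glc-PE": curve})
    assert zero["Glc-PE"].amount_pmol == pytest.approx(0.0, abs=1e-12)
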