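"""Signal containers, CSV/mzML round trips, integration and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amadorims import (
    Chromatogram,
    MassSpectrum,
    SignalError,
    annotate_q1_spectrum,
    integrate_peak,
    read_signals,
    write_signals,
)


def gaussian_trace(area=1000.0, rt=5.0, sigma=0.1, t_max=10.0, dt=0.01, baseline=0.0):
    t = np.arange(0.0, t_max, dt)
    y = baseline + area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    return Chromatogram("test", t, y)


# --- containers ---------------------------------------------------------

def test_container_invariants():
    with pytest.raises(SignalError):
        Chromatogram("x", [0.0, 2.0, 1.0], [1.0, 1.0, 1.0])  # non-monotonic time
    with pytest.raises(SignalError):
        Chromatogram("x", [0.0, 1.0], [1.0, -1.0])  # negative intensity
    with pytest.raises(SignalError):
        MassSpectrum([100.0, 100.0], [1.0, 1.0])  # duplicate m/z


# --- file I/O -----------------------------------------------------------

def test_csv_chromatogram_round_trip(tmp_path):
    path = tmp_path / "run.csv"
    chrom = Chromatogram("902.6/326.1", [0.0, 0.5, 1.0], [1.0, 5.0, 2.0])
    write_signals([chrom], path)
    (back,) = read_signals(path)
    assert back.transition_id == chrom.transition_id
    np.testing.assert_array_equal(back.times, chrom.times)
    np.testing.assert_array_equal(back.intensities, chrom.intensities)


def test_csv_three_point_file(tmp_path):
    path = tmp_path / "mini.csv"
    path.write_text("transition_id,time_min,intensity\nt1,0.0,1\nt1,0.5,3\nt1,1.0,1\n")
    (chrom,) = read_signals(path)
    assert len(chrom) == 3


def test_csv_error_reports_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("transition_id,time_min,intensity\nt1,0.0,1\nt1,oops,3\n")
    with pytest.raises(SignalError, match="bad.csv:3"):
        read_signals(path)


def test_csv_rejects_non_monotonic_time(tmp_path):
    path = tmp_path / "nm.csv"
    path.write_text("transition_id,time_min,intensity\nt1,1.0,1\nt1,0.5,3\n")
    with pytest.raises(SignalError, match="strictly increasing"):
        read_signals(path)


def test_mzml_round_trip(tmp_path):
    path = tmp_path / "run.mzML"
    chrom = gaussian_trace()
    spec = MassSpectrum([100.0, 200.5, 300.25], [1.0, 2.0, 3.0], spectrum_id="scan=1")
    write_signals([chrom, spec], path)
    back = read_signals(path)
    chroms = [s for s in back if isinstance(s, Chromatogram)]
    specs = [s for s in back if isinstance(s, MassSpectrum)]
    np.testing.assert_array_equal(chroms[0].times, chrom.times)
    np.testing.assert_array_equal(chroms[0].intensities, chrom.intensities)
    np.testing.assert_array_equal(specs[0].mz_values, spec.mz_values)
    assert specs[0].spectrum_id == "scan=1"


def test_read_rejects_malformed_xml(tmp_path):
    path = tmp_path / "broken.mzML"
    path.write_text("<mzML><run>")
    with pytest.raises(SignalError):
        read_signals(path)


# --- integration --------------------------------------------------------

def test_gaussian_area_recovered():
    peak = integrate_peak(gaussian_trace(area=1000.0), (4.0, 6.0))
    assert peak.found
    assert peak.area == pytest.approx(1000.0, rel=0.01)
    assert peak.start_time < peak.apex_time < peak.end_time
    assert peak.apex_time == pytest.approx(5.0, abs=0.02)


def test_two_identical_gaussians_window_isolates_one():
    t = np.arange(0.0, 10.0, 0.01)
    sigma = 0.1

    def g(rt):
        return 500.0 / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)

    chrom = Chromatogram("twin", t, g(3.0) + g(7.0))
    peak = integrate_peak(chrom, (2.0, 4.0))
    assert peak.area == pytest.approx(500.0, rel=0.01)


def test_all_zero_trace_gives_no_peak():
    chrom = Chromatogram("blank", np.arange(0.0, 10.0, 0.01), np.zeros(1000))
    peak = integrate_peak(chrom, (4.0, 6.0))
    assert not peak.found
    assert peak.area == 0.0


def test_window_outside_trace_errors():
    with pytest.raises(SignalError):
        integrate_peak(gaussian_trace(), (50.0, 60.0))


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.floats(0.1, 1000.0))
def test_integration_is_linear_in_intensity(scale):
    base = gaussian_trace(area=1000.0)
    scaled = Chromatogram("s", base.times, base.intensities * scale)
    assert integrate_peak(scaled, (4.0, 6.0)).area == pytest.approx(
        scale * integrate_peak(base, (4.0, 6.0)).area, rel=1e-6
    )


@pytest.mark.parametrize("dt", [0.005, 0.01, 0.02])
def test_area_stable_under_resampling(dt):
    """>=5 points per peak width keeps the trapezoid area within 2%."""
    peak = integrate_peak(gaussian_trace(area=1000.0, dt=dt), (4.0, 6.0))
    assert peak.area == pytest.approx(1000.0, rel=0.02)


def test_signal_to_noise_scales_with_noise():
    rng = np.random.default_rng(42)
    t = np.arange(0.0, 10.0, 0.01)
    clean = 2000.0 * np.exp(-0.5 * ((t - 5.0) / 0.1) ** 2)
    for noise_sd, expected in [(10.0, 200.0), (40.0, 50.0)]:
        y = np.clip(clean + 100.0 + noise_sd * rng.standard_normal(len(t)), 0, None)
        peak = integrate_peak(Chromatogram("sn", t, y), (4.0, 6.0))
        assert peak.signal_to_noise == pytest.approx(expected, rel=0.4)


# --- annotation ---------------------------------------------------------

def make_spectrum(mzs, heights, lo=700.0, hi=1100.0):
    grid = np.arange(lo, hi, 0.02)
    y = np.zeros_like(grid)
    for mz, h in zip(mzs, heights):
        y += h * np.exp(-0.5 * ((grid - mz) / 0.08) ** 2)
    return MassSpectrum(grid, y)


def test_annotation_matches_both_adducts(catalog):
    spec = make_spectrum([880.59, 902.57], [500.0, 1000.0])
    hits = {(a["species"], a["adduct"]) for a in annotate_q1_spectrum(spec, catalog)}
    assert ("34:1 Glc-PE", "[M+H]+") in hits
    assert ("34:1 Glc-PE", "[M+Na]+") in hits


def test_annotation_unknown_peak(catalog):
    spec = make_spectrum([951.0], [1000.0])  # > 1.5 Da from any catalog ion
    (hit,) = annotate_q1_spectrum(spec, catalog, tolerance=0.5)
    assert hit["species"] == "unknown"


def test_annotation_empty_spectrum(catalog):
    spec = MassSpectrum(np.array([]), np.array([]))
    assert annotate_q1_spectrum(spec, catalog) == []


def test_annotation_invariant_under_catalog_permutation(catalog):
    spec = make_spectrum([902.57, 1064.63], [1000.0, 800.0])
    forward = annotate_q1_spectrum(spec, catalog)
    shuffled = annotate_q1_spectrum(spec, catalog.sample(frac=1.0, random_state=3))
    assert forward == shuffled
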