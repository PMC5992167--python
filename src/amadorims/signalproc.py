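"""Chromatogram / mass-spectrum containers, file I/O, peak integration
and Q1 spectrum annotation.

File formats
------------
Chromatograms and spectra travel as plain CSV (chromatogram dialect:
``transition_id,time_min,intensity``; spectrum dialect:
``spectrum_id,mz,intensity``; UTF-8, header mandatory) or as minimal
mzML.  The mzML path is self-contained: a writer and reader for
uncompressed 64-bit little-endian base64 arrays inside the standard
``<spectrum>`` / ``<chromatogram>`` elements, which keeps round trips
exact without external controlled-vocabulary machinery.

Peak integration
----------------
``integrate_peak`` smooths with a 5-point moving average, takes the
apex inside the requested window, and walks outward to the first points
where the smoothed trace falls below baseline + 3*sigma(noise); the
baseline level and noise sigma are estimated from the trace outside the
window.  The area is the trapezoid integral above a straight line drawn
between the two boundary points, and S/N is apex height (baseline
corrected) over the outside-noise sigma.
"""

from __future__ import annotations

import base64
import csv
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import median_abs_deviation

__all__ = [
    "Chromatogram",
    "MassSpectrum",
    "PeakResult",
    "SignalError",
    "annotate_q1_spectrum",
    "integrate_peak",
    "read_signals",
    "write_signals",
]

PathLike = Union[str, Path]


class SignalError(ValueError):
    """Raised for malformed signal files or invalid signal arrays."""


def _validate_axes(x: np.ndarray, y: np.ndarray, xname: str, context: str) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise SignalError(f"{context}: {xname} and intensity arrays must be equal-length 1-D")
    if len(x) > 1 and not np.all(np.diff(x) > 0):
        raise SignalError(f"{context}: {xname} values must be strictly increasing")
    if np.any(y < 0):
        raise SignalError(f"{context}: intensities must be non-negative")


@dataclass
class Chromatogram:
    """A single transition's time trace: minutes vs counts."""

    transition_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        _validate_axes(self.times, self.intensities, "time", f"chromatogram {self.transition_id!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MassSpectrum:
    """A single scan or averaged spectrum: m/z vs counts."""

    mz_values: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = "spectrum"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        _validate_axes(self.mz_values, self.intensities, "m/z", f"spectrum {self.spectrum_id!r}")

    def __len__(self) -> int:
        return len(self.mz_values)


@dataclass(frozen=True)
class PeakResult:
    """Integration result for one chromatographic peak."""

    apex_time: float
    start_time: float
    end_time: float
    area: float
    height: float
    signal_to_noise: float
    found: bool = True

    @staticmethod
    def no_peak() -> "PeakResult":
        return PeakResult(np.nan, np.nan, np.nan, 0.0, 0.0, 0.0, found=False)


# --- CSV I/O ------------------------------------------------------------

_CHROM_HEADER = ["transition_id", "time_min", "intensity"]
_SPEC_HEADER = ["spectrum_id", "mz", "intensity"]


def _read_csv(path: PathLike) -> list[Union[Chromatogram, MassSpectrum]]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise SignalError(f"{path}: empty file") from None
        if header == _CHROM_HEADER:
            kind = "chromatogram"
        elif header == _SPEC_HEADER:
            kind = "spectrum"
        else:
            raise SignalError(f"{path}: unrecognized header {header!r}")
        groups: dict[str, list[tuple[float, float]]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise SignalError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                groups.setdefault(row[0], []).append((float(row[1]), float(row[2])))
            except ValueError:
                raise SignalError(f"{path}:{lineno}: non-numeric value in {row!r}") from None
    signals: list[Union[Chromatogram, MassSpectrum]] = []
    for sid, points in groups.items():
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        try:
            if kind == "chromatogram":
                signals.append(Chromatogram(sid, x, y))
            else:
                signals.append(MassSpectrum(x, y, spectrum_id=sid))
        except SignalError as err:
            raise SignalError(f"{path}: {err}") from None
    return signals


def _write_csv(signals: Sequence[Union[Chromatogram, MassSpectrum]], path: PathLike) -> None:
    kinds = {type(s) for s in signals}
    if len(kinds) > 1:
        raise SignalError("cannot mix chromatograms and spectra in one CSV")
    is_chrom = not signals or isinstance(signals[0], Chromatogram)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(_CHROM_HEADER if is_chrom else _SPEC_HEADER)
        for s in signals:
            sid = s.transition_id if isinstance(s, Chromatogram) else s.spectrum_id
            x = s.times if isinstance(s, Chromatogram) else s.mz_values
            for xi, yi in zip(x, s.intensities):
                writer.writerow([sid, repr(float(xi)), repr(float(yi))])


# --- minimal mzML I/O ---------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode_array(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode("ascii")


def _decode_array(text: str, length: int) -> np.ndarray:
    raw = base64.b64decode(text.encode("ascii"))
    return np.array(struct.unpack(f"<{length}d", raw))


def _binary_array(parent: ET.Element, accession: str, name: str, values: np.ndarray) -> None:
    arr = ET.SubElement(parent, "binaryDataArray")
    for acc, nm in (
        ("MS:1000523", "64-bit float"),
        ("MS:1000576", "no compression"),
        (accession, name),
    ):
        ET.SubElement(arr, "cvParam", cvRef="MS", accession=acc, name=nm, value="")
    ET.SubElement(arr, "binary").text = _encode_array(values)


def _write_mzml(signals: Sequence[Union[Chromatogram, MassSpectrum]], path: PathLike) -> None:
    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    run = ET.SubElement(root, "run", id="run")
    spectra = [s for s in signals if isinstance(s, MassSpectrum)]
    chroms = [s for s in signals if isinstance(s, Chromatogram)]
    if spectra:
        slist = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
        for i, spec in enumerate(spectra):
            el = ET.SubElement(
                slist, "spectrum", index=str(i), id=spec.spectrum_id,
                defaultArrayLength=str(len(spec)),
            )
            bl = ET.SubElement(el, "binaryDataArrayList", count="2")
            _binary_array(bl, "MS:1000514", "m/z array", spec.mz_values)
            _binary_array(bl, "MS:1000515", "intensity array", spec.intensities)
    if chroms:
        clist = ET.SubElement(run, "chromatogramList", count=str(len(chroms)))
        for i, chrom in enumerate(chroms):
            el = ET.SubElement(
                clist, "chromatogram", index=str(i), id=chrom.transition_id,
                defaultArrayLength=str(len(chrom)),
            )
            bl = ET.SubElement(el, "binaryDataArrayList", count="2")
            _binary_array(bl, "MS:1000595", "time array", chrom.times)
            _binary_array(bl, "MS:1000515", "intensity array", chrom.intensities)
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def _qname(tag: str) -> str:
    return f"{{{_MZML_NS}}}{tag}"


def _read_binary_arrays(element: ET.Element, context: str) -> dict[str, np.ndarray]:
    length = int(element.get("defaultArrayLength", "0"))
    arrays: dict[str, np.ndarray] = {}
    for arr in element.iter(_qname("binaryDataArray")):
        name = None
        for cv in arr.iter(_qname("cvParam")):
            if cv.get("name", "").endswith("array"):
                name = cv.get("name")
        binary = arr.find(_qname("binary"))
        if name is None or binary is None:
            raise SignalError(f"{context}: binaryDataArray without array-type cvParam or data")
        arrays[name] = _decode_array(binary.text or "", length)
    return arrays


def _read_mzml(path: PathLike) -> list[Union[Chromatogram, MassSpectrum]]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as err:
        raise SignalError(f"{path}: not valid XML ({err})") from None
    signals: list[Union[Chromatogram, MassSpectrum]] = []
    for spec in tree.iter(_qname("spectrum")):
        sid = spec.get("id", "spectrum")
        arrays = _read_binary_arrays(spec, f"{path} spectrum {sid!r}")
        signals.append(MassSpectrum(arrays["m/z array"], arrays["intensity array"], spectrum_id=sid))
    for chrom in tree.iter(_qname("chromatogram")):
        cid = chrom.get("id", "chromatogram")
        arrays = _read_binary_arrays(chrom, f"{path} chromatogram {cid!r}")
        signals.append(Chromatogram(cid, arrays["time array"], arrays["intensity array"]))
    return signals


def read_signals(path: PathLike, format: Optional[str] = None) -> list[Union[Chromatogram, MassSpectrum]]:
    """Read chromatograms/spectra from CSV or mzML (inferred from suffix)."""
    fmt = format or ("mzml" if str(path).lower().endswith(".mzml") else "csv")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise SignalError(f"unsupported format: {fmt!r}")


def write_signals(
    signals: Sequence[Union[Chromatogram, MassSpectrum]],
    path: PathLike,
    format: Optional[str] = None,
) -> None:
    """Write signals to CSV or mzML (inferred from suffix)."""
    fmt = format or ("mzml" if str(path).lower().endswith(".mzml") else "csv")
    if fmt == "csv":
        _write_csv(signals, path)
    elif fmt == "mzml":
        _write_mzml(signals, path)
    else:
        raise SignalError(f"unsupported format: {fmt!r}")


# --- peak integration ---------------------------------------------------

def _moving_average(y: np.ndarray, width: int = 5) -> np.ndarray:
    if len(y) < width:
        return y.copy()
    kernel = np.ones(width) / width
    smoothed = np.convolve(y, kernel, mode="same")
    # edges: renormalize for partial kernel coverage
    coverage = np.convolve(np.ones_like(y), kernel, mode="same")
    return smoothed / coverage


def integrate_peak(chrom: Chromatogram, window: tuple[float, float]) -> PeakResult:
    """Integrate the largest peak inside ``window`` (minutes).

    Returns a no-peak result (zero area) when nothing in the window
    rises above baseline + 3*sigma of the outside-window noise.
    """
    t0, t1 = window
    if t0 >= t1:
        raise SignalError(f"invalid window: {window}")
    times, raw = chrom.times, chrom.intensities
    inside = (times >= t0) & (times <= t1)
    if not inside.any():
        raise SignalError(f"window {window} outside the time range of {chrom.transition_id!r}")
    smoothed = _moving_average(raw)

    outside = ~inside
    # median/MAD so that other peaks outside the window do not inflate the
    # noise estimate
    if outside.sum() >= 4:
        reference = raw[outside]
    else:  # window covers (nearly) the whole trace; fall back to its edges
        reference = np.concatenate([raw[:3], raw[-3:]])
    baseline_level = float(np.median(reference))
    noise_sd = float(median_abs_deviation(reference, scale="normal"))
    threshold = baseline_level + 3.0 * noise_sd

    idx_inside = np.flatnonzero(inside)
    apex_rel = int(np.argmax(smoothed[idx_inside]))
    apex = idx_inside[apex_rel]
    if smoothed[apex] <= threshold:
        return PeakResult.no_peak()

    start = apex
    while start > idx_inside[0] and smoothed[start - 1] > threshold:
        start -= 1
    end = apex
    while end < idx_inside[-1] and smoothed[end + 1] > threshold:
        end += 1
    if end - start < 2:
        return PeakResult.no_peak()

    seg_t = times[start : end + 1]
    seg_y = raw[start : end + 1]
    baseline = np.interp(seg_t, [seg_t[0], seg_t[-1]], [seg_y[0], seg_y[-1]])
    area = float(np.trapezoid(np.clip(seg_y - baseline, 0.0, None), seg_t))
    height = float(raw[apex] - baseline_level)
    sn = height / noise_sd if noise_sd > 0 else float("inf")
    return PeakResult(
        apex_time=float(times[apex]),
        start_time=float(seg_t[0]),
        end_time=float(seg_t[-1]),
        area=area,
        height=height,
        signal_to_noise=sn,
    )


# --- Q1 spectrum annotation ---------------------------------------------

def annotate_q1_spectrum(
    spectrum: MassSpectrum,
    catalog,
    tolerance: float = 0.5,
    min_rel_intensity: float = 0.01,
) -> list[dict]:
    """Match local maxima of a Q1 spectrum to catalog [M+H]+/[M+Na]+ ions.

    ``catalog`` is a class-mass-catalog DataFrame with ``species``,
    ``mz_H`` and ``mz_Na`` columns.  Each detected peak is assigned the
    nearest catalog ion within ``tolerance`` Da (0.5 Da suits unit-
    resolution QQQ spectra; use ~10 ppm equivalents for QTOF data) or
    labelled ``unknown``.  Peaks below ``min_rel_intensity`` of the base
    peak are ignored.
    """
    if tolerance <= 0:
        raise SignalError("tolerance must be positive")
    if len(spectrum) == 0:
        return []
    y = spectrum.intensities
    peaks, _ = find_peaks(y, height=min_rel_intensity * float(y.max()))
    if len(y) == 1 and y[0] > 0:
        peaks = np.array([0])

    references = []
    for _, row in catalog.iterrows():
        references.append((row["mz_H"], row["species"], "[M+H]+"))
        references.append((row["mz_Na"], row["species"], "[M+Na]+"))
    references.sort()

    annotations = []
    for idx in peaks:
        mz = float(spectrum.mz_values[idx])
        best = None
        for ref_mz, species, adduct in references:
            delta = abs(mz - ref_mz)
            if delta <= tolerance and (best is None or delta < best[0]):
                best = (delta, species, adduct)
        annotations.append(
            {
                "mz": mz,
                "intensity": float(y[idx]),
                "species": best[1] if best else "unknown",
                "adduct": best[2] if best else "unknown",
                "delta_mz": best[0] if best else np.nan,
            }
        )
    return annotations
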