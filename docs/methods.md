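# Methods

## The measurement this package models

The Maillard reaction condenses a reducing sugar onto the primary amine
of phosphatidylethanolamine (PE); after Amadori rearrangement the
product (Amadori-PE) carries the sugar minus one water: +C6H10O5
(162.052823 Da) for glucose (Glc-PE), +C12H20O10 (324.105647 Da) for
lactose (Lac-PE). In heat-processed dairy powders these glycated PEs
are abundant, and the analytical task is to quantify them per molecular
species (total acyl carbons:double bonds — 34:1, 36:1, 36:2, 36:3) and
per sugar class.

Positive-mode CID gives two usable fragment channels:

* **DAG fragment** (either adduct): neutral loss of the glycated polar
  head — phosphoethanolamine C2H8NO4P (141.019094 Da) plus the sugar
  increment — leaves a diacylglycerol-type cation carrying both acyls.
  Its m/z depends only on the acyl composition (577.519 for 34:1,
  605.550 for 36:1, 603.535 for 36:2), and native PE makes the same
  ion by phosphate-head loss, so it is composition-specific but not
  glycation-specific.
* **Sodiated glycated head ion** ([M+Na]+ only): neutral loss of both
  acyls with the glycerol backbone leaves
  [H3PO4·CH2CH2·NH·sugar + Na]+ — C8H18NO9PNa, m/z 326.061 (glucose)
  or C14H28NO14PNa, m/z 488.114 (lactose) — plus sequential water
  losses (two modelled for the glucose head, one for the lactose
  head). These ions are invariant across acyl compositions and absent
  from native PE: glycation-specific, class-wide.

The package turns this into acquisition methods: **MRM** transitions
pair each species' sodiated precursor (Q1, rounded half-up to 1
decimal) with its class head ion (Q3); a **PIS** method fixes Q3 on the
head ion and scans Q1 across the class' precursor range, so species
never synthesized as standards (e.g. 36:3) are still detected.

## Mass conventions and numerical choices

* Atomic masses are hard-coded monoisotopic values of the most abundant
  isotope (C 12 exactly, H 1.0078250319, N 14.0030740052,
  O 15.9949146221, P 30.97376151, Na 22.98976928), giving bit-stable
  results with no data dependency.
* Cation m/z subtracts the electron mass (0.000549 Da). Instrument
  software often omits this; the difference is far inside the 5 mDa
  agreement expected of printed "exact masses". Only +1 ions are
  supported — no multiply charged glycerophospholipid ions occur in
  this assay.
* The single-dehydration glucose head ion is reported at its
  theoretical 308.051 (326.0617 − 18.0106). A published observation of
  this channel at 308.120 is irreconcilable with a water loss (69 mDa
  off) and is treated as an unexplained observation, not as something
  to reproduce.
* Method m/z rounding is half-up to one decimal. Voltages (DP/EP/CE/CXP)
  are empirical tuning values shipped as YAML defaults
  (`amadorims/data/mrm_params.yaml`); species without an explicit entry
  inherit per-sugar-class defaults. The PIS "DP" entries are opaque
  ramp strings ("90-156", "115-166"), stored but not interpreted.
* The PIS Q1 window is derived from the catalog (min/max sodiated
  precursor ± 5 m/z) rather than fixed, so the glucose-class scan
  actually covers the Glc-PE precursors near m/z 902–931.

## Signal processing

Chromatograms are `transition_id, time_min, intensity` CSV or minimal
mzML (uncompressed 64-bit base64 arrays; reader and writer are
self-contained in `signalproc`). Peak integration smooths with a
5-point moving average, finds the apex inside the user's window, and
walks outward to the first samples below baseline + 3σ. Baseline level
and σ are the median and normal-scaled MAD of the trace *outside* the
window — robust statistics so that neighbouring peaks do not inflate
the noise estimate. The area is the trapezoid integral above a straight
line between the two boundary points; S/N is baseline-corrected apex
height over σ. On clean Gaussians this recovers areas within 1% at ≥5
points per peak width. Q1 annotation matches local maxima to the
nearest catalog [M+H]+/[M+Na]+ within a tolerance of 0.5 Da by default
(unit-resolution QQQ); pass a tighter tolerance for high-resolution
spectra.

## Quantitation and validation statistics

Calibration is unweighted OLS of area on pmol injected (1/x weighting
available), with the valid range recorded as the fitted amount span;
inverting a curve outside that range flags the result as an
extrapolation instead of refusing — real samples are routinely above
the curve. Unit conversion to mg/100 g multiplies the on-column amount
back through a dilution chain (default: 1.6 mg powder → 1.5 mL extract,
10 µL injected) and by the species' molecular mass, monoisotopic by
default with an average-mass option (the convention used for published
concentrations is not recorded anywhere authoritative, so both are
offered).

Validation statistics follow the standard bioanalytical definitions:
recovery% = 100·(spiked − blank)/spike; accuracy% = 100·|expected −
observed|/expected (sign discarded); precision = CV% over replicates;
matrix factor% = 100·(response in matrix)/(response neat). The
detection limit uses the S/N = 3 convention: LOD = 3·noise/slope on a
height-based curve. PIS class totals are read off a single-species
curve (36:2 by convention); every such result carries a warning that
species-to-species ionization differences bias class totals.

## The synthetic data generator

`synthgen` emulates what a QQQ produces in this assay, not the physics
behind it: per-transition Gaussian peaks (area = amount × response
factor × matrix suppression) on a constant baseline, with additive
detector noise (default σ 30 counts on a 200-count baseline), 2%
multiplicative run-to-run area jitter (injection/ionization
variability), and an optional exponentially modified Gaussian shape to
stress the integrator with tailing. Response factors default to a ±20%
spread across species, mirroring the real spread of calibration slopes
between molecular species; retention times are arbitrary but
chromatographically ordered (longer chains later, more double bonds
earlier). Q1 spectra place [M+H]+/[M+Na]+ pairs with the intensity
split set by a sodium fraction (1.0 reproduces the sodium-saturated
condition in which only [M+Na]+ appears). Simulated designs follow the
study conditions: triplicate calibration at 0.5–10 pmol (MRM) or
1–20 pmol (PIS), spike/blank experiments as paired run sets sharing
per-replicate noise streams with the true recovery encoded as an
extraction-loss factor.

All randomness flows from one integer seed through per-(seed, run,
transition) counter-based streams, so every output is bit-reproducible
and blank/spiked pairs see identical noise. Default problem sizes
(20-minute traces at 0.01-minute sampling, 3 replicates × 5–6 levels)
keep a full simulate–integrate–calibrate–quantify cycle under a few
seconds.

What passing tests on this generator show: the pipeline's bookkeeping
is correct (areas linear in amount, calibration invertible, statistics
recover injected truth within the injected noise). What they cannot
show: behaviour on real data with drifting baselines, co-eluting
isobars, saturated detectors or retention shifts between runs — none
of which the generator emulates.

## Known limitations

* Only diacyl PE; ether/plasmalogen PE, glycated PS and advanced
  glycation end products are out of scope.
* Fragment intensities are not predicted; collision-energy response is
  configuration, not model.
* The SM catalog entries assume a d18:1 sphingoid base; real milk SM is
  a base mixture, so annotation of real SM regions may need broadening.
* Absolute concentrations in real powdered milk cannot be reproduced
  here — they require the original instrument data; the package
  reproduces the method's masses, parameters and statistical machinery,
  and validates the pipeline on synthetic ground truth instead.
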