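# Methods

This note documents the models, numerical conventions and design choices
behind `skyillum`, and what the synthetic test campaign does and does not
establish about real measurements.

## Spectral conventions

All analysis runs on 1-nm wavelength grids produced by linear interpolation
(`resample_1nm`); no extrapolation is ever performed, and requests outside a
source grid's support raise a range error. Band totals (VIS 400–800 nm,
UV-A 315–400 nm, UV-B 280–315 nm) are trapezoidal integrals of spectral
irradiance, in W·m⁻². The median filter used for quality control is a
moving-window median of length *order* + 1 (order 8 → 9-point window) with
windows truncated at the array boundaries — the median of the available
samples — so no data is fabricated beyond the grid. For odd orders the
window is placed with the extra sample on the long-wavelength side. Both
conventions are fixed and tested; anyone comparing bit-for-bit against
other implementations of "an 8th-order median filter" should check the
edge rule first.

## Calibration chain

Counts become downwelling spectral irradiance through five steps, in this
order: (1) subtraction of a dark spectrum taken from a library parameterised
by integration time and board temperature — the integration time must match
a library entry exactly (dark libraries are built on the acquisition's own
integration-time schedule) while temperature is interpolated linearly per
wavelength and clamped at the library's ends; (2) division by integration
time; (3) an additive wavelength-shift correction applied to the native
grid, followed by resampling to 1 nm; (4) multiplication by radiometric
correction factors (counts·s⁻¹ → W·m⁻²·sr⁻¹·nm⁻¹); (5) multiplication by
π, the projected solid angle of the hemisphere, giving W·m⁻²·nm⁻¹.

The wavelength shift is estimated from Hg/Ar line-lamp spectra: local
maxima above 5× the median absolute level, centroided by 3-point parabolic
interpolation, paired with the nearest catalogue line within ±5 nm; the
shift is the mean of (reference − detected) and recovers injected shifts in
[−2, 2] nm to well within the native grid spacing. Correction factors are
the per-wavelength ratio of a known source spectrum to its measurement;
factor sets from different calibration sources are spliced with linear
weight ramps over ±20 nm around the 400 nm and 760 nm transitions (weight
exactly ½ at the transition), after rescaling the outer sets onto the
middle set's absolute scale by the least-squares scalar
s = Σ(outer·mid)/Σ(outer·outer) over the transition window.

Quality control discards frames saturated at any wavelength and frames that
are zero everywhere after dark subtraction; negative post-dark values are
clamped to zero; survivors are median filtered (order 8) on the native grid
before resampling, which preserves emission lines a few nanometres wide at
sub-nanometre native sampling.

The odd/even-wavelength windowed correlation (`window_snr`) is a
signal-quality diagnostic: within ±20 nm of each wavelength the samples at
odd and even integer wavelengths are correlated (truncated to equal
length); smooth well-measured sources give |r| near 1, noise-dominated
regions near 0, and constant windows are flagged undefined.

## Regimes, filtering, binning

Solar-elevation regimes use half-open bands closed at the upper edge:
day θs ≥ 0°, civil [−6°, 0°), nautical [−12°, −6°), astronomical
[−18°, −12°), night below −18°. Elevations are true (geometric) values; no
refraction correction. Rural records are retained only when the fraction of
the moon illuminated is strictly below 0.3 (at that fraction the moon is
~3.29% as bright as a full moon); city records are all retained, since
light pollution dwarfs moonlight there. Dawn/dusk labels come from the sign
of dθs/dt, not clock time, with zero-slope runs inheriting the neighbouring
trend. Elevation bins are half-open intervals [k·w, (k+1)·w) with edges at
integer multiples of the width (1°, 2° or 5° depending on the analysis) and
are labelled by their centers.

## Fitting and R²

Basis components are splined to 1 nm and L2-normalised; each measured
spectrum is likewise resampled over the fit range (360–830 nm for this
instrument pair; 380–780 nm is the conventional choice for external
daylight databases, settable per basis) and divided by its vector norm,
with the norm kept as the record's scale factor. Weights come from ordinary
least squares with no intercept and no sign constraint; rank deficiency is
detected at condition number 10¹⁰. The reported R² is the squared Pearson
correlation between fitted and measured values across wavelengths —
computed with the standard mean-centred correlation — because that is the
statistic tracked against solar elevation throughout; the SSE-based
coefficient of determination is computed alongside (`r_squared_sse`) since
the two differ for biased fits, and only the SSE is guaranteed monotone
under basis nesting. A numerically constant fitted vector is assigned
R² = 0 rather than the correlation of rounding noise.

## The basis-extension procedure

The CIE daylight basis (S0, S1, S2) is extended one component at a time
from mean fit residuals: stage 1 uses all daylight spectra (θs ≥ 0°, both
locations pooled, every spectrum weighted equally); stage 2 uses civil
twilight (−6° < θs < 0°) under the CIE+1 model; stage 3 uses astronomical
twilight (−18° < θs < −12°) under the CIE+2 model, separately per
location. At each stage the residuals of the unit-norm spectra are averaged
first and the average is then divided by its Euclidean norm
(average-then-normalise; the other reading of the procedure —
normalise-then-average — gives a slightly different component and is not
used). Components are appended without orthogonalisation against the
parent basis and with their sign as computed; least squares absorbs both.
The rural lunar filter is applied throughout, including during component
derivation. Nautical-twilight spectra are never used for derivation, only
for evaluation. The result is two 6-component models, CIE+3R and CIE+3C,
differing only in their last component.

As a noise-floor reference for the night regime, `mean_spectrum_benchmark`
fits each night spectrum with the (renormalised) mean of the unit-norm
night spectra; to the extent the true night illumination is unchanging,
the resulting mean R² measures pure measurement variability.

## Colorimetry

Tristimulus values are CMF-weighted sums on the common 1-nm grid over
360–830 nm, using the CIE 1931 2° observer tables shipped with the package
(5-nm tabulation, linearly interpolated). The daylight locus uses the
standard construction — the CCT → x_D polynomial (two branches, 4000–7000 K
and 7000–25000 K), the locus parabola y_D = −3x² + 2.87x − 0.275, the
M1/M2 weight formulas, and the classical *un-normalised* S0/S1/S2 scaling
(the fitting module keeps a separate L2-normalised copy; the M1/M2 formulas
assume classical scaling). The constructed D65 spectrum reproduces
(0.3127, 0.3290) to ~2×10⁻⁵. sRGB swatches follow the published linear
XYZ→sRGB matrix with per-channel hard clipping to [0, 1] and standard gamma
encoding; per-bin brightness is log₁₀ of the L2 norm rescaled into
[0.3, 1] (all-equal norms degenerate to scale 1).

## The synthetic campaign

The generator is the package's study-conditions module, not a test
convenience: its defaults encode the structure the analysis must recover.

* **Intensity**: log₁₀ total VIS irradiance of the sun-driven term follows
  a logistic in solar elevation from 10²·⁵ W·m⁻² at high sun to an
  asymptote far below the night floors (center −13°, width 5°), so the
  diel swing spans ~8 decades and the floors take over below about −15°.
* **Spectral shape**: the daylight term is a CIE daylight spectrum whose
  CCT rises from 6500 K at θs ≥ 0 by 800 K per degree of solar depression
  (clipped at 25000 K), multiplied by a Chappuis-type Gaussian absorption
  band (600 ± 50 nm) whose optical depth peaks at 1.2 at θs = −12°
  (σ = 3°). This produces the twilight blue shift with its chromaticity
  minimum in the bin at the configured peak elevation.
* **Night floors**: the rural floor (total VIS 10⁻⁵·⁵ W·m⁻²) is a smooth
  airglow continuum plus a 558 nm line (σ = 2.5 nm, 6× the continuum); the
  city floor is exactly 100× brighter (10⁻³·⁵ W·m⁻²) and is built from a
  weak continuum plus mercury lines, a sodium complex across 570–615 nm
  and the 819 nm NIR sodium line.
* **Moonlight**: an additive daylight-shaped (4500 K) term, zero below the
  horizon, with total VIS equal to the city floor at full moon and scaled
  by b(f) = f^γ, γ = log 0.0329 / log 0.3 ≈ 2.835, so that b(1) = 1 and
  b(0.3) = 0.0329 exactly.
* **Instruments**: a high-sensitivity unit 'A' (180–875 nm, used below the
  horizon) and a daylight unit 'B' (340–1025 nm, used above it — hence no
  UV-B coverage in the daylight regime), each with a slightly quadratic
  factory wavelength polynomial carrying a small additive error (−0.79 and
  −0.98 nm), a smooth positive correction-factor curve, dark counts affine
  in integration time and board temperature (which makes the library's
  temperature interpolation exact), Gaussian read noise plus
  Gaussian-approximated shot noise, 16-bit saturation at 65535 counts, and
  automatic selection of the longest integration time (up to 60 s) keeping
  predicted peak counts below 85% of saturation.
* **Campaign structure**: one 24-h sinusoidal solar-elevation track per
  location spanning −30° to +18°, one record per minute (1440 per
  location), ephemeris tables at 10-min cadence from which record geometry
  is interpolated, and a ground-truth ledger (line positions, floors,
  shifts, the config itself) from which every truth spectrum is exactly
  reproducible. A fixed seed yields byte-identical output.

What the generator does **not** emulate: radiative transfer or
scattering physics (the twilight parameterisation is an empirical stand-in
whose recoverable features — line positions, floor levels, dip location —
are the test surface), clouds and minute-to-minute turbidity variation,
star fields, stray light, detector nonlinearity, or lunar-phase effects on
twilight shape. Passing tests therefore demonstrate that the pipeline
recovers known structure through a realistic acquisition chain, not that
the generator is an atmospheric model. One consequence worth noting: with
Chappuis absorption disabled the chromaticity-vs-elevation curve retains a
weak minimum where the night floor overtakes the ever-bluer twilight term;
the absorption is what deepens the dip and pins it at −12°.

## Problem sizes and tolerances

The default campaign (2880 records, ~1.9k pixels each) generates in ~3 s
and calibrates in ~4 s; the full acceptance script runs in well under a
minute, and the test suite in under half a minute. The noise-free
calibration round trip is checked to 10⁻⁹ relative using a truth spectrum
whose detector signal is affine in wavelength (so piecewise-linear
resampling is exact); with curved spectra the chain is accurate to the
linear-interpolation error of the native grid (~10⁻⁴ relative). Mean
residuals below 10⁻¹² norm are treated as degenerate (spectra within the
basis span). Unit-norm checks on basis components use 10⁻¹⁰.

## Known limitations

* R² as squared Pearson correlation is scale- and offset-blind: a fit that
  is proportionally wrong scores 1. The SSE variant is reported alongside
  for that reason.
* The extension procedure is greedy — components are locked in stage
  order, with no joint refit — by design, to mirror the regime-by-regime
  interpretation of the components.
* The generator's integration-time schedule is discrete; real campaigns
  adjust exposure continuously and occasionally saturate, which here
  happens only if a truth spectrum overwhelms the shortest exposure.
* External daylight databases and 6-component daylight models can be
  loaded through the basis CSV format for comparison, but none are
  bundled.
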