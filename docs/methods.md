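# Methods

This note records the models implemented in `pmbdose`, the conventions and
default parameters, the numerical choices, and what the synthetic data do
and do not represent.

## Coordinate and unit conventions

All positions are in mm in field coordinates: origin at the field centre,
x across the minibeam slits, y along them, y increasing upward. The
calorimeter measurement position in the mono-energetic set-up is
(0, −11) mm. Dose maps are cell-centred rasters; the default pixel spacing
is 25.4/600 = 0.04233 mm (a 600 dpi flatbed scan). Uncertainties are
standard uncertainties in fractional percent at k = 1 unless stated;
expanded uncertainties use k = 2.

## Synthetic minibeam field

The generating function is

```
D(x, y) = A · [v + (1 − v) · Σᵢ rampᵢ · Gᵢ(x)] · (1 + g·y) · E(y)
```

inside the field extent and zero outside, where `Gᵢ` is the slit top-hat
(width 0.4 mm) convolved with a Gaussian of width `blur_sigma` (an erf
difference), `v` is a uniform valley scatter background, `g` a linear dose
gradient along the beamlets, `rampᵢ` a linear per-slit amplitude ramp
standing in for a collimator tilt, and `E(y)` a slit-length envelope with a
2 mm raised-cosine roll-off at the ends. Per-pixel Gaussian noise is added
and clipped at zero; any stochastic output requires a seed and is bit-
reproducible for a fixed seed.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_slits / slit_width / pitch / slit_length | 15 / 0.4 mm / 4.0 mm / 50 mm | collimator geometry of the emulated field |
| field_extent | 72 × 72 mm² | irradiated field size |
| blur_sigma (mono) | 0.9 mm | beamlets clearly distinct at the 2 cm WED measurement depth; a surrogate, not a measured value |
| blur_sigma (SOBP), `spec.sobp()` | 1.3 mm | beamlets "still distinct but less so" at 10 cm WED |
| valley_fraction | 0.05 (mono), 0.10 (SOBP) | scatter fills the valleys with depth; surrogate values |
| vertical_gradient | +0.0033 /mm | calibrated so the vertical correction at y = −11 mm is ≈ 0.964, the magnitude observed on film; the positive sign (dose increasing upward) is what makes the −11 mm position dimmer than the centre |
| peak_dose | 10 Gy | amplitude scale only; every analysis statistic is a ratio |
| noise_sd | 0 | noise is opted into per study |

The 625-spot scanned delivery is subsumed into the smooth beamlet model;
slit divergence is not modelled, so the beamlet pitch at the measurement
plane equals the collimator pitch exactly. That idealization matters for
one published observation: a detector of radius r responds to the
fundamental lateral harmonic of a periodic field through 2·J₁(k₁r)/(k₁r),
which changes sign at r = 0.61·pitch = 2.44 mm. A measured field whose
effective pitch is magnified a few percent by divergence puts a 2.5 mm
aperture below that critical radius (dose *loss* at a half-pitch offset),
while the strictly 4.0 mm-pitch surrogate puts it just above (slight dose
gain). The suite asserts the measured-field sign pattern and therefore
documents this limitation as an expected failure of the surrogate, not of
the integrator.

`generate_minibeam_map` accepts `pad_mm` to add a zero-dose margin around
the field so that large apertures (e.g. the 40.8 mm Bragg-Peak-chamber
radius at (0, −11) mm) can be integrated; dose outside the scanned field is
taken as zero, as film analysis implicitly does.

## Depth-dose surrogate and SOBP construction

The pristine Bragg curve is an analytic stand-in (power-law buildup plus a
Gaussian-broadened peak whose distal edge decays with the peak Gaussian,
σ = max(0.35, 0.012·range) mm); after construction the depth axis is
rescaled so the distal 80% falloff (r80) sits exactly at the requested
range. It exists to exercise the r80 range-scaling procedure, not to model
proton transport. An SOBP is a weighted sum of pristine components whose
peaks span the modulation interval (the deepest overshooting the plateau
end by 0.45σ); weights are solved by non-negative least squares with
Lawson-style (minimax-seeking) reweighting, holding the plateau flat to
well under 1% across ranges 30–200 mm and widths 5–60 mm.

## Aperture DAP per unit area

`dap_per_area` integrates the raster over a disc: pixels are classified
exactly against the circle except for a boundary ring resolved by 4×4
subpixel coverage sampling, and the integral is divided by the identically
discretized disc area (so a uniform map returns its dose exactly, and
coverage errors largely cancel for smooth fields). The validation reference
`dap_per_area_supersampled` subdivides *every* candidate pixel 16×16 and is
kept implementationally independent; the two agree to well within 0.1% for
all detector radii used (2.5, 7.8, 8.0, 40.8 mm) at the spacings tested
(0.042–0.15 mm). Discs must lie inside the map (the error reports the
overhang); enlarge the raster with `pad_mm` when a large aperture is
needed near the field edge.

Offset scans normalize the DAP/A to a reference offset (0 mm horizontally,
−11 mm vertically) and are interpolated with monotone cubic (PCHIP)
polynomials between the 0.5 mm grid points.

## Positioning Type B

The positioning model is Gaussian per axis, mean at the nominal position,
σ = 0.5 mm (±1 mm at 95%, 2σ convention), axes independent. `sample_type_b`
draws 10⁶ offsets per axis by default, evaluates the interpolated
normalized scan, and reports the standard deviation (as %) per axis and the
quadrature combination. Draws beyond the scan range (≈ 6·10⁻⁵ of them for
the default ±2 mm coverage at σ = 0.5) are clipped to the range ends,
counted and warned about; rejecting them instead would change the estimate
negligibly. Fewer than 1000 samples triggers an instability warning.

For the film-derived factors, `positional_type_b_on_factor` samples a
*common* per-axis displacement of both apertures entering the ratio
(the detector assembly moves as one), re-evaluates the unnormalized DAP
trends at the displaced positions, recomputes the ratio per sample, and
combines the per-axis standard deviations in quadrature.

## Correction factors

- `kvert` = mean over repeated film maps of DAP/A(0, −11) ÷ DAP/A(0, 0)
  for one aperture radius; the sd of the per-film ratios is Type A.
- `kprof` = mean over films of DAP/A(r = 8.0) ÷ DAP/A(r = 7.8) at
  (0, −11) mm.
- `kimp` = d(pure graphite) ÷ d(full geometry); `kgap` = d(compensated) ÷
  d(pure graphite); scored doses are inputs (particle transport is out of
  scope) and their statistical uncertainties combine in quadrature. The
  product kimp·kgap telescopes to d(compensated)/d(full) exactly.
- Dose conversion: both depth-dose curves are normalized to their own
  maximum (percentage depth dose), the graphite depth axis is scaled by
  r80(water)/r80(graphite), and the factor is the water/graphite dose ratio
  at the reference depth (2.0 cm mono, 10.0 cm SOBP). r80 is located on the
  distal side of the peak by linear interpolation between bracketing
  samples; PDDs are interpolated with PCHIP.

Which kvert applies where: in the mono-energetic configuration the
calorimeter measures at (0, −11) mm and needs no vertical correction —
kvert(Roos) corrects the chamber; in the SOBP configuration the calorimeter
measures at the field centre and kvert(PSPC) enters its own dose equation.

## Calorimeter analysis

Quasi-adiabatic: straight lines are fitted to pre- and post-irradiation
drift windows (default length 60 s, ≥ 10 samples, ending/starting one
sample clear of the beam window) and extrapolated to the irradiation
*midpoint*; ΔT is their difference there and dose = c·ΔT. Extrapolating to
a common instant cancels any shared linear drift exactly; the midpoint is
the standard choice because it also cancels the first-order effect of
radiative heat loss during delivery. A temperature *drop* beyond 3× the fit
residual is rejected; large fit residuals warn.

Isothermal: one baseline line is fitted jointly over both drift windows;
the dose is the trapezoidal integral of (baseline − power) divided by the
core mass. The integration span extends two samples beyond the irradiation
window, which makes the trapezoidal sum exact for piecewise-constant
(energy-layer-stepped) depressions whose switch times lie on the sample
grid — the trace generator snaps window and step times to the grid and
emits the mean of the one-sided limits at jump samples for the same reason.
Noise-free round trips through generator + analysis are exact to machine
precision in both modes, a property the test suite asserts at < 10⁻⁶.

Default constants describe a 16 mm-diameter, 2 mm-thick graphite core:
c = 706 J/(kg·K), m = 0.72 g. Trace defaults: 300 s record at 10 Hz, beam
on 120–180 s. Combining the two modes takes the arithmetic mean and reports
the half-difference as a consistency metric, warning above 1% disagreement.

## Dose assembly

`dose_to_water` multiplies the core dose by the configuration's required
factors (mono: conversion, kimp, kgap; SOBP: + kvert_pspc), rejecting
missing, duplicate or unexpected factor names. Because the equation is a
pure product, fractional uncertainties combine exactly in quadrature; the
budget stores every (name, Type A, Type B) component and its combined value
is recomputable bit-exactly after JSON serialization. A maximum deviation
quoted as an expanded (k = 2) uncertainty is halved via
`expanded_to_standard` before entering the quadrature. The
calorimeter-vs-chamber `ratio_report` divides the calorimeter dose by the
kprof-corrected chamber dose and combines all three uncertainty sources.
The core-dose Type A defaults to the empirical sd of repeated trace
analyses, since no published calorimeter repeatability is available.

## Film processing

Scans of one film are averaged per pixel (variance ∝ 1/k); the signal is
the net optical density of a single (red-channel-equivalent) channel,
netOD = log₁₀(unexposed/irradiated); calibration uses
dose = a·netOD + b·netODⁿ with a, b ≥ 0 and n free in [1, 3] — monotone,
through the origin, and verified monotone on a dense grid after fitting
(non-monotone inputs such as duplicate netOD at different doses are
rejected). netOD above the calibration range is clipped with a warning, not
extrapolated. No quenching correction is applied; for ratio statistics
normalized within one film this cancels anyway.

## What passing tests show — and don't

The synthetic fields reproduce the *structure* the analysis relies on
(periodic beamlets, valley background, along-beamlet gradient, depth-
dependent blur) with known ground truth, so the tests validate the
integrators, propagation machinery and sign/ordering arguments. They do not
validate the surrogate against measured film: peak-to-valley ratios, the
exact 8% offset responses, and the measured film pitch (see above) are
properties of the real beam that the generator only emulates in direction
and order of magnitude. Likewise the depth-dose surrogate supports the r80
procedure but carries no transport physics, and scored-dose inputs to
kimp/kgap are taken at face value.

## Problem sizes

Default analyses run on 600 dpi rasters (1701² pixels for the 72 mm field,
2646² with the 20 mm margin), 10⁶ Monte Carlo draws per axis for Type B
estimates, 0.1 mm depth grids, and 3001-sample traces; repeated-recovery
studies use 60–200 seeded repetitions. These sizes keep every statistic's
sampling error far below the tolerances asserted while running the whole
suite in well under a minute on one core.
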