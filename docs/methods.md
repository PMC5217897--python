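# Methods

This note documents the measurement models implemented in `gariqc`, the
defaults and why they were chosen, the numerical details, and what the
synthetic test bed does and does not establish about real lab data.

## Granulometry

Material shaken through a stack of nine sieves (125, 180, 250, 355, 500,
710, 1000, 1400, 2000 μm) plus a pan yields ten contiguous size classes.
Retained masses are normalised to mass fractions μ₃ᵢ; the cumulative
undersize curve accumulates them in ascending diameter.

* **Pan class bounds** are (0, 125 μm): particle diameters are physically
  non-negative, so the class midpoint used in the weighted mean is
  62.5 μm. **Oversize bounds** are (2000, 2800 μm) by default — 1.4× the
  largest mesh, continuing the ≈√2 progression of the sieve series; both
  are configurable through `SieveSpec`.
* **Median diameter**: the cumulative curve is taken piecewise-linear
  through the points (class upper bound, cumulative fraction) with
  (pan lower bound, 0) as the left anchor; the median is the 50%
  crossing. If the curve touches 0.5 exactly at a node, that node is
  returned (the lower end of any flat stretch).
* **Weighted mean**: Σᵢ (dᵢ₋₁+dᵢ)/2 · μ₃ᵢ over all ten classes.
* Sieving time (10 vs 15 min) is carried as metadata only; its effect on
  the distribution is not significant, and no correction is applied.
* Replicate summaries use the arithmetic mean and the sample (n−1)
  standard deviation; with one replicate the SD is reported as absent.

Degenerate inputs (zero total mass, class counts that do not match the
sieve spec) raise typed errors rather than propagating NaNs.

## Bulk density, swelling index, moisture

Simple two-reading ratios: BD = m/V (tapped volume), SI = V_sw/V_init,
h = (fwt − dwt)/fwt. The moisture form is the drying loss; the literal
dry/fresh ratio is mathematically its complement and is exposed only
behind `as_printed=True` for traceability, because for oven-dried gari it
yields ~0.91–0.96 instead of the observed few-percent moisture. A
swelling index below 1 (shrinkage) is physically unexpected for gari and
warns without rejecting. An optional 24 h check weight flags trials whose
relative 24 h → 48 h mass change exceeds 0.1% (not dried to constant
weight); flagged trials are reported, not dropped.

## Bomb calorimetry

A static-jacket instrument with m_W = 1000 g of water. The reduction has
three steps.

**Temperature rise.** The trace shows a fore (drift) period, the
combustion rise and an after period. Straight lines are fitted by least
squares to the fore and after periods and both are extrapolated to the
mid-rise time — the instant the trace crosses halfway between the two
lines; ΔT is the difference of the fitted lines there. This cancels any
linear drift common to both periods and is exact for step- and
drift-plus-step-shaped traces. Window boundaries are auto-detected: the
trace is boxcar-smoothed (60 s window) and a point counts as "rising"
when the centred-difference slope of the smoothed trace exceeds
5×10⁻⁴ K/s; the fore window ends and the after window starts twice the
smoothing extent outside the detected rise, which keeps the residual
exponential settle under the threshold out of the after fit. Explicit
window times override the detection. A full Regnault–Pfaundler integral
correction is deliberately not implemented. Known systematic: with an
exponential settle (τ ≈ 35 s) the extrapolated after line is biased by
~10⁻⁴ K, i.e. ≲ 0.01 kJ/g on a gari-sized charge — an order of magnitude
below the sensor-noise contribution — so the machine-precision round-trip
guarantee applies to the algebraic chain below, not to trace extraction.

**Calibration and sample values.** K = (H_B·m_B + H_I·m_I)/ΔT − m_W·c_W
from a benzoic-acid firing; then H_M = ((m_W·c_W + K)·ΔT − H_I·m_I)/m_M
and H_G = (H_M·m_M − H_F·m_F)/m_G. When a run manifest contains several
calibration firings their constants are averaged. Negative K or H_M are
flagged as warnings (miscalibration / failed runs), non-positive ΔT is an
error. Configuration defaults — benzoic acid 26 460 J/g and a ~1 g
pellet, ignition wire 50 J per firing, light fuel oil 45 400 J/g,
c_W = 4.184 J/(g·K) — are standard handbook values for this class of
instrument and are all overridable; they are configuration, not
constants, because certified values vary by lot. Energies are joules
internally; outputs report kJ/g.

## Cyanide

Photometric picrate elution: ppm = A₅₁₀ × 396, valid for the kit's
nominal 100 mg sample / 5.0 mL elution geometry. Off-nominal geometry
warns; an opt-in proportional rescaling (×100/mass × volume/5.0) is the
only dimensionally consistent extension and is never applied silently.
The 10-shade colour chart spans 0–800 ppm; since per-shade values are not
published, the default anchors are evenly spaced (configurable). Chart
classification returns the nearest anchor, ties breaking to the lower
shade (the conservative direction is deliberately *not* chosen here; the
chart is a rough screen either way).

## Titratable acidity

TTA% = 0.450 · V_NaOH[mL] / (1 − h), lactic-acid equivalents per 100 g
dry-corrected. The 0.450 coefficient is kept as the protocol's literal
constant for bit-compatibility; the suite re-derives it from first
principles (0.05 M NaOH, 20.0 mL aliquot of a 5.00 g/100.0 mL extract,
lactic acid 90.08 g/mol → 0.4504) and the two agree within 0.09%. The
moisture h is the per-sample mean from the moisture assay by default
(per-trial moisture is not generally available for the same aliquot); any
mapping sample → h can be passed to override. Acids other than lactic are
not speciated.

## Factorial analysis

Balanced 2×2 designs with r ≥ 2 replicates, decomposed by cell/marginal
means into grand mean, main effects, interaction and residuals; the
zero-sum constraints and exact reconstruction hold by construction. The
ANOVA partitions SS_total = SS_A + SS_B + SS_AB + SS_error with
df = 1, 1, 1, 4(r−1) and tests each source against the error mean square.
A zero error mean square reports F = ∞, p = 0 for sources with positive
SS. Alongside p-values the table carries a "probability" column
100·(1 − p), the complement-form significance statement used in field
reports. Unbalanced or k-way designs are out of scope.

## Synthetic data

The generator inverts each measurement model: declared truths are mapped
to the raw readings a perfect instrument would produce, then perturbed
with Gaussian noise **on the raw instrument scale**, truncated at
physical bounds (non-negative masses, volumes, absorbances; dwt ≤ fwt).
Noise defaults (SDs): sieve class mass 0.1 g; cylinder mass 0.01 g and
volume 0.2 cm³; soak volumes 0.3 mL; fresh/dry weights 0.01/0.02 g;
trace temperature 0.02 K per 1 s sample; absorbance 0.002; titration
volume 0.02 mL. They reflect the stated accuracy of the bench instruments
(±0.01 g balance, ±0.01 mL burette) inflated where handling dominates
(sieving losses, volume reading). Replication follows the survey
protocol: 4 sieving runs, 5 moisture, 4 calorimeter firings, 3 each for
density, swelling, cyanide and acidity.

Grain size is a mass-weighted lognormal (median, σ_ln) discretised onto
the sieve classes; calorimeter runs compute the ΔT implied by the
declared energies and emit a trace with linear drift (2×10⁻⁵ K/s),
exponential approach (τ = 35 s) and sensor noise, sampled at 1 Hz over a
600 s fore period and 900 s after ignition.

The `togo_maritime` preset declares 14 sample truths spanning the ranges
observed for south-Togo market gari (weighted mean ~591–934 μm implied by
medians 524–831 μm at σ_ln = 0.45; BD 0.560–0.680 g/cm³; SI 3.35–4.20;
moisture 4.65–9.05%; GCV 15.56–15.70 kJ/g; cyanide 0.4–3.2 ppm; TTA
0.62–1.55%). Truths sit at least ~3 replicate-mean noise SDs inside each
range endpoint (SDs measured by Monte Carlo under the default noise
model), so an in-range end-to-end run is a property of the declared
conditions rather than of a lucky seed. The preset is a demonstration of
the pipeline, not a reconstruction of any particular survey's values.

**What passing tests do and do not show.** The generator emulates
unbiased Gaussian instrument noise around an exact measurement model. It
does not emulate sample heterogeneity between replicates, sieve blinding
or attrition, incomplete combustion, drift in the picrate chemistry,
endpoint-detection bias in titration, or storage-driven moisture gain —
so parameter recovery here validates the *reduction arithmetic and its
statistical behaviour*, not the field accuracy of the lab methods.

## Problem sizes and numerics

Oracle-equivalence tests run 100–1000 random trials; calorimetry noise
recovery uses 200 simulated firings; the ANOVA type-I rate uses 2000 null
datasets (r = 4, σ = 0.03); the end-to-end demonstration reduces the full
14-sample preset (~70 trace files) — the whole suite completes in well
under a minute on one core. Fractions must sum to 1 within 1e-9;
decomposition reconstruction is exact to 1e-12; CSV output uses %.10g
formatting, comma delimiters and "." decimals regardless of locale, and
identical seeds yield byte-identical generated datasets.

## Known limitations

* ΔT extraction assumes drift that is locally linear and a
  single-rise trace; double firings or jacket disturbances are not
  detected beyond the failed-combustion (ΔT ≤ 0) check.
* Colour-chart anchor values are a guess (evenly spaced) pending the
  kit's actual shade calibration.
* The acidity moisture correction uses one h per sample; aliquot-level
  moisture variation is not propagated.
* No uncertainty propagation beyond replicate SDs; no nitric/sulfuric
  acid or net-calorific corrections in calorimetry.
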