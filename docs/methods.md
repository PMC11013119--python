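# Methods

This note records the models, estimators, defaults and numerical
choices behind `nanofilm`, and what validation on synthetic films does
and does not demonstrate.

## Scan images and conventions

A `ScanImage` is a rectangular grid of finite reals with an isotropic
pixel size in nm: heights in nm (`topography`) or contact-potential
values in mV (`potential`).  Row 0 is the top scan line; the column
index is the fast axis; pixel centres sit at `(i+0.5, j+0.5)·pixel_size`.
Operations that mix channels check the channel tag and refuse
mismatches.  The ASCII dialect is the whitespace-matrix shape common to
SPM exports, with `#`-prefixed `key: value` header lines
(`pixel_size_nm`, `channel`, `units`) that override caller-supplied
calibration; values are written with 9 significant digits (round trips
agree to ≤1e-8 relative).  Float TIFF is single-channel uncompressed
32-bit, bit-exact on round trip for float32 data.  The container
accepts grids down to 2×2 so that file round-trip checks stay cheap;
the analysis entry points require at least 8×8.

## Synthetic films

The generator emulates a phase-separated monolayer as a binary
high-phase mask plus rendering artifacts.  Two morphologies:

* **disks** — random sequential adsorption of non-overlapping disks
  and regular 5–8-gons (random rotation), radii lognormal
  (log-σ = 0.3) around the radius at which `n_domains` mean-area shapes
  reach the target coverage; placement stops once realized coverage is
  within ±0.02 of target, and candidate shapes that would overshoot the
  band are shrunk.  A bounded attempt count turns pathological targets
  into an error instead of a hang.
* **coagulated** — white noise smoothed with a Gaussian of 8 px
  correlation length, thresholded at the quantile matching the target
  coverage; gives irregular connected blobs resembling jointly
  coagulated domains.  Coverage is exact to quantile granularity.

Rendering: topography = base + Δh·mask + tilt plane + deposition
streaks + white Gaussian noise; potential = base + ΔV·mask convolved
with an isotropic Gaussian (the finite tip–sample averaging of KPFM,
default σ = 20 nm ≡ 2 px), plus white noise.  Streaks are ~rows/20
full-length Gaussian-profile ridges (widths 1–3 px, random amplitudes
up to the configured maximum) aligned with one axis, mimicking
Langmuir–Blodgett deposition striations.  The blur uses symmetric
reflection at the boundary, which preserves the image mean to machine
precision.  All randomness derives from the spec's single seed;
identical specs render bit-identical pairs.

Presets encode the three film compositions the analysis chain is
designed around: a pure-lipid control (disks, f = 0.27, 0.33 nm /
336 mV), a film doped with the short-tail 12-3-12 surfactant (disks,
f = 0.27, 0.28 nm / 304 mV — the short-tail species partitions poorly
into the film and barely perturbs it) and one with the long-tail
16-3-16 surfactant (coagulated, 0.57 nm / 658 mV).  The 16-3-16 film's
coverage is not quantified in the literature beyond "increased"; the
preset uses f = 0.35 as a realistic raised value.  Default noise
(σ_h = 0.05 nm, σ_v = 20 mV) and streak amplitude (0.05 nm) are
plausible instrument figures chosen once, not fits; real scans add
1/f scan-line noise, tip-shape convolution of the topography and
slow drift that the generator deliberately omits — recovery results on
synthetic films therefore validate the estimators' correctness and
statistical behaviour, not their performance on any particular
instrument's artifacts.

## Levelling

`level_image` subtracts a least-squares plane (order 1) or constant
(order 0); `per_line` additionally subtracts each scan line's median,
the standard streak correction.  Both background estimates accept an
exclusion mask (masked flattening): with protruding domains present, an
unmasked plane fit absorbs part of the step wherever domain placement
correlates with position, and an unmasked line median lands on the
*high* level in scan lines that are mostly domain, wrecking them.  The
pipeline therefore levels in two passes: a plane-only pass seeds a
first segmentation, whose mask excludes the domains from the final
plane + line-median fit.  Lines with fewer than 8 background pixels
keep their plane-only level.  A constant input returns a zero image
with a warning rather than an error.

## Coverage estimators

**Histogram method.** 256-bin histogram of the levelled image, smoothed
with a 5-bin moving average.  Candidate peaks are local maxima (plateau
tolerant, edges included); peak pairs at least 10 bins apart are tried
in order of combined height, and the accepted pair is the first whose
deepest intermediate bin falls below half the lower peak — noise
wiggles inside a single mode never pass this valley-depth test, so a
single-phase image raises `NotBimodal` instead of producing a sham
threshold.  Coverage is the fraction of pixels above the valley.

**Particle method.** Connected components (8-connectivity by default)
of the thresholded image; components below `min_area` (default 4
pixels) are discarded as noise; coverage is the retained area fraction.
With no size filter and the same threshold it is pixel-identical to the
histogram method, which the tests assert.

**Model average.** Mean of the two point estimates with margins
combined in quadrature, rounded to integer percent by default.  The
quadrature rule is an inference from the published coverage tables this
mirrors (it reproduces both printed combined margins); it treats the
two methods' errors as independent, which is optimistic since they
share the threshold.  For a single image the per-method margins are
zero; margins become meaningful when averaging repeat experiments.

## Cross-section contrasts

Profiles are sampled by bilinear interpolation at ≥16 equally spaced
points between two in-grid endpoints.  `step_delta` classifies samples
against the midrange value, drops a central exclusion zone (default 20%
of samples) around the crossing — the sample closest to midrange — and
returns `median(high) − median(low)`; medians make the estimate robust
to residual streaks and stray pixels, and the estimator is exactly
linear under affine rescaling.  A constant profile, or one whose
classes empty after exclusion, raises `NoStep`.

Profile placement mimics a careful operator: random boundary pixels of
the domain mask (seeded), profile direction along the local mask
gradient (smoothed with σ = 2 px), default length 400 nm.  Candidates
are rejected when they leave the image, cross more than one boundary,
or fail an isolated-step clearance test: every sample must be at least
`min(distance to crossing, 10 px) − 2 px` away from the opposite
phase.  The clearance test is what keeps the ΔV estimate unbiased under
tip blur — without it, lines passing near a neighbouring domain inherit
part of its blurred potential in their low plateau.  The cap reflects
that leakage beyond 5 blur widths is negligible; both parameters are
exposed.  The pipeline places profiles on a speck-cleaned mask
(components and holes ≤16 px removed) from the topography channel —
the sharper channel in this model — and reads the identical lines off
both channels, so Δh and ΔV come from the same locations.  Potential
profiles are taken from the raw image (no levelling); topography
profiles from the masked-flattened image.

Aggregation over n profiles reports mean ± t(1−α/2, n−1)·s/√n, a
Student-t interval at 95% by default (n is finite and modest; the
normal interval would be anticonservative).  n ≥ 2 is required; the
pipeline's default is 100 profiles per film.

## Electrostatics

The dipole-sheet relation is implemented verbatim in practical units
(V[mV] = 12π·μ⊥[mD]/A[Å²]) because the published worked values are
stated in those units; forward and inverse are exact inverses.  The
charged-sheet model V = zσ/2ε₀ (SI) is inverted for the surfactant
number density n = ε₀V/(z·e), i.e. σ = 2ε₀V/z divided by the 2e charge
of a gemini headgroup; a literal shorthand form εV/z that conflates
charge and number density circulates in the literature and is exposed
separately as `charge_density_literal` for auditability.  Constants:
ε₀ = 8.854×10⁻¹² F/m, e = 1.602×10⁻¹⁹ C, 1 mD = 3.33564×10⁻³³ C·m.
The surfactant-per-lipid ratio n·A keeps the tip height z as a free
parameter: z is not measurable from the images and published
order-of-magnitude claims about this ratio are not reproducible without
it, so the package exposes the calculation rather than asserting a
value.  The bundled literature fixture stores the published
(π, A, V, μ⊥, subphase) rows for pure DOPC and DPPC films;
`verify_fixture` recomputes every derived cell and the DPPC−DOPC
contrast rows (94 mV at 20 mN/m, 271 mV at 30 mN/m) and flags
disagreement beyond one unit in the last printed digit.

## Problem sizes and determinism

The pipeline's reference configuration is a 512×512 image (10 nm
pixels, a 5.12 µm scan) with 100 profiles; one full
generate-and-analyse run takes well under a second on one CPU, and the
parameter-recovery validation (3 presets × 10 seeds at 512×512) runs in
a few seconds.  Unit tests use 64–256 px grids with proportionally
fewer, larger domains so that 400 nm profiles still fit between
boundaries.  Every stochastic step (mask synthesis, rendering noise,
profile placement, hypothesis property tests) is explicitly seeded;
reports embed a hash of the analysis-relevant configuration, and
identical configurations produce byte-identical report files.

## Known limitations

* Two-phase films only: no multi-level segmentation or watershed
  splitting of merged domains.
* The step estimator assumes plateaus on both sides; continuously
  graded boundaries bias it low.
* Masked flattening depends on a sane first-pass segmentation; images
  whose histogram is not bimodal abort with `NotBimodal` rather than
  guessing.
* The generator's noise model is white and Gaussian; scan-line (1/f)
  noise, drift and tip-shape convolution of topography are not
  simulated.
* Absolute potentials are not calibrated — only contrasts between
  phases are meaningful, as in any single-probe Kelvin-probe
  measurement.
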