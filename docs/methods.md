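# Methods

## Measurement model

A plate of up to 18 seeds (6×3 grid of 1 cm wells on a matt black support)
is imaged by a line-scanning SWIR camera: a cube of ~200×320 pixels × 163
bands spanning 1,250–2,500 nm (≈7.7 nm spacing). Raw radiance is converted
to percent reflectance pixelwise against an image of a diffuse standard of
known reflectance $\rho$ (50% grey Spectralon or a 90% PTFE sheet):

    R(x, y, λ) = (raw − dark) / (reference − dark) × ρ,

with the dark frame optional and zero by default. Negative results clip to
0; pixels whose reference signal does not exceed the dark level are
invalid, stored as 0 and counted in the cube metadata and the log.
Reflectance is always carried in **percent**, never as a fraction: the SQI
construction below uses unit x-steps against percent y-values, so it is
deliberately not scale-invariant, and a percent/fraction mix-up would
change every index value (a test asserts this).

## SQI

SQI is the clockwise angle, in degrees, at the middle vertex of the
polyline through (−1, R1637), (0, R1734), (1, R1854), where the three
wavelengths are resolved to the nearest instrument band centers (at most
5 nm away by default — just above half the band spacing; ties break toward
the lower wavelength). The branch rule — angle when the center sits at or
below the flank mean, 360° minus the angle otherwise — is the reading
consistent with the clockwise-angle geometry and with continuity at 180°,
where the three points are collinear. The cosine is clamped to [−1, 1]
before the arccos to absorb floating-point overshoot. The x-axis uses unit
steps, not the physical 97/120 nm band offsets.

SQI_areal is computed mean-first: the seed's mean spectrum over its
(optionally margin-eroded) analysis mask, then SQI of the three mean
values. Because SQI is nonlinear in reflectance this differs from the mean
of per-pixel SQI, and a test pins the distinction. SQI_pixel is computed
independently per pixel over the full seed mask.

PBR (peak-to-base area ratio) at a threshold *max*SQI is the fraction of a
seed's pixels with SQI_pixel **strictly** below *max*SQI. The full seed
mask (margin 0) is the default PBR denominator; the margin is configurable.

Strictness convention: all selection comparisons are strict — SQI_areal <
*max*SQI, PBR > *min*PBR, SQI_pixel < *max*SQI — following the "lower
than"/"greater than" wording of the rules. The choice is centralised in
`seedsqi.sqi.STRICT_THRESHOLDS` and the rule implementations.

## Segmentation

Seed areas are pixels spectrally similar to a user-designated reference
area (supplied as rectangle coordinates, typically small boxes at the known
well centers; never interactively). Two similarity measures are provided:
the spectral angle mapper (scale-invariant; zero-signal pixels get the
maximal angle π) and Pearson cross-correlation (positive-affine-invariant;
flat pixels get 0). The thresholded mask is labeled by connected components
(default 8-connectivity), holes are filled unconditionally (seed areas are
closed), components below `min_area_px` (default 10 px, small relative to
the ~20–26 px seed diameters at ~106 ppi) are dropped, and components
touching the image border are dropped by default because their spectra are
unreliable. Labels are assigned in raster-scan order of each component's
top-left pixel. Margin erosion uses the Euclidean distance transform —
a pixel survives if its distance to the nearest background pixel exceeds
the margin — which is faithful to a metric margin on diagonal boundaries
where iterated 3×3 structuring elements are not.

The display smoothing filter is a 3×3 kernel with weight 2^(−d) at
Euclidean offset d (center 1, edge 0.5, corner 2^(−√2) ≈ 0.3752),
renormalised over in-mask pixels so constants are preserved at mask edges.
Smoothing is off by default and not used for selection statistics; it
exists for rendering SQI_pixel maps.

## Selection statistics and calibration

With N seeds of which N_OK are sound, and N_get selected of which N_get|OK
are sound: SR_init = N_OK/N, RR = N_get/N, SR = N_get|OK/N_get (undefined
when nothing is selected), YR = N_get|OK/N_OK (undefined when the lot has
no sound seeds), TER = (N_get + N_OK − 2 N_get|OK)/N. Undefined values are
reported as missing, never as 0. TER·N is the integer misclassification
count, and calibration minimises that integer, so optima compare exactly
with no floating-point ties.

*Single rule.* Candidate thresholds are the midpoints between consecutive
sorted distinct SQI_areal values plus one sentinel below the minimum and
one above the maximum. Every selection achievable by a threshold rule
appears exactly once in this sweep, so the sweep optimum is the exact
optimum (verified against exhaustive enumeration over all truth
assignments of lots up to 8 seeds). Among tied optima the smallest
threshold is chosen.

*Dual rule.* A grid search over [floor(min SQI_pixel), ceil(max
SQI_pixel)] × [0, 1] at steps of 1° and 1% (both configurable). All
TER-minimising cells are reported. The chosen pair takes the
per-coordinate mode of the optima, ties toward smaller values; when the
two modes do not coincide on an optimal cell the nearest optimal cell to
the mode pair is chosen instead, so the chosen pair is always itself
optimal. PBR is evaluated once per seed from its sorted pixel values by
bisection, making the full grid cheap.

*Cross-validation.* Thresholds calibrated on one lot are applied unchanged
to another; the self-application TER is the calibration error and the
transferred TER the validation error. Seeds with invalid regions
(over-eroded or border-touching) are excluded from calibration and
validation and noted in the log. The TER curve is returned rather than
assumed convex — its observed downward-convex shape is empirical, not
guaranteed.

## Synthetic plates

The generator emulates exactly the structure the method relies on, with
full ground truth (label raster, class table, per-pixel dip-depth map):

* geometry — 200×320 px, 3×6 grid, elliptical seeds with radii 9–13 px;
* spectra — a gentle linear baseline ramp (40% → 20% across the band
  range) for seed tissue, flat 5% background, and a Gaussian absorption
  dip (σ = 30 nm) centered at 1,730 nm;
* classes — sound seeds with dip depth 12–20% scaled radially by
  1 − (r/R)², so the dip (and the low SQI_pixel core) is strongest at the
  seed center; shibudane with a mild bump (negative depth); "others" flat;
* presets — *sugi-like* (well-separated SQI classes; unsound seeds
  spatially flat) and *hinoki-like* (weaker separation; unsound seeds
  carry a small radial dip of their own, 1.5–5%, the regime where PBR adds
  information and the dual rule helps);
* noise — additive Gaussian reflectance noise, default sd 1%, from an
  explicit rng seed;
* radiance — raw = reflectance / ρ × reference, with a smooth lamp-like
  reference spectrum and optional multiplicative vignetting, so
  calibration inverts the construction exactly.

Depth ranges, proportions and noise were fixed once to give class
separations comparable in character to the real lots (sound far below
180°, unsound at or above it) and are the standing study conditions for
the test suite. What passing tests show: the chain of calibration,
segmentation, index computation and threshold calibration is internally
consistent and recovers known truth under the stated noise. What they do
not show: performance on real seed spectra, whose baselines are curved,
whose noise is structured (scan-line and detector effects), and whose
class spectra overlap more than any preset here; absolute SQI ranges per
species are not emulated, only orderings and separability. The generator
makes no attempt at radiative transfer or biochemistry.

## Problem sizes and numerical choices

The test suite runs plates at the full 200×320×163 scale for the
end-to-end checks (a few seconds each) and smaller plates (70×120) for
Monte-Carlo property checks. Calibration grids default to 1°/1% steps.
All stochastic tests fix their rng seeds. ENVI I/O supports BSQ/BIL/BIP
little-endian rasters with the header keys samples, lines, bands,
data type, interleave, wavelength (nm); cubes round-trip bit-for-bit.

## Known limitations

* Touching seeds are not split (wells separate seeds physically); no
  watershed.
* No VNIR-range processing and no multivariate chemometrics — the index is
  the method.
* Germinable vs dormant sound seeds are not discriminated; the method
  targets anatomical soundness only.
* The single-file ENVI reader covers the common header subset, not every
  dialect extension.
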