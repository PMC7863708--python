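# Methods

## Regional gray-level statistics

A region of interest is a manually drawn closed polygon (vertices in 0-based
pixel coordinates, origin top-left). It is rasterized with the even–odd rule
sampled at pixel centers, with boundary-center pixels counted as inside; the
rule is deterministic, orientation-independent, and translation-equivariant
on the integer grid. Rasterizing a polygon that encloses no pixel center is
an error rather than an empty region.

For the pixels inside the contour the package reports n, min, max, mean,
sample standard deviation, and the gray-scale median (GSM). The GSM of an
even-sized region is the mean of the two central order statistics (so values
ending in .5 occur); it is carried downstream at full precision and never
rounded. Zero-level pixels are *not* excluded from any statistic.

## Brightness ranges

The 14 "virtual histology" bands are closed intervals `[lo, hi]` that must
tile `[0, 255]` exactly; the configuration loader and the CLI refuse
non-tiling bands. The built-in default places the 15 cut points at
`round(256·i/14)` (i = 0…14), giving 14 contiguous bands of width 18–19, each
with a probable-tissue label (anechoic fluid through calcification-like) and
a dark-to-bright display color ramp. Because the canonical boundaries of this
analysis tradition are tied to specific acquisition set-ups and are expected
to be recalibrated per application, they live in the JSON config file; every
output row records which band source was used (`config` vs
`fallback-uniform`).

A region's brightness distribution assigns every pixel to exactly one band;
counts sum to n and percentages to 100 within 1e-9 by construction.
Pseudocolor rendering replaces in-region pixels by their band color and
leaves the rest of the image as the original gray.

## Fascia-anchored normalization

With `medF0` the GSM of the segmented posterior-fascia region, the factor is
`Fn = |medF0 − 200| / medF0` and the transfer `f(r) = r(1 + Fn)` for
`medF0 ≤ 200`, `f(r) = r(1 − Fn)` otherwise — algebraically the single map
`r ↦ r·200/medF0`, which the exact-factor policy evaluates directly so that
half-integer rounding boundaries are bit-reproducible. The absolute value is
deliberate: the signed form `(medF0 − 200)/medF0` would darken images whose
fascia is *below* the anchor instead of brightening them, defeating the
purpose of the reference; the signed variant remains available behind
`signed_literal=True` purely for auditing.

Two rounding policies exist. `exact_factor` (default) uses Fn at full
precision. `paper_compat` rounds Fn to two decimals before the transfer,
reproducing the prototype convention in which the factor is reported at two
decimals (medF0 = 220 → Fn = 0.09 → f(50) = 45.5 → 46). Pixels are always
rounded half away from zero — the only disambiguation consistent with
45.5 → 46 — and clipped to [0, 255]; the number of clipped pixels is recorded
in the normalization metadata.

Consequences the test suite verifies:

- the transfer is monotone non-decreasing, so within-region rank order (and
  hence the median's order-statistic position) is preserved;
- for an odd-count fascia region the post-normalization fascia GSM is
  exactly 200 under `exact_factor`;
- a second normalization changes no pixel by more than one gray level
  (the re-measured fascia median can move at most 0.5 by rounding, bounding
  the residual factor by 1/200).

## Synthetic phantom

The phantom emulates the first-order gray-level structure of a renal scan:
a dark background (mean 40), a kidney ellipse of cortex (mean 90) around a
brighter sinus ellipse (mean 150), and a bright posterior fascia band (mean
220), on an 800×600 raster. Speckle is multiplicative and unit-mean:
`s = (1 − a) + a·R` with R a unit-mean Rayleigh variate and
`a = speckle_scale ∈ [0, 1]`, so `a = 0` is the exact noiseless limit and
`a = 1` fully developed Rayleigh speckle. The default `a = 0.3` keeps the
sample GSM of a region within a few gray levels of its configured mean
(fully developed speckle would displace the median to ≈ 0.94 of the mean,
which is stronger than the post-processed B-mode texture this phantom
emulates). Each pixel is `clip(round(region_mean · s))`. The fascia band is
forced to an odd×odd pixel footprint so its pixel count is always odd.

`phantom_with_fascia_gsm` constructs a phantom whose *realized* fascia GSM
equals a requested integer exactly: the speckle field is fixed by the seed
and the fascia mean is bisected (the realized median is monotone in the
mean) until the sample median lands on the target. This builds a stated
input condition deterministically; it does not touch the analysis path.

Study simulation produces one image per patient × side × physician × method.
Patient anatomy is a persistent normal perturbation of the four region means
(sd 6 gray levels, shared across all of that patient's acquisitions);
operator/device bias is a linear gain and offset applied to the synthesized
amplitudes — in full under the `random` method, replaced by the fixed
study-wide preset (gain 1, offset 0) under `standardized`. Random streams
derive hierarchically from (study seed, patient, side, crc32(physician id)),
so extending the physician roster leaves existing images bit-identical, and
a physician's random and standardized scans of one kidney share a speckle
field (a null operator effect therefore makes the two methods produce
identical images). What the phantom does **not** model: depth-dependent
attenuation and TGC curves, beam geometry, shadowing, anisotropy — passing
tests validate the measurement/statistics pipeline, not ultrasound physics.

## Operator statistics

Each image category is compared across operators (or devices) on 15
variables: the GSM and the 14 band percentages, the latter treated as
continuous. Per variable: a Kruskal–Wallis H test (mid-rank ties,
tie-corrected H, chi-square reference with k−1 df; all-identical data is
defined as H = 0, p = 1), then a two-sided Wilcoxon–Mann–Whitney test for
every group pair, run regardless of the omnibus outcome. The rank-sum test
uses the exact null distribution (dynamic-programming count of the
Mann–Whitney U) when both samples have n ≤ 25 and no ties, and otherwise the
normal approximation with tie and continuity corrections. Anderson–Darling
normality uses the estimated-parameters case with the small-sample
correction `A² (1 + 0.75/n + 2.25/n²)` and the standard piecewise
exponential p-value approximation. No multiple-testing correction is applied
across variables or pairs — the protocol reports uncorrected tests at
α = 0.05 and prints the number of tests performed. Note the protocol treats
repeated images of the same patients by different physicians as independent
samples; the package follows that protocol without endorsing it (shared
patient effects make the between-operator tests conservative under the
null).

## Problem sizes and numerical choices

Replicate-heavy statistical checks (the headline pattern over 50 simulated
studies; type-I-error calibration over 2000 simulations per test) run on
reduced 160×120 phantom rasters: the group statistics consume one GSM and 14
percentages per image, which are insensitive to raster size, while the
phantom default stays 800×600. Rasterized masks are memoized per (geometry,
size) since a simulated study reuses a handful of ROI shapes across hundreds
of images. All randomness flows through `numpy.random.Generator` seeded
hierarchically from a single study seed; identical inputs and seeds yield
byte-identical outputs, including CSV tables.

## Known limitations

- Band boundaries are a uniform fallback tiling unless configured; analyses
  meant to match a specific clinical calibration must supply their own
  ranges.
- One-point normalization rescales multiplicatively only; it cannot remove
  additive offsets (a two-point scheme anchoring a dark reference at 0 is
  out of scope by design).
- The exact rank-sum path is limited to n ≤ 25 per group without ties;
  beyond that the asymptotic approximation is used.
- The phantom's operator model (linear gain/offset) is the simplest
  mechanism producing between-operator heterogeneity; real consoles apply
  nonlinear gray-scale compression.
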