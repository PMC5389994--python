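# Methods

## Receptor model

The modelling chain is the classical receptor-level account of early bee
vision: quantum catch, von Kries adaptation, saturating response.

* **Quantum catch.** P = R · Σ_λ I_s(λ)S(λ)D(λ), summed over the shared
  wavelength grid. Integrals are plain discrete sums with uniform weight;
  the grid-spacing factor cancels between the catch and the sensitivity
  factor, so it is omitted throughout.
* **Von Kries adaptation.** R = 1/Σ_λ I_B(λ)S(λ)D(λ). Each receptor
  rescales its gain independently to the prevailing background in its own
  spectral domain. Two contracts follow and are enforced by tests: the
  background stimulus yields E = 0.5 exactly (the implementation divides by
  the background catch computed with identical arithmetic, rather than
  multiplying by a stored reciprocal, precisely so this holds to the last
  bit), and rescaling the illuminant by any c > 0 leaves every response
  unchanged to machine precision.
* **Response.** E = P/(P+1), dimensionless in [0, 1), half-maximal at the
  adaptation point. No receptor-specific half-saturation constant is used:
  the adaptation state already plays that role. The saturation compresses
  relative differences at high catch — this is the third ingredient of the
  L-channel story and is verified numerically in the sweep tests
  (CV(E) ≤ CV(P) wherever mean P > 1).

**Default adaptation state.** Illumination is CIE D65 (packaged as the
standard 10-nm relative SPD over 300–700 nm; every analysis band falls on
that grid, so resampling is exact). The background is the mean of the leaf
regions actually present in the analyzed image set; when no leaf regions
exist the packaged synthetic green-leaf curve (dark in the UV, rising to
0.45 at 700 nm) is used and a warning logged. One adaptation state is shared
across all images of a run.

## Spectra and sensitivities

All spectra live on a common strictly-increasing wavelength grid, by default
the seven filter peaks 340, 400, 460, 520, 580, 640, 700 nm. Resampling is
linear with extrapolation forbidden — with only seven points, higher-order
schemes would invent structure. The low-resolution grid is adequate for
spectrally smooth stimuli: a test compares responses computed at 1-nm and
7-band resolution for broad Gaussian reflectances and finds them within 5%
relative. Narrowband stimuli (features ≲ 60 nm wide) are outside what the
grid can represent.

Receptor sensitivities default to the Govardovskii et al. (2000) A1 pigment
template for the alpha band (peak value 1 before normalization; width grows
with peak wavelength) plus a Gaussian UV beta band centered at 340 nm with
σ = 25 nm. Beta amplitudes default to S: 0, M: 0.1, L: 0.25 — the UV
secondary peak grows as the main peak shifts to longer wavelengths; when a
template is built at an arbitrary peak (the factor sweep), the amplitude is
interpolated linearly through those anchors. Summed sensitivities are
normalized to user-specified relative totals, default 1:1:1 (the true
relative totals of the bee receptors are not published); normalization
rescales each curve so its grid sum equals its weight, which keeps shapes
exact and makes the operation idempotent. Measured sensitivities can be
loaded from CSV and normalized the same way.

## Image pipeline

* **White balance** maps, per band, the darkest pixel inside the
  gray-reference rectangle to 0 and the lightest to 1 (affine, clipped).
  The reference strip — not the whole image — is the authority; ties break
  row-major. Pixel values are treated as linear reflectance afterwards; the
  correction fixes the endpoints of a gray scale and asserts nothing about
  sensor nonlinearity.
* **Alignment** is translation-only at integer pixels: exhaustive
  normalized cross-correlation over a ±max_shift window against the band
  nearest 520 nm (mid-spectrum, typically the strongest reflectance signal,
  hence the best correlation contrast). Out-of-frame pixels are zero-filled
  and dropped from the stack's validity mask; pixel values are never
  altered, only moved. A best shift on the window edge logs a
  residual-misalignment warning; a constant band logs a skip and keeps the
  identity shift.
* **Sampling** draws n = 1000 uniform random pixels per region, without
  replacement when the mask allows, with replacement (logged) otherwise;
  fully reproducible under a seed.
* **Rendering** is pure: false color (bee mode maps the 580/460/340-nm
  bands to R/G/B — UV becomes blue, blue green, yellow red; human mode maps
  640/520/460), 8-bit heat maps of E (round-half-up), and ommatidium-scale
  downsampling that partitions the image into an aspect-preserving grid of
  ≈ n_facets blocks (the honeybee eye has roughly 5000 facets) and replaces
  each block by its mean.

## Region statistics

SNR = mean(E)/SD(E) over a region's sampled pixels, per receptor — a
within-object homogeneity measure, not photon noise. SD is the population
convention (divide by n), stated in output metadata; note that published
figure captions in this literature sometimes say "standard error" where the
stated definition is mean/SD — this package follows the mean/SD definition
and does not silently reconcile the two. Zero-variance regions get an
infinite-flagged SNR, excluded from aggregation with a logged count.
Responses to a region's *mean spectrum* are exposed separately from the
mean of per-pixel responses; the two differ under the saturating response
(Jensen's inequality) and both are legitimate summaries with different
meanings. Channel comparisons use Kruskal–Wallis across the three
receptors' SNR samples plus pairwise Wilcoxon signed-rank tests paired by
species; no multiplicity correction by default (a Holm adjustment is
available behind a flag and reported alongside raw p-values). Comparisons
refuse to run on fewer than five species.

## Null-model factor sweep

The null model uses flat unit background reflectance, flat unit
illumination, and a one-hot "sensitivity" that samples exactly one band.
The one-hot reading of "unit sensitivity" is deliberate: an all-ones
sensitivity would make every peak's response identical by construction and
the sweep would be uninformative. Random reflectance spectra are i.i.d.
Uniform(0, 1) per band (a Beta alternative is available); petal-like
spectra come from the synthetic generator (or from CSV when real
per-species means exist). Each factor — D65 illumination, average-leaf
background, template sensitivities, petal reflectances — is switched on in
all 16 combinations; per combination the peak is swept across the 7 bands
and mean/SD of P and E recorded over one shared set of input spectra (so
rows differ only through the factors). Template sensitivities in the sweep
are normalized to equal totals across peaks.

## Synthetic scenes

The generator emits schematic scenes — center disc, petal annulus, leaf
background, gray strip of ≥ 5 patches spanning 0–1 identically in every
band — with the statistical structure the analysis assumes, not botanical
realism:

* Region mean curves are linear in wavelength: petal 0.10 → 0.78, leaf
  0.06 → 0.45, center 0.05 → 0.40. Everything reflects more light at long
  wavelengths; petals are brightest at every band; leaves and centers are
  disproportionally dark in the UV/blue. Levels were chosen once so that
  desk-scale SNRs land in the single-to-low-double-digit range typical of
  this kind of imagery.
* Per-pixel Gaussian band noise, clipped to [0, 1], with SD nondecreasing
  in wavelength (petal 0.030 → 0.050, leaf 0.050 → 0.080, center
  0.050 → 0.090); petals are the most homogeneous region.
* A band-shared additive blocky texture field (amplitude 0.03, block 3 px)
  models shading/surface structure common to all bands. It is what makes
  cross-band registration well-posed — without any shared fine-scale
  structure, a one-pixel misregistration would be statistically
  unidentifiable in the darkest bands — and it adds cross-band noise
  correlation, which real scenes also have.
* Random spectrum draws are cumulative (jittered base level plus
  nonnegative jittered increments), so single draws are nondecreasing in
  wavelength by construction and the SD of repeated draws grows with
  wavelength automatically.
* Across species, petal curves get a short-wavelength-weighted offset
  (SD 0.08, profile 1 → 0.15 across the grid, capped at ±0.2 to preserve
  monotonicity): flower colors spread out most in the UV/blue. All classes
  get a small overall level jitter (SD 0.02).
* Scan distortion: per-band affine gain (0.65–0.90) and offset (0.02–0.08),
  chosen to keep distorted values inside [0, 1], and integer band shifts up
  to ±2 px; the band nearest 520 nm is never shifted, being the
  registration reference. The strip's extreme patches sit at exactly 0
  and 1, so after clipped noise the darkest/lightest reference pixels are
  exact and white balance inverts the distortion exactly (to quantization
  when written as 8-bit PNG).

What passing desk-scale tests show — and what they do not: the synthetic
scenes reproduce the *sign structure* of the real analysis (SNR ordering
S < M < L in every region class, petal SNRs several-fold above leaf/center,
null-model sweep patterns), because that structure follows from the
modelling chain plus the qualitative reflectance statistics the generator
encodes. They do not reproduce full-scale magnitudes, which depend on the
actual photographs, measured sensitivities and true relative receptor
totals; magnitude-level checks require pointing `run_database` at the real
image database.

## Problem sizes and numerical choices

Default study size is 30 species at 160×160 px, 1000 pixels per region, and
10,000 random spectra in the sweep — sizes at which every Monte-Carlo
property asserted in the tests is stable across seeds. Alignment searches
±(shift range + 2) px exhaustively. NCC ties break toward the smaller
displacement (then lexicographically). Degenerate inputs fail loudly:
zero-overlap adaptation, zero-range gray reference, empty masks, grids
mismatched between stack and receptor set. Population-SD computations
return exactly 0 for constant input so the infinite-SNR flag is reliable.

## Known limitations

* Template sensitivities approximate, not reproduce, measured bee
  receptors; relative receptor totals default to 1:1:1 for lack of
  published values. Both are overridable from CSV.
* Bands are treated as point samples at the filter peaks; real filters have
  finite bandwidths.
* Translation-only integer registration; no rotation, scale, or subpixel
  refinement, and no lens/vignetting or film-response correction beyond the
  gray-scale affine fix.
* The model stops at the receptor level: no opponent coding, color spaces,
  or receptor-noise-limited discrimination.
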