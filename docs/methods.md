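# Methods

## Optical model and stain separation

Chromogenic brightfield stains absorb light multiplicatively, so stain
amounts combine additively in optical density (OD): a pixel renders as
`I_c = round(255 · 10^(−Σ_s M_{c,s} A_s))` per RGB channel `c`, with `A_s`
the planted/true OD of stain `s`. `M` is the fixed H-DAB matrix
(hematoxylin ≈ (0.650, 0.704, 0.286), DAB ≈ (0.269, 0.568, 0.778), both
normalized to unit length; residual = normalized cross product). The
matrix is user-overridable, but no stain-vector estimation from the image
is attempted. Unmixing computes `OD_c = −log₁₀(max(I_c, 1)/255)` and
`A = M⁻¹·OD`, clamping negatives to zero.

**Quantization limits.** The renderer quantizes once to 8 bits; ODs are
clipped at 3.0 (transmitted intensity < 1 unit). Round-trip accuracy of
render→unmix is therefore bounded by intensity rounding: for single-stain
pixels up to OD 1.5 the recovered OD is within 0.02; for two-stain
mixtures the bound degrades as the darkest channel approaches a few
intensity units — at the extreme (hema, DAB) = (1.5, 1.5) the green
channel renders at 3/255, where half-step rounding corresponds to ±0.073
OD after matrix inversion. No decoder can beat this: the set of ODs
consistent with the observed 8-bit triple is that wide. The test suite
asserts the measured bounds (0.02 for single stains and for mixtures up
to OD 0.8 per stain; 0.08 across the full (0, 1.5)² square).

**Inverted gray.** Downstream intensity measurements use
`gray = 255 − round(255·10^(−OD))`, i.e. the 8-bit appearance of that
stain alone on white, inverted so larger = more stain (OD 0 → 0,
OD 1 → 229, OD ≥ 3 → 255). This keeps 8-bit histograms monotone in stain
amount with a fixed, documented scale.

**Auto-threshold.** Implemented as Otsu's between-class-variance
maximization. Interactive tools often default to an IsoData variant; on
the near-bimodal hematoxylin/DAB histograms this assay produces the two
are practically identical, and Otsu is unambiguous to specify. The
nuclear mask dilation radius defaults to 5 px (≈1.4 µm at 0.27 µm/px), a
one-to-two-cell-border margin; no authoritative value exists for it.

**Display rescale.** A brightness/contrast adjustment to the 0–235 range
is part of the zonation measurement path (applied to each RGB channel
before unmixing there, `rescale=False` to disable) because that assay is
defined on display-adjusted images; all other quantification paths use
raw intensities, and gamma adjustments are never applied before
quantification.

## Specificity (S/N) index

WT and KO sections stained in the same run are unmixed; the WT
hematoxylin channel is auto-thresholded and dilated to define the tissue
mask; DAB inverted-gray histograms inside the mask are normalized to
frequencies (so section-area differences cancel) and ratioed bin-by-bin
with a shared pseudocount ε (default: one count at the smaller sample,
1/min(n_WT, n_KO)), keeping the curve finite and making the identical
case exactly 1. The scalar index is `Σ_i w_i·ratio_i` with
`w_i = i/Σ_j j`: zero-intensity bins carry no stain information and
high-intensity bins — where specific chromogen concentrates — dominate.
The weighting is a declared convention of this package (the assay it
reproduces never published one); comparisons between protocols are
therefore relative, and the batch API reports indices normalized to the
batch maximum alongside raw values.

## Zonation

Profiles sample the inverted-gray DAB channel every 1 px of arc length
along a polyline axis; at each sample the value is the mean over
0.5-px-spaced bilinear samples spanning the 27.4 µm line width (≈2 cell
widths) perpendicular to the local direction. Axis positions are
normalized to [0, 1] before cross-axis averaging because anatomical axes
differ in length. LOWESS uses tricube-weighted local linear regression
with 2 robustness iterations and span 0.3 — smooth at ~100 samples
without flattening crypt-tip structure; both pooled-datapoint and
averaged-profile fitting are possible since the fit takes raw (position,
value) points. Group comparison runs per-grid-position pooled-variance
two-tailed t-tests without multiplicity correction (reported
per-position). Positions where both groups are constant and equal report
t = 0, p = 1; constant but different (pathological zero-variance
separation) are flagged NaN.

## Object scoring

Nuclei: Otsu threshold of the hematoxylin gray → hole fill → 8-connected
components → area filter (default 5–400 µm²) → morphometrics.
Circularity `4πA/P²` uses the Crofton perimeter estimator; the naive
pixel-edge perimeter makes a perfect digital disk measure ≈0.78, while
Crofton gives ≈0.97, so a 0.95 disk sanity bound is meaningful.
Classification cuts default to 40 µm² area and 0.8 circularity
(hepatocyte nuclei ~8–10 µm and round; Kupffer nuclei small and
elongated); both inclusive for the hepatocyte side, both exposed in
config. Cytosolic signal is the mean DAB gray in a ring (default 1.5 µm)
around the nucleus, excluding all nuclei; "per unit area" equals the mean
intensity (sum/area), with µm² as the default area unit. Vessel scoring
auto-thresholds the wall-stain channel inside a user seed box, keeps the
largest component, requires ring topology (an enclosed lumen), and
measures DAB in a band (default 2 µm) just interior to the ring — the
luminal face where endothelium lies; the alternative reading (the ring
itself) was rejected because smooth muscle surrounds, not includes, the
endothelium. Percent-positive area counts region pixels with gray in
[lo, hi] (defaults 50–255).

## Puncta

DoG band-pass with σ_small = 1.2 px and σ_large = 2σ_small targets spots
of 2–6 px diameter, near the resolution limit of 20×/0.8 NA brightfield
scanning. Local maxima above an absolute floor of 2 gray units (a
technical guard against quantization maxima, applied before any
biological filter) become candidates; non-maximum suppression radius is
2σ_small. A punctum belongs to the cell label at its maximum; background
maxima are discarded. Amplitude is the mean original-image gray over a
disk of radius 2σ_small. Acceptance requires amplitude strictly greater
than 2× the parent cell's mean; the cell mean includes punctum pixels by
default (the literal reading of the rule), with an option to exclude
candidate footprints. Cell segmentation is pluggable — any label image is
accepted — because production segmentation (generalist cell models,
epithelium models) is out of scope.

## Expression scores

Percent expressing is the fraction of cells per (ontology, tissue) group
with value > 0, as a percentage. Zone scoring sums each zone's marker-gene
log-fold changes per cluster; clusters scoring ≥ X% of the zone's maximum
(X ∈ {50, 75}, chosen by expected within-zone transcriptional variance)
are eligible, and the top 5 by score are selected, ties broken by
ascending cluster id. "Within the Xth percentile of the maximum" is read
as percent-of-maximum, not a distribution percentile — a distribution
percentile is incoherent for the small cluster counts this rule serves.
Zone aggregation sums selected-cluster log-fold changes per gene rather
than re-running differential expression, because the module operates on
provided matrices, not raw counts; if no cluster scores above zero the
selection is empty and flagged.

## Synthetic scenes: what they emulate, and what not

Scenes plant elliptical counterstained nuclei, cytoplasmic DAB (uniform,
linearly graded along an axis, or per-cell), isotropic Gaussian puncta,
and annular vessels (wall stain on the counterstain channel, endothelial
DAB in a band inside the wall), mixed by the same Beer–Lambert model the
unmixer inverts, quantized once to 8 bits. Knockout renderings zero every
target-specific DAB term and keep counterstain and background — matched
geometry, same seed. Optional additive Gaussian intensity noise (σ = 1
unit) is off by default so exact expected values hold.

Study-condition builders fix the scenarios used in tests and in
`scripts/acceptance.py`: ~40-nucleus fields at 0.27 µm/px for
specificity; specific-DAB amplitudes {0.1, 0.2, 0.4, 0.8, 1.2} for
monotonicity; hepatocyte-like (semi-major 4–5 µm, axis ratio ≥ 0.9) vs
Kupffer-like (≈3 µm, ratio ≈ 0.33) populations; 20 profiling axes per
gradient scene; puncta of σ = 1.5 px placed ≥ 4σ_large apart with peak
ODs calibrated by bisection so their measured footprint amplitude is
exactly 3× (planted) or 1.5× (decoy) the parent cell mean, straddling the
2× rule from both sides; percent-area scenes with six non-overlapping
DAB⁺ disks covering an analytically known 7.5% of the region.

Synthetic scenes do **not** model scanner optics (blur, chromatic
aberration, vignetting), stain texture or heterogeneity within
structures, tissue autofluorescence/background gradients, touching or
overlapping nuclei, or stain-vector variation between runs. Passing tests
therefore demonstrate correctness of the measurement chain under the
stated optical model — not robustness to real-slide artifacts, which
requires knockout-controlled tissue.

## Numerical choices and degenerate inputs

- Constant images cannot be thresholded (error), and empty masks/regions
  are errors rather than NaN results.
- Per-pair and per-sample failures in batch APIs are recorded and
  isolated, never silently dropped; flagged records (empty cytosolic
  ring, ringless vessel seed, zero-variance positions) carry an explicit
  flag column.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); rendering and the batch pipeline are
  bit-deterministic given spec/config, and every pipeline output embeds
  the config hash that produced it.
- Problem sizes in tests and the acceptance script (128–400 px scenes,
  100 seeded puncta scenes, 200 random score matrices, 500 cells per
  expression group) were chosen as the smallest sizes at which the
  checked properties are non-trivial and stable.

## Known limitations

- At most 3 stains; two-chromogen assays (e.g. brown + pink DAB products)
  are emulated structurally by placing the second stain on the
  counterstain channel, not spectrally.
- The specificity-index weighting is a convention; absolute index values
  are not comparable across packages, only rankings within a batch.
- Mixed-pixel OD recovery degrades beyond ~OD 0.8 per stain (see
  quantization limits above); quantitative per-pixel OD claims should be
  restricted to that range on 8-bit input.
- The built-in nuclei-seeded cell segmentation (label expansion from
  segmented nuclei) is intentionally simple; dense or touching cells need
  an external segmenter supplying label images.
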