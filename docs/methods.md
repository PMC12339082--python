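# Methods

This note documents the models implemented in `osteoquant`, the choices
made where the underlying measurement protocols leave details open, what
the synthetic phantoms do and do not emulate, and the package's known
limitations.

## Gray-level calibration

qBEI gray values are linear in backscattered intensity and, over the
compositional range of bone, approximately linear in calcium content. The
calibration is a two-stage affine map:

1. *Session normalization.* The gray levels measured on the pure carbon and
   aluminum standards are mapped onto canonical positions (defaults 25 and
   225). This absorbs gain/offset drift of the detector chain between
   sessions; any pair of measured standards with aluminum brighter than
   carbon is admissible.
2. *Calcium scale.* Canonical gray converts to calcium as
   `Ca = s·(GL_canonical − GL₀)` with slope `s = 0.17` wt%Ca per canonical
   step and zero-calcium offset `GL₀ = 25` (the carbon anchor: carbon
   contains no calcium). One canonical gray step therefore equals one BMDD
   bin, which is why the histogram resolution is 0.17 wt%Ca.

All four constants live in `CalibrationConstants`. Negative calibrated
values (organic material darker than the zero point) are clipped to 0
rather than treated as errors — such pixels are below the mineralization
threshold in every downstream step. Values above 45 wt%Ca (beyond pure
hydroxyapatite) indicate a broken calibration and raise. Off-sample pixels,
when a sample mask is supplied, are carried as NaN; without a mask the
5.2 wt%Ca mineralization threshold performs the background separation.

## BMDD

The BMDD is the histogram of calcium content over mineralized pixels
(Ca ≥ 5.2 wt%Ca by default, the same boundary used to binarize the image
for lacuna analysis), normalized to percent of contributing area. Bins are
half-open `[k·w, (k+1)·w)` anchored at 0 with `w = 0.17` wt%Ca. Because
integer gray levels calibrate onto exact multiples of `w`, the bin-index
computation adds a 1e-9 guard so each gray level falls into exactly one bin
(without it, floating-point jitter scatters a quantized level across two
adjacent bins and the histogram develops a comb artifact). The guard biases
nothing for continuous-valued input.

Descriptors:

* **CaMean** — frequency-weighted mean of bin centers. For gray-quantized
  input this carries a fixed +w/2 offset relative to the quantized levels
  themselves (each level sits at its bin's lower edge); it cancels in any
  within-pipeline comparison.
* **CaPeak** — center of the maximal bin; exact ties average the tied
  centers. No smoothing is applied: determinism is preferred over
  cosmetics, and the descriptor is used comparatively.
* **CaWidth** — full width at half the peak frequency, linearly
  interpolated between bin centers with virtual zero bins at both ends,
  using the *outermost* half-max crossings so that noisy multi-modal curves
  yield a stable, conservative width. A single-bin curve has width `w`.
* **CaLow / CaHigh** — area fractions below the 5th / above the 95th
  calcium percentile of a reference BMDD. The reference pools curves by
  unweighted per-sample mean (each animal counts equally regardless of bone
  area, matching the per-animal cohort statistics), and percentiles are
  read off the pooled cumulative distribution treating each bin as uniform
  over its extent. Bins straddling a percentile are apportioned linearly —
  with the consequence that a curve evaluated against a reference built
  from itself returns CaLow = CaHigh = 5% exactly, a property the tests
  assert. The cohort pipeline builds the reference from the wild-type
  metaphyseal curves of each age group.

## Histomorphometry

All structural measures work on the binary mineral mask (Ca ≥ 5.2 wt%Ca;
off-sample pixels are never mineralized). The bone long axis is the image
vertical, metaphysis downward; coordinates are 0-based row-major and all
band intervals half-open.

**Band detection and front.** The growth plate appears as a transverse run
of rows whose mineralized fraction is at most `band_frac` (default 0.08 —
tolerant of partial bone bridges, yet below the mineral fraction of the
sparsest trabecular compartment the pipeline must distinguish from the
band). The mask is first opened with a 3×3 structuring element to suppress
single-pixel noise; the opening is exact for smooth boundaries whose
staircase treads are ≥ 3 px. Per column, the metaphyseal front is the first
mineralized pixel below the band core. Columns are invalid if they are
mineralized inside the band core (bridges), never mineralize below it, or
mineralize only far beyond the band core (`overhang_frac`, default half the
band thickness) — the latter rule rejects open marrow channels whose first
mineral belongs to deeper structures, not to the band boundary. For ROI
construction, invalid columns receive interpolated front values from their
valid neighbors.

**Band ROIs.** Primary spongiosa: `[front, front + 500 µm)` per column;
secondary: the following 1000 µm. Depths are rounded to the nearest pixel
count (568 and 1136 px at 0.88 µm/px). Bands clipped by the image border
emit a warning; fully outside raises. A lateral `column_range` excludes the
cortical bands from trabecular ROIs (the pipeline default margin is 80 µm,
covering the 60 µm cortex plus a buffer).

**BV/TV** is the mineralized pixel fraction of the ROI, with areas reported
in µm².

**Tb.Th** is the area-weighted mean of the 2D local-thickness field: for
each mineralized pixel, the diameter of the largest inscribed disc
containing it. The field is computed by sphere-covering on the Euclidean
distance transform: a pixel at EDT value `d` seeds a disc of integer radius
`⌈d⌉ − 1` (the largest integer radius that provably fits) with diameter
`2⌈d⌉ − 1` px; discs are painted in descending radius order. Everything
outside the raster counts as background, so no disc extends past the
border, and the analysis window around an ROI is padded by twice the
largest disc radius so boundary-crossing structures keep their true
thickness. The estimator matches an exhaustive inscribed-disc search
exactly on integer-EDT geometries and within one pixel elsewhere; a slab of
width `n` px measures `2·⌈n/2⌉ − 1` px, i.e. exact for odd widths and one
pixel low for even widths. This ≤ 1 px bias is shared by both cohorts in a
comparison and largely cancels in percent differences. The
distance-transform estimator was chosen over the plate-model surrogate
`2/(BS/BV)` because it is assumption-free on small rasters.

**Tb.N** is the plate-model quantity `(BV/TV)/Tb.Th`, reported per mm.
Direct intercept counting is not implemented; Tb.N is deliberately a
derived measure of the two measured quantities.

**Growth-plate thickness** is, per column, the pixel gap between the last
epiphyseal and first metaphyseal mineralized pixel around the band core,
scaled to µm; columns bridged by bone, reaching the image border, or
exceeding the overhang limit on either side are excluded, and the mean is
taken over valid columns.

## Osteocyte lacunae sections

Lacunae are connected components of the unmineralized phase using
8-connectivity (with the implied 4-connectivity of the mineralized
complement — the standard digital-topology pairing that avoids adjacency
paradoxes). A component qualifies only if *enclosed*: it touches neither
the raster border nor (8-adjacency) any off-sample pixel. This excludes
marrow space and vascular canals connected to the outside and substitutes
for an explicit cortical-interior restriction. Sectional areas are pixel
counts times pixel area, gated inclusively to [5, 200] µm²; perimeters use
the Crofton 4-direction estimator, which converges more smoothly for small
objects than boundary-pixel counting.

The summary's evaluated bone area is mineralized area *plus* lacunar area
(the lacunae perforate the bone they are counted against); porosity is the
lacunar share of that area, density the count per mm² of it, and medians
use the mean-of-two convention. Zero lacunae yield zero porosity/density
with medians marked undefined. Empty-vs-filled classification is an
upstream manual input (per-sample counts); only the normalized percentage
is computed here.

## Cohort statistics

Per measure and age group, the two genotype groups are compared with a
normality-gated test: Shapiro-Wilk at α = 0.05 in each group; both passing
selects the unpaired two-sided Student's t-test (equal variances),
otherwise the two-sided Mann-Whitney U — exact null distribution when the
smaller group has ≤ 8 observations and no ties, normal approximation with
tie correction otherwise. Either-group failure triggering the rank test is
a deliberate resolution of the gate's laterality. Mineral-content measures
additionally get a two-way ANOVA with site and genotype as factors using
type-II sums of squares (appropriate for the unbalanced cohorts, 20/18 and
7/7, without emphasizing the interaction), followed by Tukey HSD — over
site levels by default, over all site×genotype cells on request. No
multiple-testing adjustment is applied across measures, matching the
original analysis protocol. Group contrasts are reported as
`100·(mean_mut − mean_wt)/mean_wt`.

## Synthetic phantoms

The generator renders an 8-bit longitudinal section at 0.88 µm/px:
lateral cortical bands (60 µm), an epiphyseal trabecular compartment ending
in a 30 µm subchondral plate, the unmineralized growth-plate band (default
150 µm, parallel boundaries with a smooth ±2.6 µm lateral wiggle, spanning
the full section width), and a metaphysis whose first 500 µm carry
primary-spongiosa texture and the remainder secondary texture. Per-zone
calcium is Gaussian with means decreasing from cortex (24.0 ± 1.5 wt%Ca)
to epiphysis (23.0 ± 1.5) to metaphysis (21.5 ± 2.0) — the tissue-age
gradient of long bones — mapped to gray through the inverse calibration,
with additive Gaussian camera noise (default 2 gray levels) last.

Trabecular texture is an axis-aligned lattice of rods with jittered
spacing: the rod width plants Tb.Th and the width/spacing ratio plants
BV/TV, so both planted values are well defined — the reason this texture
was chosen over random blob fields. Default targets: primary 40% / 25 µm,
secondary 25% / 45 µm, epiphysis 35% / 50 µm. Lacunae are stamped into the
cortex as elliptical voids (log-normal areas, median 15 µm², kept inside
the 5–200 µm² gate; aspect 1.4–2.6, oriented near the bone axis) with a
2 px clearance that keeps every planted lacuna enclosed. All ground truth
is recorded from the rasterized image (lacuna areas as pixel counts, band
BV/TV as rasterized mineral fractions, growth-plate thickness per column),
never from the continuous parameters.

**Cohorts.** Per-animal targets are the configured values times log-normal
multipliers (default CV 8% between animals, 2% for calcium means); mutant
animals additionally carry the multiplicative effect profile. By default
each group's multipliers are normalized to mean exactly 1 ("group-mean
anchoring"), so the planted cohort contrast equals the configured effect
scaling by construction and the measured percent difference estimates it
without between-animal sampling error — the generator's purpose is planted
ground truth at realistic per-animal spread, not inferential null
simulation. For calibration studies of the test procedures themselves,
`anchor_group_means=False` restores iid draws; the test suite verifies
both regimes (exact contrasts when anchored, ~5% type-I error when not).
The shipped effect profiles (`data/effect_profiles.yaml`) encode the
reported group differences per age: growth plate ×0.82 / ×0.75, primary
BV/TV ×0.77 / ×0.62, secondary BV/TV ×0.64 / ×0.51, secondary Tb.Th
×0.79 / ×0.76 at 8 / 15 weeks, with mineralization and primary Tb.Th
unaffected. The empty-lacuna increase is reported only graphically in the
source study, so its factor (~2×) is a plausible default rather than a
transcribed number. Sexes alternate and carry no planted effect.

**What the phantoms do not emulate.** Rods are straight, disconnected and
axis-aligned — no plates, branching or anisotropy gradients; marrow is
empty rather than textured; noise is additive Gaussian, not Poisson
electron statistics; there are no charging artifacts, cracks, or embedding
defects; the growth plate never vanishes or folds. Passing tests therefore
demonstrate correctness of the measurement chain on idealized anatomy and
faithful recovery of planted contrasts — not robustness to every
real-world imaging pathology.

## Problem sizes and numerical choices

Full-size phantoms are 1200 × ~2400 px (≈1 × 2.1 mm), which holds several
trabecular rods per band and keeps a cohort render-and-measure cycle at a
few seconds per animal; the reproduction script renders about 190 phantoms
in a few minutes. Unit tests use a 520 px-wide phantom with a 700 µm
metaphysis and a correspondingly shortened secondary band. Determinism is
seed-exact: identical (config, seed) produce byte-identical images, and
rerunning a measurement reproduces floats to 1e-12. Degenerate inputs are
errors, not NaNs: empty ROIs, all-zero curves, missing bands, constant
statistical samples and undersized groups all raise typed exceptions, and
a failed growth-plate stage leaves the remaining stages of a sample record
intact.

## Known limitations

* 2D section surrogates only — no 3D stereology; Tb.N is plate-model
  derived, not intercept-counted.
* The Tb.Th estimator has a ≤ 1 px (0.88 µm) even-width discretization
  bias; comparative measures are insensitive, absolute values of thin
  structures are reported to that accuracy.
* CaMean/CaPeak of gray-quantized input carry the half-bin convention
  offset described above.
* Front detection presumes one dominant transverse band; sections with
  multiple comparable unmineralized bands (e.g. double physes) would need
  manual ROI input.
* The cortical column band of the pipeline is a configured margin, not a
  segmented cortex; strongly curved cortices would need polygon ROIs,
  which `ROISpec` supports but the pipeline does not auto-generate.
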