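# Methods

## Problem and model

Diffuse large B-cell lymphoma (DLBCL) has no delimited tumor region: the
malignant B cells are dispersed through the tissue, so the tumor proportion
score

    TPS = 100 · (PD-L1-positive tumor cells) / (viable tumor cells)

cannot be computed by outlining tumor area the way it is for solid tumors.
The scoring rule implemented here replaces the unavailable tumor-cell
denominator with a morphological selection.  DLBCL B cells carry nuclei
roughly twice the size of normal lymphocytes, while the very largest cells
in a field (macrophages, vascular endothelium) are usually *not* tumor.
All in-ROI cells are therefore ranked by nucleus area (descending), the top
`m` fraction is excluded as probable oversized non-tumor cells, the next
`k` cells are designated the tumor population, and

    TPS* = 100 · (PD-L1-positive cells among the selected k) / k.

When fewer than `k` cells survive the exclusion, the denominator falls back
to the number actually selected and the result carries an `under_k` flag;
slides with fewer than `min_cells` cells in total (default: `k`) are
returned as a structured "insufficient cells" outcome with no numeric
score, matching the clinical practice of excluding low-cellularity slides
rather than extrapolating.

Per-cell positivity uses the stain physics of brightfield IHC.  Under the
Beer–Lambert law, per-channel optical density is linear in stain
concentration along fixed absorption vectors; with the standard
(Ruifrok–Johnston) hematoxylin and DAB vectors the two concentrations are
recovered per pixel by least squares.  A pixel is *brown* when its DAB
optical density reaches `dab_od_threshold`; a cell is positive when the
brown fraction inside its dilated nucleus boundary reaches the threshold
`t`.  The dilation exists because PD-L1 is a membrane protein: the nucleus
mask alone excludes exactly the pixels that carry signal, so each mask is
grown a few pixels to take in the membrane ring.

## Pipeline

1. **ROI delineation.** The slide (a directory of 256 px tiles) is
   partitioned with half-open tile bounds.  Tiles are marked out-of-ROI
   either by inverting expert non-ROI polygon annotations (a tile is out
   when its overlap fraction with the annotated union exceeds
   `roi.overlap_threshold`, default 0.5 — a majority rule) or by a
   training-free tissue classifier (a tile is tissue when at least 2% of
   its pixels are chromatic in HSV; stains are saturated, glass and
   achromatic debris are not).  The classifier slot is pluggable so a
   learned patch classifier can be substituted.
2. **Detection.** Nucleus centers are local maxima of the Gaussian-smoothed
   (σ = 1.5 px) hematoxylin OD channel, with minimum separation 6 px (the
   smallest nucleus diameter the generator produces) and an absolute
   prominence floor of 0.15 OD.  The contract (`patch → points`) accepts
   model-based detectors.
3. **Segmentation.** Marker-controlled watershed on inverted hematoxylin
   OD, foreground = smoothed OD > 0.1 (σ = 0.5 px keeps the foreground
   within ~0.6 px of the true nucleus boundary).  Seeds landing on
   background claim a radius-3 disk so every detected cell has nonzero
   area.  Masks are then grown by `segment.dilation_radius` (default 3 px)
   with a distance-limited nearest-label expansion: contested pixels go to
   the nearest region, so label maps remain partitions at every stage.
4. **Positivity.** Brown mask at `dab_od_threshold = 0.15` OD; per-cell
   brown ratio within the dilated region; positive iff ratio ≥ t (t = 0
   degenerates to "any brown pixel ⇒ positive" — a ratio of exactly 0 is
   never positive).
5. **Scoring.** The m/k/t rule above with defaults m = 0.06, k = 3000,
   t = 0.1, and clinical strata [0,5) / [5,50) / [50,100] (a score exactly
   at a cutoff enters the higher stratum; the boundary side is a declared
   convention).

## Concordance statistics

Agreement between raters, and between the algorithm and a rater panel, uses
ICC3k — the two-way mixed-effects, consistency, average-measures
intraclass correlation for a fixed rater set.  With targets as rows and
raters as columns, the two-way ANOVA decomposition gives
`ICC3k = (MS_R − MS_E)/MS_R` and `F = MS_R/MS_E` with df1 = n−1,
df2 = (n−1)(k−1); the p-value comes from the F distribution and the 95% CI
from F-quantile inversion, the standard construction for average-measures
mixed ICCs.  Rows with missing ratings are dropped listwise (logged).
Parameter-sensitivity comparisons use `log10(MSE + 1e-12)`; the epsilon
floors exact agreement at −12 instead of −∞.

## Synthetic data: what it emulates, and what it does not

The generator renders 256×256 RGB patches through the same Beer–Lambert
forward model the stain module inverts (white background, so inversion is
exact up to 8-bit quantisation).  Per patch it places a configurable mix of
cell classes — small lymphocytes (nucleus radius 3–5 px), tumor B cells
(6–11 px), large non-tumor cells (12–18 px); radii are generator choices in
pixels, not calibrated measurements — by dart-throwing with pairwise center
spacing `r_i + r_j + 5` px.  That spacing keeps nuclei disjoint and lets a
neighbouring membrane graze another cell's dilated boundary by at most
about 1 px, so per-cell positivity ground truth is effectively exact while
the packing still reaches the >100 cells per patch of the emulated domain.
The class roster is drawn i.i.d. from `class_mix` before placement
(largest-first), so realized proportions track the configured mix.
Nuclei render with a mild radial chromatin falloff (denser at the center),
which is more realistic than flat disks and gives the hematoxylin channel a
unique per-nucleus maximum.  Positive cells carry a DAB membrane annulus
2–3 px thick covering a random arc fraction in [0.5, 1.0] (incomplete
membranes are the norm in real slides) at OD 0.5–1.0.

Slides are tile grids; a configured fraction of tiles renders as
achromatic artifact (smooth gray debris with fat-like voids) and is
recorded as rectangular non-ROI polygons in the ASAP XML dialect, so the
annotate-then-invert ROI workflow is exercised end to end.  Slide-level
truth (including the true TPS over tumor cells) covers non-artifact tiles
only.

Deliberately **not** emulated: photorealistic chromatin texture, scanner
noise and compression, out-of-focus regions, stain variation between
slides, cytoplasmic (non-membranous) DAB, overlapping/clumped nuclei, and
anisotropic cell shapes.  Passing the synthetic recovery tests therefore
demonstrates that the rule, the stain model, and the geometry plumbing are
correct — not that the classical detector/segmenter match trained models on
real tissue; those backends are pluggable precisely because real slides
need them.

## Numerical and design choices

- Exclusion count is `floor(m·N)`; rounding direction is a declared choice.
- Ranking ties (equal nucleus areas) break by (center y, center x, id), so
  scores are invariant to input order.
- `dab_od_threshold = 0.15` OD operationalises "brown"; there is no
  universal numeric definition, so it is a config key and is swept in
  tests.  It sits well below the weakest rendered membrane (0.5 OD) and
  above deconvolution crosstalk from pure hematoxylin (< 0.1).
- Stain vectors default to the standard H-DAB matrix and may be overridden
  per slide to absorb staining variation; estimating vectors from data
  (Macenko-style) is out of scope but fits the same interface.
- Dilation tie-breaks follow the Euclidean distance transform
  (deterministic); the radius (3 px) is a free parameter because the
  magnitude of "enough to cover the membrane" is tissue- and
  magnification-dependent.
- Detection match radius 5 px at the emulated 40× scale; precision of an
  empty prediction set is defined as 0.
- All geometry is in pixels; no physical pixel size is assumed.

## Problem sizes used in validation

The score-recovery cohort is 20 slides of 7×7 tiles (≈ 4500 cells each,
85/10/5 tumor/small/large mix so the top-k selection stays inside the
tumor population after the m-exclusion) with true positive tumor fractions
spanning 0–100%.  The exclusion-sensitivity comparison uses 6 slides of
4×4 tiles with k = 1000 and membrane-negative large cells, where dropping
the largest 6% can only help by construction.  ICC calibration uses 500
replicates of a known-variance-components two-way model (n = 30, k = 3)
and 500 null tables (n = 200, k = 3).

## Known limitations

- The classical detector and watershed are tuned to the synthetic domain's
  contrast; on real slides they are starting points, not replacements for
  trained models.
- TPS* assumes enough genuine tumor cells that the top-k selection is
  dominated by tumor; in tumor-sparse tissue the score reflects whatever
  large cells exist (the `under_k` flag and stage counts make this
  visible, but cannot correct it).
- The traditional TPS is only computable when an external viable-tumor
  count exists (here: synthetic truth), so algorithm/rater comparisons on
  real data rest on TPS*.
- ICC confidence intervals assume the usual normal-theory two-way model;
  heavily discretised or bounded rater scales are approximated, not
  exactly modelled.
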