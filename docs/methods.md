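# Methods

`eosmap` implements a whole-slide decision-support pipeline for
eosinophilic esophagitis (EoE) histology. This note documents the model,
its parameters and conventions, what the synthetic data emulate, and the
numerical choices that were genuinely open.

## Pipeline model

A whole-slide image (WSI) is scanned with a square high-power-field (HPF)
kernel of side 2144 px (548 µm at 400X), stepped by a 500-px stride along
both axes. Each HPF is tiled into 448-px sub-patches — for the default
geometry a 5×5 grid of 25 tiles with a uniform 24-px overlap — and each
sub-patch is segmented into two binary masks: intact eosinophils
(Eos-Intact) and basal zone (BZ). A pixel may belong to both classes
(an eosinophil inside the basal zone), to one, or to neither. Tile masks
are stitched with a logical OR in overlap regions, then contiguous regions
smaller than a per-class area floor are relabeled as background: 1800 px
for eosinophils and 2007 px (1% of a 448² sub-patch, re-derived and
asserted at import) for BZ.

Each HPF yields two local scores: the number of intact eosinophils
(connected components of the filtered mask) and the BZ area fraction
(positive BZ pixels / HPF pixels). Collected over all HPF positions these
form two score maps, each cell carrying a tissue-validity flag: an HPF is
tissue when at least 15% of its pixels have HSV saturation above 0.10
(slide background is near-white, so saturation separates tissue from
glass). Four slide-level biomarkers reduce the maps:

- **PEC** — peak eosinophil count: max count over tissue HPFs. Clinical
  activity cutoff: PEC ≥ 15.
- **SEC** — spatial eosinophil count: fraction of tissue HPFs with
  count ≥ 15.
- **PBZ** — peak basal zone: max BZ fraction over tissue HPFs.
- **SBZ** — spatial basal zone: fraction of tissue HPFs with BZ
  fraction ≥ 15%.

All four thresholds are inclusive (≥). The 15% SBZ threshold follows the
pipeline's methods definition; a 25% figure also circulates in discussion
of the same biomarker, so the threshold is exposed as a parameter
(`sbz_threshold`) rather than silently reconciled.

**Severity ground truth.** A slide is histologically severe (not in
remission) when PEC ≥ 15 **or** its EoEHSS total exceeds 3. The EoEHSS
scores eight histologic features (EI, BZH, DIS, EA, SL, SEA, DEC, LPF),
each 0–3 for grade and stage. "Total" is ambiguous between one combined
sum and separate grade/stage sums; the default convention sums grades and
stages separately and fires when either exceeds the cut (equivalently,
`max(grade_sum, stage_sum) > 3`), with a `combined` single-sum mode
available. The default was chosen because remission is conventionally
defined by *both* total grade and total stage being low.

**Classifiers.** Severity is predicted from (PEC, SEC, PBZ, SBZ) by an
SVM, LDA, or MLP (default hidden layers 20-50-100), trained under a
repeated protocol: stratified random 80/20 split per repeat seed, 20
repeats, median (and spread) reported. Features are standardized inside
the pipeline so scaling statistics come from the training fold only. The
windowed multi-classifier routes slides with PEC within ±Δ of 15
(inclusive) to an inner model C_in and the rest to C_out; Δ = 9 gives the
[6, 24] inner window. Both region models default to a 100-20-100 MLP.
Each region is split 80/20 independently per repeat, so regions
contribute to train and validation proportionally to their size; held-out
predictions are pooled before computing accuracy, sensitivity and
specificity. A Δ sweep over [1, 12] picks the median-accuracy argmax,
skipping Δ values whose window leaves a region empty; ties break toward
the smallest Δ (the same rule as the PEC-threshold baseline sweep).

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| `hpf_side_px` / `hpf_side_um` | 2144 / 548 | px / µm | one 400X HPF |
| `stride_px` | 500 | px | ~¼ HPF; finer strides only refine maxima |
| `subpatch_side_px` | 448 | px | segmenter input size |
| `eos_min_area_px` | 1800 | px | noise floor for eosinophil regions |
| `bz_min_area_px` | 2007 | px | 1% of a sub-patch |
| `tissue_fraction_gate` | 0.15 | — | minimum tissue per HPF |
| `sec_threshold` | 15 | cells | clinical activity count |
| `sbz_threshold` | 0.15 | — | BZ spatial threshold (see above) |
| `pec_cut` / `hss_cut` | 15 / 3 | — | severity rule |
| Δ (`delta`) | 9 | cells | inner window [6, 24] |

## Numerical and geometric conventions

- Coordinates are 0-based, row-major, top-left origin, half-open extents.
- Tiling requires an exact uniform integer overlap: with n = ⌈patch/tile⌉
  tiles per axis, the overhang n·tile − patch must divide n − 1; otherwise
  the geometry is rejected rather than silently padded.
- HPF anchors sit at stride multiples; when the last stride-aligned window
  does not end at the slide edge, one trailing anchor is clamped so the
  final window does. Slides smaller than one HPF (but at least one
  sub-patch) are white-padded on the right/bottom; padding adds no mask
  pixels and the BZ denominator stays hpf_side².
- Contiguous regions use 8-connectivity (configurable to 4). The area
  filter removes components strictly smaller than the floor; a component
  exactly at the floor is kept. Filtering runs after OR-merging, at HPF
  scope, so regions split across tile seams are not spuriously deleted.
- Segmentation probabilities are thresholded inclusively: a pixel at
  exactly 0.5 is positive.
- An eosinophil is counted in every window where its clipped, filtered
  component survives the area floor; per-HPF segmentation has no
  whole-slide component identity, so a sliver clipped below the floor at a
  window edge is dropped like any other small region. An
  `area_over_disk` count mode (positive area / nominal 1961-px disk) is
  available for masks with merged cells.
- Segmentation metrics (mIoU, mPrecision, mRecall, mSpecificity) are
  means of per-(image, class) ratios — not ratios of pooled counts; the
  distinction is enforced by test. Zero-denominator cells (class absent
  from truth and prediction) score 1 by default — perfect agreement on
  absence — or can be skipped.
- Zero tissue-valid HPFs raises a `NoTissueError`; no spatial score ever
  divides by zero. Degenerate training folds (single-class) are skipped
  with a warning; at least half the repeats must remain valid.

## Synthetic data: what it emulates and what it does not

**Slides.** A tissue band on a white background, a BZ band attached to
one tissue edge (the basal zone is anatomically a layer; the edge is
randomized per seed), and eosinophils as non-overlapping disks of
configurable radius (default 25 px, the labeling convention for real
eosinophils) placed fully inside the tissue. Colors are flat and chosen so
channel thresholds separate the classes exactly; the bundled
`reference_color` segmenter exploits this. The renders deliberately lack
H&E texture, stain variation, partially-degranulated cells, tissue folds
and scanning artifacts — so passing scan tests demonstrates the geometry,
stitching, filtering and scoring machinery is correct, not that any
particular segmenter performs well on real stains. The production-grade
deep segmentation network these interfaces were shaped around is exactly
what the pluggable `Segmenter` contract replaces.

**Cohorts.** Each patient contributes 1–3 slides sharing an activity
state drawn with probability `activity_prevalence` (default 0.45). PEC is
a zero-inflated, overdispersed count: inactive slides are 0 half the time
with a small sub-clinical tail capped below 15 (the activity cutoff is
definitional, so inactive means PEC < 15); active slides draw
15 + NegativeBinomial(k = `pec_dispersion`, mean 35), reaching the
hundreds. SEC is 0 below the cutoff and rises monotonically with PEC. The
BZ driver mixes the realized eosinophil severity g(PEC) = PEC/(PEC+25)
with an independent uniform component, weighted by `eos_bz_coupling`
(default 0.6); PBZ is an affine clip of the driver and SBZ a monotone
clip of PBZ above the 15% threshold. Coupling 1 with zero noise makes PBZ
a strict monotone function of PEC (rank correlation exactly 1); coupling
0 makes the BZ scores independent of activity. EoEHSS scores are noisy
monotone bins of the matching AI score: BZH grade uses the clinical
epithelial-thickness cut points (15%, 33%, 66%), with the scale's gap
between "absent" and ">15%" mapped to grade 1; EI cut points default to
{1, 15, 60} cells for grade and {5%, 33%, 66%} for stage and are
conventions, not clinical constants. The six remaining features follow
the slide's latent severity loosely, which makes some low-PEC slides
severe through their EoEHSS total — this is what pulls the optimal
PEC-threshold baseline below 15, reproducing the qualitative behaviour of
real severity classification.

No distributional parameter of the generator is a measured clinical
quantity; the generator fixes the *shape* of the problem (zero inflation,
heavy tail, monotone proxy scores, BZ-driven low-PEC severity) so the
pipeline's orderings and invariants can be tested. Absolute accuracies on
synthetic cohorts are higher than anything achievable on real slides
(~0.97 vs ~0.85) because the synthetic severity rule is nearly closed
over the four features; consequently ordering comparisons between
near-ceiling models (windowed vs single) are weak on synthetic data, and
are asserted only in a majority-of-seeds sense.

## Problem sizes used by the test suite and acceptance script

Geometry examples run at full scale (pure arithmetic). Scan equivalence
against a brute-force window oracle uses twenty 100-px slides with a
64-px HPF at stride 1. The classifier study uses cohorts of 520 patients
(~1000 slides) at coupling 0.6 under the 20-repeat protocol, five
generator seeds; the KS separation of PBZ by activity uses 100 seeds of
200-patient cohorts. These sizes were chosen so the entire suite runs on
one CPU in a few minutes while keeping every statistical bar meaningful.

## Known limitations

- No SVS/DICOM pyramid reading; slides are in-memory rasters or PNG/TIFF
  files. The scan engine is dimension-agnostic but tested at desk scale.
- The reference segmenter is exact only on the synthetic palette; it is a
  correctness oracle for the scanning machinery, not a stain model.
- Patient-grouped splitting is available (`group_by_patient`) but the
  default splits by slide, matching the per-WSI classification protocol.
- The Δ sweep retrains both region models per candidate Δ; with MLPs this
  is the slowest path in the package (minutes at cohort scale).
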