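# Methods

This note documents the models and procedures behind `wsisampler`, the
defaults it ships with, and what its synthetic experiments do and do not
demonstrate about real whole-slide images (WSIs).

## The virtual slide

Real WSIs are gigapixel images; the quantity the pipeline actually consumes
is far smaller: the tissue class at a patch's centre pixel. A
`VirtualSlide` therefore stores a coarse label raster — one class per
`raster_step × raster_step` pixel cell (default 32, so a 20000² px slide
costs a 625² raster) — plus a ground-truth tumour ROI polygon. Patch
"content" is never rendered; `label_at(x, y)` is a pure raster lookup at
the centre pixel, mirroring the central-pixel convention of point-based
pathologist annotation. Coordinates are 0-based level-0 pixels, x
rightward, y downward, half-open everywhere; physical resolution defaults
to 0.49 μm/px, so a 224 px patch is 110 μm and a 3 mm scoring box is
6122 px.

### Generation

`generate_slide` builds, deterministically from a seed:

- a rectangular tissue region inset 5% per side (the background margin);
- a star-convex tumour ROI: an ellipse (axis ratio drawn from 0.75–1,
  random orientation) perturbed radially by 8–16 random harmonics with a
  total amplitude of 0.06–0.12, scaled analytically so its area matches
  the requested `roi_area_fraction` of the tissue area (accepted domain
  0.01–0.6; default experiments use 0.15). The amplitude bound keeps the
  blob "mostly convex": the Dice overlap between the blob and its own
  convex hull is ≈ 0.999, so the convex-hull ROI representation used
  downstream is not handicapped by construction. The analytic outline is
  then *snapped to the raster* — the stored `gt_roi` is the boundary of
  the union of cells whose centre falls inside the blob — so polygon
  containment and raster labels agree exactly, with no boundary-cell
  ambiguity;
- class labels inside the ROI: a Gaussian-filtered white-noise field
  (σ = 4 cells ≈ 128 px correlation length) is thresholded at the
  quantiles of the requested composition, producing spatially clumped but
  well-interspersed class regions whose realised fractions are exact to
  ±1 cell. The default composition is tumour 0.50, stroma/fibrosis 0.30,
  lumen 0.05, necrosis 0.05, inflammation 0.04, mucin 0.03, vessels 0.03,
  giving a ground-truth area TSR of 0.50/0.80 = 0.625;
- non-ROI tissue: stroma 0.55, muscle 0.20, inflammation 0.15, lumen 0.10
  by the same mechanism, plus a contiguous 256 px band of
  **normal epithelium** along the tissue border. This band is the
  false-positive source: epithelium outside the lesion that a 9-class
  classifier tends to call tumour.

What the generator does *not* emulate: texture and stain variation (the
classifier is simulated, so none is needed), multi-focal lesions (a single
connected ROI per slide), concave or infiltrative tumour margins beyond
the harmonic perturbation, holes inside the ROI, and tissue folds/artefacts.
Consequently, passing synthetic tests demonstrates that the *sampling,
clustering and estimation machinery* is correct and unbiased under known
conditions — not that any particular CNN reaches a given accuracy on real
tissue.

## Simulated classification

The 9-class stage is a row-stochastic confusion matrix over 11 ground-truth
classes (the 9 outputs plus background and normal epithelium, which a
classifier never emits). `make_confusion(overall_accuracy,
normal_epi_to_tumour_rate)` places `overall_accuracy` (default 0.79, the
published accuracy of the reference VGG19) on each diagonal and spreads the
residual uniformly, except that the tumour↔stroma/fibrosis partner receives
double the uniform share in those two rows — the documented dominant
confusion — and normal epithelium emits tumour at the configured rate
(default 0.3), otherwise splitting between non-informative and stroma.
Background deterministically reads as non-informative.

The binary false-positive stage models the second network that inspects
every tumour-predicted patch and decides "true tumour epithelium" vs
"false positive". A patch with tumour ground truth is retained with
probability `sensitivity`; any other tumour-predicted patch is relabelled
`normal_epithelium` (the stage's negative output, kept distinct from a
discard so corrections remain auditable) with probability `specificity`.
Both default to 0.927, the single published accuracy of the reference
binary network, which does not separate sensitivity from specificity.
Applying the stage to *all* non-tumour ground truths, not only normal
epithelium, matters quantitatively: first-stage errors such as
stroma→tumour (≈ 4.7% per patch at accuracy 0.79) otherwise accumulate
with sample count and, at tile-by-tile density, percolate through DBSCAN's
2000 px neighbourhood into a single slide-spanning cluster.

Both stages are driven by ground truth and a seeded generator, never by
image content; a real model drops in through the same
`ClassifierBundle` interface.

## Sampling rules

"Allocated randomly in each grid box" is implemented as: the patch's
*top-left corner* is uniform over the box, and the patch may overhang the
box's right/bottom edge (never the slide edge). This reading is forced by
the 5-patch cap — five non-overlapping 224 px squares cannot fit wholly
inside a 640 px box, but their top-left corners can. Overlap (positive-area
intersection of half-open squares) is checked only against patches of the
same box. Densification adds `min(4 × tumour hits, cap − existing)`
patches per box; the in-ROI fill tops every box whose centre lies in the
hull union up to the cap. Note that with the cap at 5 and 4 patches per
hit, a first resampling round saturates every tumour box, so a second
round is a no-op by construction; it is retained as a configuration for
completeness.

Placement redraws a location until it is clear of same-box patches and not
centred on background. Rather than giving up after a fixed retry budget,
the implementation falls back (after 100 failed draws) to enumerating the
exact free region and drawing uniformly from it — distributionally
identical to unbounded retry, but it terminates and can prove a dead end.
Dead ends are real: four patches can jointly block every top-left position
in a 640 px box (each blocks up to 447×447 of the 640×640 candidate set);
this occurs in roughly 1% of fully densified boxes and is logged and
skipped.

## ROI prediction and scoring

Corrected tumour patch centres are clustered with DBSCAN at eps = 2000 px
and `min_samples` = 3 — the smallest value consistent with rejecting
points "without multiple neighbours"; both are configurable since results
are somewhat sensitive to them. Clusters with fewer than three
non-collinear points are dropped. Each cluster's convex hull is a
predicted ROI polygon; multiple clusters are scored as a union. Dice/F1 is
computed on areas rasterized at the slide's raster step (cell-centre
containment); two empty regions score 1.0 (vacuous agreement), one empty
region 0.0. Dice at raster steps 16 and 32 differs by < 0.02 on default
ROIs, so the default step does not limit the metric.

## TSR estimation

TSR = T/(T+S) over patches classified tumour or stroma/fibrosis; other
classes are ignored. The four strategies:

- **uniform_roi** (n = 100): rejection-sampled uniform centres over the
  hull union, at least 112 px from slide edges. Fresh patches are drawn
  rather than reusing pipeline patches, so the count is ≈ 100 regardless
  of pipeline density.
- **box_max_density** (n = 120): an axis-aligned 6122 px window is placed
  at the candidate centre (stride = window/4, clamped inside the slide,
  ties to smallest (y, x)) holding the most corrected tumour points, and
  sampled on a RandomSpot lattice — an equilateral-triangular lattice with
  a uniformly random offset. The pitch is derived as the largest value for
  which at least n lattice points fall in the box for *every* offset
  (floor(L/row-height) × floor(L/pitch) ≥ n), with a floor of 224 px so
  adjacent spots cannot be near-duplicate patches.
- **sliding_mean**: unweighted mean of per-window TSRs over a 6122 px
  window sliding at stride window/2; a window participates if its centre
  is inside the hull union and it holds at least `min_counts` = 10
  tumour+stroma patches (both parameters are conventions of this package;
  no reference values exist).
- **gt_locations**: classification at the pathologist's own sampling
  points, bounding achievable accuracy. For synthetic slides these points
  are a fixed property of the slide: 50 RandomSpot locations in the 3 mm
  box of maximum ground-truth tumour-cell density, seeded by the slide's
  own seed.

Errors across a slide set are RMSE and signed mean error, ground truth
minus estimate, where the per-slide ground truth is the TSR of the true
classes at the slide's annotation points. RMSE ≥ |ME| always (Jensen).

## Pipelines, determinism and problem sizes

The attention pipeline spawns three independent random streams (sampling,
classification, TSR) from the config seed, so every run is bit-reproducible
from (slide seed, config). The tile-by-tile reference covers the slide
with contiguous full 224 px tiles (partial edge tiles dropped — a partial
patch has no defined centre-class semantics; background-centred tiles
excluded) and shares the ROI and TSR stages. Speed is compared as the
patch-count ratio, a hardware-independent proxy; wall-clock is not
asserted anywhere.

Default experiment sizes — 20000² px slides (625² raster), 10–20 slides
per evaluation set — were chosen so that a full evaluation runs in seconds
on one CPU while each slide still spans ≈ 1000 grid boxes at 640 px, which
is enough for grid effects, DBSCAN behaviour and binomial TSR error to be
in their asymptotic regimes.

## Known limitations

- The confusion-matrix simulator reproduces marginal accuracies, not the
  spatial correlation of real CNN errors (which cluster in ambiguous
  tissue); synthetic error rates at boundaries are therefore optimistic.
- The convex-hull ROI cannot represent concave lesions; the Dice ceiling
  on strongly concave ground truth would be below 1 even with a perfect
  classifier.
- The tile-mode and attention-mode results share the classifier model, so
  comparisons isolate sampling effects only.
- No real-WSI reader is bundled; the `VirtualSlide` surface (dims, label
  lookup, ROI) is the contract a vendor-format adapter would implement.
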