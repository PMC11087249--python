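# Methods

## Zone partition

The partition operates on exclusive multi-class label masks: every pixel
carries exactly one class code, so an immune pixel can never coincide
with a tumor pixel. Distances are exact Euclidean distance transforms
(`scipy.ndimage.distance_transform_edt`) computed on the pixel grid and
scaled to µm by the mask's resolution, separately against the K17+ and
K17− tumor pixel sets. Distance is measured to tumor *pixels*, not an
extracted contour: for any point outside a region the two are equal, so
"distance to the closest tumor boundary" is obtained without committing
to a boundary parameterization. A brute-force reference
(`brute_force_zones`, exhaustive min over all tumor pixels) shares the
contract and is used to verify the fast path pixel-for-pixel.

Each non-tumor pixel with `dmin = min(d_pos, d_neg)`:

* `dmin > depth_um` → outside the band (default depth 25 µm — the depth
  at which K17-dependent immune contrasts are maximal; a 5–200 µm sweep
  is available via `depth_sweep`);
* `dmin ≤ contact_um` → contact shell (intratumoral compartment);
* otherwise → peritumoral band;

with the side (K17+/K17−) decided by the smaller distance. **Tie rule:**
pixels with `|d_pos − d_neg| ≤ 1e-9 µm` go to the K17+ side. Ties are
common on integer grids, so some deterministic rule is required; sending
them to K17+ biases *against* the headline direction (immune depletion
near K17+), making positive findings conservative. A consequence worth
noting: swapping the two tumor labels swaps all zone labels exactly
*except* on tied pixels, which land on the K17+ side in both
orientations — the symmetry tests account for this.

`contact_um` defaults to 1.5× the pixel pitch (≈0.52 µm at 0.346 µm/px),
which captures 8-connected adjacency. Because the masks are exclusive,
"cells overlapping or directly contacting tumor" reduces to sub-pixel
adjacency; there is no overlap case.

ROI-excluded pixels carry a dedicated sentinel, receive no zone label,
and enter no denominator. ROI rasterization uses a pixel-center-in-polygon
test with boundary pixels included (orientation-invariant).

## Zone scores

Cell counts are estimated by pixel mass, not instance counting:
`count = pixels × resolution² / cell_area`, with lymphocytes (CD4, CD8)
approximated as 8 µm diameter circles and macrophages (CD16, CD163) as
16 µm circles. Rasterized disks reproduce integer counts to well under
10% for disjoint cells; densely packed or clipped cells bias the estimate
low, which affects both K17 zones alike.

Denominators: the peritumoral score divides by the whole peritumoral band
area of the marker — immune pixels are stromal and stay in the
denominator (excluding them would inflate scores in dense infiltrates).
The intratumoral denominator is the tumor territory of the marker plus
its contact shell, so intra scores are densities over the tumor territory
being infiltrated. The intratumoral denominator is genuinely
underdetermined by the zone-score definition (which is unambiguous only
for the band); tumor+shell area is this package's choice and is applied
uniformly to both markers, so the K17−/K17+ contrast is insensitive to
the convention. Scores are reported in cells/mm² throughout.

Ratios `ZS(K17−)/ZS(K17+)` are flagged `undefined_zero_denominator` when
the K17+ score is zero; such cases are excluded from ratio-based
summaries but retained for raw-score statistics.

The digital K17 score is the percentage of tumor pixels that are K17+,
with ≥10% (boundary inclusive) classifying a case as K17-high.

## Cohort statistics

Paired two-sided t tests run on raw per-case score pairs (a log option
would be easy to add but raw scores are the default and the tested path).
Degenerate inputs follow a fixed contract: all-zero differences give
(t=0, p=1), nonzero constant differences give (±∞, p=0), both flagged.
The headline summary is the fraction of cases with the K17− score
*strictly* higher; ties count as not-higher and undefined cases are
excluded. No multiple-testing correction is applied; p values are
reported per class and compartment as-is.

## Randomization null

Per case and replicate, each immune class's estimated cell-equivalent
total (rounded to an integer, held fixed across replicates) is re-placed
uniformly — as disks of the class geometry — over the pooled admissible
stroma: contact and peritumoral pixels of both markers. Scores are
recomputed on the fixed zone map; the statistic is |ZS(K17−) − ZS(K17+)|
per class and compartment, and the empirical p uses the add-one estimator
`p = (1 + #{null ≥ obs})/(1 + n_reps)`, so the minimum attainable p is
`1/(1+n_reps)` and p is never zero. Replicate disks may overlap one
another (their union is counted) and are clipped at tumor pixels; disk
mass falling outside the band is dropped, mirroring how observed cells at
the band edge are counted. The number of replicates, the placement
territory and the statistic are configuration, not doctrine — 199
replicates is the default.

Note that the null tests *uniform placement*, not only K17 asymmetry: a
generator (or tissue) that concentrates cells in the contact shell will
reject in the intra compartment even without any K17 effect. Calibration
is therefore checked on the peritumoral statistic: under a no-effect
generator the empirical p values are uniform (KS test).

## Synthetic generator

Tumor nests are unions of random ellipses (radius mean±sd in µm); each
connected nest is cut by a straight line through a random direction so
that the configured fraction of its area is K17+, giving contiguous
subregions. Immune cells are placed by an inhomogeneous Poisson process
over the generator's *own* nearest-boundary zones (computed from the
tumor-only mask): intensity `base_intensity` in K17− territory and
`base_intensity × zone_modulation` in K17+ territory, within a stromal
band of `band_depth_um` (default 25 µm). The expected number of contact
(intratumoral) cells is `intra_fraction/(1 − intra_fraction)` times the
expected peritumoral count (default `intra_fraction = 0.25`), with the
same marker weighting inside the shell. Defining intensities on the
generator's zones — not the pipeline's recovered zones — keeps recovery
tests non-circular.

Cells are rasterized as filled disks (8 µm lymphocytes, 16 µm
macrophages) that never overwrite tumor pixels. A hard-core constraint
(minimum center distance = sum of radii, enforced for *all* role pairs by
rejection sampling with a bounded attempt budget) prevents disk overlap;
without it, same-class overlaps merge pixel mass and bias the
pixel→count conversion low at realistic intensities. Counts remain
Poisson-exact because the number of cells is drawn first and only
positions are resampled. Truth tables attribute each cell by its disk
center and record true zone areas.

What the generator does *not* emulate: chromogen appearance, stain
bleed-through, segmentation errors, realistic cell morphology, or spatial
clustering of immune cells beyond the zone effect. Passing recovery tests
therefore demonstrates the correctness of the spatial quantification
given correct masks — not robustness to upstream segmentation error.

## Problem sizes and defaults

Scanner-scale defaults (580×580 px at 0.346 µm/px) mirror an mIHC
inference patch. Cohort-level experiments (parameter recovery, null
calibration) run at 1.0 µm/px over ~1.2×1.2 mm regions with ten nests of
radius 70±15 µm, chosen so each case's peritumoral band (~0.1 mm²)
carries stable Poisson counts at a CD8 intensity of 500 cells/mm² —
about 25 expected K17− band cells per case against 5 in K17+ territory
under the 0.2 modulation, enough to make per-case reversals vanishingly
rare at 50 cases. Base intensities (CD4 200, CD8 500, CD16 200, CD163
400 cells/mm²) are in the range of moderately infiltrated carcinoma
stroma. The zone logic is resolution-agnostic, so the coarser grid is a
problem-size choice, verified by the scale-consistency test.

## Numerical choices

* Distances compared in µm with 1e-9 tolerance for the tie rule.
* Disk rasterization includes a pixel when its center lies within the
  radius; dot-dilation radii round to the nearest integer pixel.
* Connected components use 8-connectivity.
* False negatives in the evaluation are counted per source dot, even when
  several dots' disks merge into one blob.
* Micro-averaging: TP/FP/FN are summed over patches before computing
  PPV/recall/F1; PPV and recall are undefined (NaN) on empty
  denominators, F1 is 0 if either is 0 and undefined only if both are.
* Per-case seeds spawn from one master `SeedSequence`; every simulation
  is bit-reproducible for a fixed config and seed.

## Known limitations

* Pixel-mass cell counting cannot distinguish touching cells of the same
  class; there is no instance segmentation mode.
* Plain (not geodesic) distances: influence zones can cross stromal gaps
  and lumina.
* The intratumoral denominator convention (tumor + contact area) affects
  absolute intra scores; cross-study comparisons should fix the
  convention.
* The randomization null conflates K17 asymmetry with any departure from
  uniform placement in the intra compartment (see above).
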