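# Methods

## Problem and approach

Circulating tumor cells (CTCs) are enumerated from immunofluorescence-FISH
(imFISH) microscopy fields with four aligned channels: DAPI (nuclei), CD45
(pan-leukocyte antigen), and the centromere enumeration probes CEP8 and
CEP17. A cell is a CTC candidate when it is an intact DAPI-positive
nucleus, is CD45-negative, and carries an aneuploid number (>= 3) of CEP8
or CEP17 signals. The package implements this standard twice: as an
auditable rule-based pipeline (segmentation -> per-nucleus features ->
four-condition decision) and as an AlexNet-style CNN trained on
per-nucleus crops, with the same evaluation machinery over both.

## Rule-based pipeline

**Nucleus segmentation** (`segmentation`). The DAPI channel is smoothed
(Gaussian, sigma = `smoothing_radius_px`, default 2 px), binarized with
Otsu's threshold (foreground strictly above; ties toward the lower
level), and cleaned by opening -> hole filling -> closing with a disk of
radius `morphology_radius_px` (default 5 px), dropping components below
`min_area_px`. 8-connected components are labeled in raster-scan order of
their first pixel. QC flags mark regions that are too small/large
(`min_area_px`=200, `max_area_px`=50000 at the native 2728x2192 field
scale, linearly rescalable via `SegmentationParams.scaled_to`), aggregated
(solidity < 0.85, a proxy for overlapping/superposed nuclei), or touching
the field border. Flagged regions are retained but excluded from calling;
the numeric gates are engineering defaults — the interpretation standard
names the exclusions but no thresholds. A 3x3 Sobel gradient operator is
exposed (`gradient_magnitude`) for inspection; it is not load-bearing in
the mask construction, which follows the thresholding+morphology path. A
marker-controlled watershed baseline (`segment_watershed`) splits touching
nuclei: Euclidean distance transform, light smoothing (sigma 1) to kill
discretization ridges, peaks at minimum separation `morphology_radius_px`
as markers.

**Spot detection and merging** (`spots`). Within each nucleus mask
dilated by `margin_px` (5 px), a white top-hat with a disk of radius
`max_spot_radius_px` (8 px — probe features are small, on the order of
<= 10 px) isolates compact bright features; an Otsu cut on the top-hat
response restricted to the search area separates spots from background,
and components of >= `min_spot_area_px` (4 px) become signal points. Two
points merge when their centroid distance is below one spot diameter; for
unequal spots the pair diameter is the mean of the two equivalent
diameters (min/max are available). Merging collapses connected components
of this graph and repeats until no pair remains mergeable, so the
operation is idempotent and order-independent; merged area is the sum,
the centroid the area-weighted mean. Merging is per channel only — CEP8
and CEP17 signals are never merged with each other.

**Cell calling** (`caller`). The four conditions are applied in order and
each outcome is recorded: (1) no QC flag, (2) DAPI positive (true by
construction for a DAPI-segmented nucleus, kept explicit for
traceability), (3) CD45 negative — the fraction of nucleus pixels above a
global per-field CD45 threshold (Otsu by default) must not exceed 0.30;
the gate is strict, exactly 30% still passes, (4) >= 3 merged signal
points on CEP8 OR CEP17 (`signal_logic` configurable to AND; OR is the
conventional reading of a dual-probe panel, where aneuploidy of either
chromosome suffices). A missing probe or CD45 channel participates as a
failed condition — it can suppress a positive call but never fabricate
one — and is never silently read as diploid.

## CNN classifier

`cnn` builds an 8-weighted-layer network: five same-padded convolution
layers (activation after each, 2x2 max pooling after layers 1, 2 and 5)
and three fully connected layers with L1/L2 kernel regularization, ending
in a 2-way softmax (CTC vs non-CTC; a 1000-way head would contradict the
binary task). Hyper-parameters are selected on the 3x2x2 grid activation
{softmax, ReLU, tanh} x regularizer {l1, l2} x factor {0.01, 0.02} by
stratified 5-fold cross-validation with seeded folds; ties break in grid
order. "softmax" as a hidden activation is unusual but implemented
literally (normalization over the channel axis) so the grid is complete;
ReLU/l2/0.01 is the default operating point. Filter counts below 16 and
filter sizes above 10 px trigger warnings (empirically non-convergent /
wastefully large for these features).

The numeric backend (`_nn`) is a small self-contained NumPy
implementation — im2col convolution, max pooling, dense layers,
softmax cross-entropy, Adam (beta1 0.9, beta2 0.999), He initialization —
written for this package. Everything is float32 and seeded; in
single-threaded NumPy a fixed seed reproduces training bit-for-bit.
Optimizer, learning rate (1e-3), batch size (32) and epochs (30) are
conventional defaults, all configurable. The reference configuration uses
64x64 4-channel crops with filters (32, 64, 64, 96, 128) and kernel 5;
tests and the acceptance script run a lighter desk-scale configuration
(filters 16x5, kernel 3, fewer epochs, grid search on a 150-crop
subsample) chosen so the full workflow trains in minutes on one CPU
core. Input size must be divisible by 8 (three poolings).

Crops are cut per nucleus: square window centered on the centroid with
side 1.5x the larger bounding-box side, reflective padding at borders,
channels stacked in fixed order DAPI/CD45/CEP8/CEP17 (a missing channel
is a recorded zero plane), intensities scaled to [0, 1] by bit range —
not per-crop normalized, so total probe intensity remains informative.

## Evaluation

`evaluation` computes TP/FN/FP/TN with CTC-positive as the positive
class, and Se = TP/(TP+FN), Sp = TN/(TN+FP), precision = TP/(TP+FP),
F1 = 2·precision·recall/(precision+recall). A zero denominator yields an
explicitly undefined metric, never 0. AUC uses the Mann-Whitney rank
statistic with ties counted 1/2. Percentages round half-away-from-zero
to one decimal; `metrics_report` additionally computes the F1 percentage
from the already-rounded sensitivity and precision, the convention under
which the published worked-example tables are self-consistent.

## Synthetic fields

`synthetic` renders seeded fields (default 512x512, 8-bit) with full
ground truth: elliptical nuclei (radius N(20, 2) px clipped to
[0.75, 1.5]x the mean, axis ratio U(0.85, 1.2), steep super-Gaussian DAPI
profile at half amplitude on the boundary), CD45 disks (180 vs background
8) over leukocyte nuclei, Gaussian probe spots (sigma 2.5 px, amplitude
210) with 3-5 per channel in tumor cells and 1-2 in diploid cells,
additive Gaussian noise, and optional deliberately overlapping nucleus
pairs placed at 0.75-0.85x the sum of radii. Class mixture defaults to
20% tumor cells, 40% leukocytes, 40% diploid non-leukocytes. Cell
placement keeps a 14 px boundary gap between non-overlapping nuclei
(anything under twice the closing radius would fuse masks); spots keep a
pairwise separation of 4x the spot radius — above the merge distance, so
rendered counts are unambiguous — with several-spot configurations placed
on a jittered ring, the one geometry that guarantees the separation even
in the smallest nuclei. A `confluent_spots` toggle deliberately violates
the separation to exercise the merge rule. All randomness flows from the
seed; per-field seeds derive from a master seed via `SeedSequence`.

Ground-truth labels are computed by the decision rule itself from the
generated CD45 status and spot counts, so generator and caller agree by
construction on clean data — passing rule-consistency checks therefore
demonstrates correct implementation of the rule, not clinical accuracy.
The simulator omits point-spread blur, photobleaching, uneven
illumination, autofluorescence, debris and the true morphological
heterogeneity of patient CTCs; results on synthetic benchmarks bound
implementation correctness, not expected performance on patient images
(which are not public). The difficulty tiers ("easy" noise-free,
"noisy" sigma 12, "overlapping" 20% overlapped) are proxies, not
calibrated to real data.

## Numerical choices and degenerate inputs

* Otsu on fewer than two distinct levels returns the maximum value, so
  strictly-above thresholding yields an empty foreground (blank fields
  produce zero regions, constant CD45 a red proportion of 0).
* Otsu ties break toward the lower threshold; the implementation is the
  vectorized cumulative-moment form and is checked against exhaustive
  search in the tests.
* Merged spot areas are integer pixel counts; merged centroids are exact
  area-weighted means.
* `merge_spots` on <= 1 point, `label_nuclei` on an empty mask, and
  `confusion` on empty inputs are all defined (identity / empty / error)
  rather than accidental.
* Region labels are deterministic (raster order); no module except `cnn`
  and `synthetic` consumes randomness at all.

## Problem sizes in the shipped checks

The bundled tests and the acceptance script run entirely on synthetic
data at desk scale: 43 fields (~516 cells) for the rule-consistency
benchmark, 20 clean + 12 overlapping fields for segmentation recovery and
watershed splitting, 1000/100/100 random instances for the spot-merge /
Otsu / AUC oracles, and a 150-crop grid search plus 1300-crop training
and 300/700-crop held-out evaluation for the CNN. These sizes are the
package's desk-scale defaults; all of them scale up by parameter.

## Known limitations

* The hue decomposition of RGB composites cannot be lossless where
  channels overlap spatially (orange/red are adjacent hues); per-channel
  grayscale files are the native, lossless input.
* The plain pipeline deliberately reports overlapping nuclei as one
  AGGREGATED region and excludes them; only the watershed baseline splits
  them. Neither re-assigns spots in the cut region with sub-pixel care.
* The CNN backend is CPU-only and single-threaded by design; it is meant
  for desk-scale experiments, not large-scale training.
* Cell-level calling only: no per-patient positivity cutoffs, no 3-D
  stacks, no proprietary microscope formats, no image registration.
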