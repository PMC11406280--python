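# Methods

This note documents the models, estimators and numerical choices behind
`sdmfuse`, the assumptions they rest on, and what the synthetic-world tests
do and do not establish about real data.

## Geometry and coordinate handling

All spatial rules — 150 m deduplication, 256 m confinement and neighbor
imputation, 1,300 m split buffers — are Euclidean distances in meters, so
the whole pipeline operates in a single projected CRS (WGS84/UTM).
Geographic inputs are reprojected with an in-package transverse Mercator
implementation (Krüger series to third order in the flattening, verified in
the tests against an independent meridian-arc formulation and accurate to
millimeters within a zone; round-trip error is far below the 1 m contract).
Rasters use the north-up convention: row-major, origin at the top-left
corner, half-open pixel cells, an affine geotransform, and a JSON sidecar
for georeferencing next to each TIFF.

## Occurrence curation

Assumption: duplicate records of one species within 150 m are repeat
observations of the same individuals, and a species whose every record
falls within 256 m of its own centroid carries no range signal (typically
one planted or fenced individual photographed repeatedly).  Deduplication
is a greedy pass in stable input order — the first record wins — chosen for
determinism; the result is idempotent and leaves no same-species pair
closer than the radius.  The confinement rule is evaluated against the
species' coordinate centroid.  Coordinate-uncertainty filtering (≤ 120 m)
applies only when the input provides the column; otherwise it is skipped
with a warning.

## Labels: neighbor imputation and taxonomic ranks

A 256 × 256 m image around a record shows the whole local community, so an
anchor's label set is the union of species observed within 256 m (center
distance — i.e. overlapping image footprints).  Imputation runs on the
deduplicated set, is symmetric between anchors, and is monotone in the
radius.  Species with fewer than 500 label-set memberships (counted after
imputation) are dropped, and species/genus/family name→index maps are
lexicographic and serialized with every checkpoint and map.  Genus and
family targets are the taxonomy images of the species set; supervising all
three ranks shares signal between related species with few records.

## Partitioning

Climate pixels are coarse (~1 km), so two points within ~1.2 km can carry
identical covariates; both split modes therefore keep a 1,300 m buffer
between train and test.  In the uniform mode a seeded random candidate is
accepted only if every neighbor beyond the 256 m overlap radius is farther
than 1,300 m, and its overlapping neighbors move to the test set with it
(they are declared overlaps, not independently buffered — the brute-force
checker `check_exclusion` measures distances to the accepted seed anchors).
Latitudinal folds use half-open one-degree bands anchored at the integer
degree below the data; distance to a band is the projected vertical
distance to its edge latitude, solved per-anchor by Newton iteration on
the inverse projection.  At desk scale (worlds ~10 km across) the uniform
sampler frequently exhausts candidates before reaching the target test
fraction; it then warns and returns the anchors it found, which is the
intended behavior rather than an error.

## Inputs

Image patches are windows whose center pixel contains the anchor; integer
imagery is scaled into [0, 1] by the dtype maximum.  Anchors whose window
would cross the raster edge are dropped, not padded — padding would
fabricate land cover.  Climate vectors are the value of the pixel owning
the point (no interpolation) standardized per band to mean 0 / SD 1
(population SD) fitted over the valid study region; a constant band is a
fatal input error.

## Models

Three architectures share the rank-head design (three parallel linear
heads on a common representation; no hierarchical masking between ranks):

* **climate MLP** — B → 1000 → 1000 → dropout 0.25 → 2000 → 2000 with ReLU
  between hidden layers; heads read the last hidden layer.
* **image encoder** — a stem convolution followed by one stride-2 residual
  block per depth level with doubling width, then global average pooling.
  Convolutions use Kaiming initialization; each block's second batch-norm
  scale is zero-initialized so the block starts as identity-plus-shortcut,
  which stabilizes early training.  The minimum input side is
  2^depth pixels; smaller patches are rejected with the required minimum.
* **fused** — encoder features concatenated with the MLP's penultimate
  activations, one fully connected fusion layer (width `fusion_dim`,
  default 512), ReLU, then the heads; trained jointly end to end.

Species probabilities are independent sigmoids of the species logits —
a multilabel contract, so a row need not sum to one.  All widths and depths
are configurable; the test suite trains the same architectures at toy
sizes (e.g. width-8 depth-2 encoders on 16 px patches) that the defaults
scale up from.

The layers are implemented in numpy with hand-written backward passes
(im2col convolution, batch normalization with running statistics, inverted
dropout, Adam).  Every backward pass is verified against central finite
differences in the test suite; model state snapshots include batch-norm
running statistics so early stopping restores exactly the best epoch.

## Sampling-aware loss and completeness

With citizen-science labels, an unrecorded species is weak evidence of
absence at best.  Plain BCE has two failure modes here: the many absences
drown the few presences, and false absences are punished hardest exactly
where sampling is thinnest.  The sampling-aware BCE addresses both:
within each observation the present-species and absent-species terms are
averaged separately (class balancing per row), and the absent term is
multiplied by a per-location completeness

    c_i = min(1, n_i / n_ref),

where n_i is the number of distinct species recorded within 256 m of the
anchor and n_ref is the 0.95 quantile of n_i over all anchors — a proxy for
how species-rich a thoroughly surveyed neighborhood looks.  At c = 0 the
gradient with respect to every absent-species logit vanishes exactly; at
c = 1 with balanced rows the loss equals plain BCE up to the per-class
normalization constant (both identities are asserted to 1e-9).

A single-label softmax cross-entropy (`ce`), with one uniformly sampled
positive per anchor, reproduces the older single-label training style for
comparison.  The learning-rate sweep helper interprets a stepwise sweep
from 5e-6 to 1e-1 "in increments of 0.5" as multiplicative half-decade
(×10^0.5) steps.

Training is seeded mini-batch Adam (default 13 epochs); after each epoch
the mean per-species AUC_ROC on the monitoring split selects the best
weights.  When the monitoring split is too small for any species column to
contain both classes (possible at toy scale), the AUC is undefined and the
loop falls back to the final epoch's weights instead of silently keeping
the initialization.

## Metrics

AUC_ROC is computed from the Mann–Whitney statistic on rank data (ties
count one half) — this, not trapezoidal integration, is what makes
constant-score baselines exactly 0.5.  AUC_PRC and mean average precision
use the step-wise average-precision construction.  Binary metrics use
strict `score > threshold`; precision with zero predicted positives is 0.
Top-K ranking breaks score ties by ascending species index for
reproducibility.  Per-species metrics that are undefined (single-class
columns) are excluded from the median/IQR aggregation.  The random
baseline draws standard-normal scores through the logistic function ten
times and averages every aggregate across trials; the frequency baseline
rescales training frequencies linearly onto [0.001, 1.0] and repeats the
constant row for every evaluation anchor.

## Maps and community change

Strided inference assigns each window's S probabilities to that window's
own output cell (no overlap averaging — linear time, and one model
evaluation per cell), georeferenced to the window center, with the climate
vector sampled at the center.  Output grids have
`floor((H − window)/stride) + 1` rows.

Spatial community change is the mean, over a cell's existing neighbors (up
to 8; border cells use what they have rather than padded values, since
padding would invent communities), of the Euclidean norm of the S-vector
difference.  Temporal community change is the per-cell Euclidean distance
between two dates' stacks; it is symmetric, satisfies the triangle
inequality, and equals δ√S for a uniform per-species shift δ.  The same
operators applied to per-band z-scored, block-averaged raw imagery give
the null baselines.  The Pearson-correlation helper for comparing change
maps with external references uses ordinary inference; spatially corrected
significance tests are out of scope.

## Synthetic worlds

The generator separates information channels by construction: climate
carries only the B smooth Gaussian-field covariates, imagery carries only
the categorical land-cover layer (an independently smoothed field cut at
quantiles, rendered at m pixels per cell with per-class 4-band signatures
spaced ≥ ~47 digital numbers apart plus texture noise of SD 12).  Species
presence at a cell is `sigmoid(w·env + a[landcover] + b) > u`, with u set
at a prevalence quantile drawn from [0.05, 0.35] and re-calibrated into
[0.02, 0.5]; half the species have zero land-cover affinity.  This makes
the modality comparison identifiable: climate-only models cannot learn the
land-cover component, image-only models cannot learn the climate
component.  Sampling effort is an exponentiated smooth field; anchors are
drawn proportional to it and each truly present species is recorded with a
per-species detection probability, producing incomplete lists by design.
All randomness flows from one seed; worlds are reproducible bit for bit.

What the synthetic worlds do **not** emulate: sensor noise and atmospheric
effects, phenology and seasonal imagery differences, taxonomic label
noise, non-stationary niches, and the sheer scale of real archives.
Passing recovery tests therefore demonstrates that the pipeline's
machinery is correct and that its statistical behavior matches its design
under controlled conditions, not that a given accuracy will be reached on
real imagery.

## Problem sizes used by the test suite

The package's own desk-scale study conditions, chosen once:

* **recovery / modality ordering** — 44 × 44-cell worlds, 16 species, 19
  climate bands, 8 imagery pixels per cell; 1,100 anchor draws at
  detectability 0.6; width-8 depth-2 encoders, (64, 64, 128, 128) MLPs,
  fusion width 64; 8 epochs of Adam at 3e-3; maps at one cell per stride.
  Three seeds (11, 21, 31); the fused model's median per-species map
  AUC_ROC against the hidden truth exceeds 0.85 on species with prevalence
  ≥ 0.05, beats the climate-only model on land-cover-driven species and
  the image-only model on climate-driven species (seed medians).
* **loss comparison** — 36 × 36-cell worlds with strong effort bias
  (concentration 4.0) and detectability 0.25, 4,000 anchor draws, climate
  MLPs trained 12 epochs with each loss; over seven seeds the
  sampling-aware loss matches or beats plain BCE on the fully known truth.
* **disturbance** — land cover flipped in a 16 × 16-cell rectangle and
  imagery regenerated; the trained fused model's temporal change is higher
  inside than outside (one-sided rank-sum, p < 0.01).
* **baseline calibrations** — score matrices up to 5,000 × 2,221 with ten
  random-baseline trials.

## Known limitations

* The numpy training loop is single-process and CPU-bound; the
  architecture is scale-faithful but the default full-scale widths are
  impractical without swapping the layer library for a GPU framework.
* The uniform split's greedy candidate pass can fall short of the target
  test fraction in dense regions (it warns); no spatially stratified
  candidate scheme is implemented.
* The completeness estimator is a richness-quantile heuristic; it ignores
  detection differences between species at a site.
* GeoTIFF georeferencing lives in JSON sidecars rather than embedded TIFF
  tags, and CRS support covers WGS84/UTM only.
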