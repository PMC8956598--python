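# Methods

This note documents the models, parameters and numerical choices behind
`fibromorph`, and what the synthetic-study tests do and do not establish
about real Cell Painting data.

## Synthetic cohort and morphology model

The cohort generator reproduces the structure of a population-scale
fibroblast screen: 91 donors split 45 healthy / 32 sporadic PD / 8 GBA PD /
6 LRRK2 PD, five donors contributing a second biopsy (96 cell lines), and
demographic matching of PD donors to healthy controls by age (uniform jitter
within ±3 years of the PD partner) and sex.  All familial-PD donors and 31 of
the 32 sporadic donors are matched, giving 45 pairs of which 37 (sporadic +
LRRK2) feed the disease task; one sporadic donor remains unmatched, mirroring
the asymmetry of a 46-PD / 45-control cohort.

Each line carries a 20-parameter morphology vector: per-channel mean staining
intensity (16-bit counts), nucleus and cell area mean/SD (px²), eccentricity,
per-channel texture grain radius (px) and per-channel radial skew
(dimensionless, −1 = center-heavy, +1 = edge-heavy).  The vector is composed
additively in units of the per-parameter population SD:

```
params = baseline + donor_scale·SD·z_donor + line_scale·SD·z_line
         + disease_scale·shift·[line is PD]
```

with `z` standard normal per donor / per biopsy and `shift` a fixed seeded
±SD pattern on a seeded 30% subset of parameters, reflecting the expectation
that disease signal is spread thinly over many features rather than
concentrated in one.  Parameters are clipped to physical ranges, so very
large effect scales saturate.  Second biopsies share the donor component and
redraw the line component; one configurable "discordant" repeat donor also
redraws half of the donor component, emulating a biopsy from a different body
site.

Effect scales are free parameters, not calibrated claims about real
fibroblasts: the real magnitudes of line/donor/disease variation are unknown,
so tests and experiments state the scale they assume (e.g. "between-line
variance at least twice within-line variance") and verify that premise before
asserting recovery.

## Plate layouts

Each 96-well plate carries all 96 lines, one per well.  Layout 1 places the
randomly permuted matched pairs in horizontal well-pairs with the
healthy/PD member order alternating by row parity, yielding a
checkerboard-like alternation of control and PD wells; the six lines without
a partner (the unmatched PD line and the five second biopsies) fill the last
three well-pairs.  Layout 2 exchanges the four 4×6 quadrants diagonally
across the plate center (implemented as a cyclic shift by (4, 6)); the map is
an involution, moves every well a Manhattan distance of 10, and sends edge
wells toward the center, which is the purpose of the second layout — any
location bias present in one layout is displaced in the other.

## Tile rendering

Cells are ellipses with a nucleus (visible in DAPI) inside a larger cytoplasm
(visible in ER/RNA/AGP/MITO at 40% intensity inside the nucleus).  Candidate
cell centers are rejection-sampled so no two centers lie within one nucleus
diameter — nuclei in a fibroblast monolayer essentially never overlap, and
without this constraint rendered nucleus areas would be biased low by
label overwriting.  Within each cell the channel intensity is modulated by a
linear radial profile `1 + skew·(ρ − ½)` and a multiplicative Gaussian-smoothed
noise texture whose correlation length is the line's grain radius.  Batch
artifacts are applied last: per-channel log-normal gain (SD 0.15), a radial
vignette of seeded strength 0.1–0.3, Poisson photon noise and Gaussian read
noise (SD 30 counts).  Rendering is a pure function of (cohort spec, plan,
master seed): each tile's generator is spawned from the master seed and the
tile's (batch, plate, line, tile) address.

What the simulator does *not* emulate: real cell shapes and organelle
substructure, cell-cycle and confluence effects, staining chemistry,
growth-rate differences, focus drift.  Tests passing on this generator
demonstrate that the *analysis chain* is correct and leakage-free under known
ground truth — not that any particular effect size is achievable on real
images.

## Pre-processing

Per (batch, plate, channel) the background is the per-pixel 10th-percentile
image over all tiles of the plate, Gaussian-blurred (sigma 50 at full tile
size; rescaled to 8 px for 96-px desk tiles) and floored at 1e-6; tiles are
divided by it, which cancels gain and vignetting.  Nuclei are detected on the
corrected DAPI channel by Gaussian smoothing (sigma 2; 1.5 at desk scale),
Otsu's threshold, 8-connected components and an area filter (80 px² full
scale / 30 px² desk).  8-bit conversion clips each channel between its
0.001th percentile from the bottom and 1.0th percentile from the top — the
symmetric reading of "0.001 and 1.0 minimum and maximum percentile"; the
alternative (100.0 from the bottom) would make the upper clip a no-op — then
applies the fixed log curve `log1p(255·d)/log1p(255)` on the normalized
clipped values and rescales to [0, 255].  Normalizing *before* the log makes
the conversion exactly invariant to positive rescaling of the input, which is
what per-channel percentile clipping is meant to achieve; percentiles are per
tile (the per-image reading), not per plate.  A zero-range channel maps to
all zeros.  Cell crops are extracted centered on nucleus centers (center at
index side/2, 0-based); crops touching the tile boundary are skipped and
counted.

## Deep embeddings

Each channel is replicated to RGB, scaled to [0, 1], bilinearly resized to
the backbone's input side and pushed through a fixed backbone; the
activations are projected to 64-D and the five channel vectors concatenated
to 320-D in the fixed order DAPI | ER | RNA | AGP | MITO.  The projection is
i.i.d. N(0, 1)/√64 — norm-preserving in expectation — generated from a seed
and shared across channels (one projection per backbone).  The backbone is a
contract (`identifier`, `input_side`, `output_dim`, `evaluate`); the bundled
`PoolingBackbone` (D = 256) computes multiscale mean/max pools, gradient
pools, intensity and gradient quantiles, difference-of-Gaussian band
energies, Laplacian energies and foreground fractions — deterministic,
offline, and sensitive to the same image attributes (brightness layout,
texture scale, edge density, object area) that a pretrained network's
penultimate activations respond to.  `MeanPoolBackbone` is a purely linear
variant used to exercise linearity-sensitive contracts.

## Engineered features

Nuclei are segmented in DAPI (Otsu components seeded at the detected
centers), Cells in the RNA channel by seeded watershed constrained to contain
their nucleus, Cytoplasm as the exact per-object set difference.  The feature
set is representative (~190 columns), not a bit-compatible reproduction of a
full CellProfiler catalogue: area/shape (area, perimeter, eccentricity, form
factor 4πA/P², solidity, equivalent diameter) per compartment; intensity
(mean, integrated, SD, min, max, mass displacement) per compartment ×
channel; radial distribution (FracAtD over 4 equal-width normalized-distance
rings, normalized distance = d_centroid/(d_centroid + d_edge)) of the RNA and
AGP channels within Cells; per-object co-occurrence texture (contrast,
correlation, entropy at offsets 1 and 3, 8 levels re-binned per object so the
values are invariant to gray offsets) in every channel; and the per-tile
granular spectrum (successive grayscale openings with disk elements,
`g_k = 100·(I_{k−1} − I_k)/I_total`) per channel, replicated onto the tile's
cells as image-scoped measurements.  Features undefined for a degenerate
object are set to 0 and flagged in a `QC_DegenerateObject` column.

The tile-level image statistics are per channel: Otsu foreground/background
mean and SD, foreground fraction, and a focus proxy `v/(v + 0.01)` with `v`
the variance of the Laplacian of the [0, 1]-normalized image — bounded in
[0, 1] and strictly decreased by blurring, the two properties QC relies on.

## Profile assembly

Embeddings are centered per (batch, plate-layout) group; engineered features
and image statistics are centered and then scaled to unit column L2 norm
(center-then-scale for both).  Well profiles are the unweighted arithmetic
mean over the well's cells/tiles, computed after normalization; on balanced
designs the two orders commute, and the normalize-then-aggregate order is the
implemented one.  Group means are computed over all data including held-out
groups: held-out units are entire batches/layouts, so their centering uses
only their own *unlabeled* data and leaks no labels; a train-only mode exists
for methodological comparison.

## Classification tasks

All models consume well-level profiles.  Four model kinds are provided:
cross-validated logistic regression (lbfgs, internal 3-fold penalty search,
falling back to a fixed unit penalty when a class has a single training
example), cross-validated ridge classification (decision values mapped to
probabilities by softmax), random forest (100 trees), and an MLP with one
hidden layer of 200 units.  Predictions are probability vectors; line-level
predictions are per-line means of well probability vectors.

* **Line identification** (96 classes): for each held-out (batch, layout),
  train on the other batches with the other layout.  4 batches × 2 layouts →
  8 splits.  Metrics: well- and line-level accuracy and the predicted-rank
  histogram, with rank = 1 + number of classes with strictly greater
  probability, ties broken by class index.
* **Donor identification** (91 classes): for each biopsy role and held-out
  (batch, layout), train on one line per donor and evaluate the predicted
  rank of the repeat donors' counterpart biopsies.
* **Disease classification**: whole matched pairs are dealt greedily to 5
  folds (familial-PD pairs first, then by fold size with sex/age tie-breaks;
  37 pairs → sizes 8/8/7/7/7, LRRK2 counts within 1).  GBA pairs are held
  out of the default task and available via an explicit flag.  Scoring is
  line-level ROC AUC by midranks (ties get half credit), per subgroup
  (all PD / sporadic / LRRK2), with all controls retained in every subgroup.

Channel ablation drops or isolates one channel's 64-block (embeddings) or
FeatureName-matched columns (engineered; channel-free features are kept under
`omit` and dropped under `only`).  Training titration subsamples training
wells per line and tiles per well through fixed seeded permutations, so the
k-sample set is nested in the (k+1)-sample set.  The design-bias check
regresses disease state on design covariates (age/sex dichotomies and
plate-position encodings: edge/corner/center, row pairs, column triplets)
with L1 regularization, choosing the penalty by the one-standard-error rule —
the conservative convention under which pure-noise covariates are selected
only rarely while a planted confound survives easily.

## Feature importance

Rankings come from impurity importances (forest) and absolute coefficients
(linear models) per (architecture, fold); the top-K threshold is the smallest
multiple of 20 whose cross-validated AUC is within one cross-fold SD of the
full-feature AUC ("maintains the same performance", operationalized); the
intersection over all 15 lists (3 architectures × 5 folds) is pruned greedily
in mean-rank order at |Pearson r| > 0.75 over line-level means (the level at
which group differences are displayed), grouped by family ×
compartment-or-channel, and tested control-vs-sporadic and control-vs-LRRK2
with two-sided Mann–Whitney U (exact for group sizes ≤ 10, tie-corrected
normal approximation otherwise), Bonferroni-adjusted for the 2 comparisons.

## Problem sizes

Three named plans set the study geometry:

* `full_plan()` — 4 batches × 12 plates × 96 wells × 76 tiles of 2960×5056 px
  (the full design; configuration only, never rendered in tests),
* `desk_plan()` — 2 batches × 2 plates × 4 tiles of 512² px,
* `micro_plan()` — 2 batches × 2 plates × 2 tiles of 96² px, ~6 cells/tile.

Multi-seed experiments (chance calibration, the AUC-vs-effect-scale curve,
and the acceptance script) use `micro_plan()` so that a ten-seed experiment
runs in minutes on one CPU; signal-recovery tests use a slightly larger
variant (2 plates per layout per batch, 6 tiles, 12 cells) chosen so the
planted between/within-line variance ratio of the resulting well profiles
exceeds 2, the premise under which line recovery is asserted.  Desk-scale
pre-processing constants (background blur 8 px, detection sigma 1.5, minimum
object area 30 px²) are the full-scale constants rescaled to the 96-px tile.

## Known limitations

* The pooling backbone is not a trained network; absolute task accuracies on
  synthetic data say nothing about the accuracies a pretrained Inception
  would reach on real images.
* Well means discard within-well heterogeneity by construction.
* The renderer's ellipse-with-texture cells cannot exercise fine-grained
  morphology features (e.g. solidity is nearly constant); those features are
  validated on constructed geometric fixtures instead.
* Greedy fold balancing optimizes subgroup counts first and sex/age only as
  tie-breaks; exact covariate balance is not guaranteed for adversarial
  cohorts.
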