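# Methods

## Coiler phenotyping

### Shape model

Each segmented worm silhouette is summarised by area `A` (foreground
pixel count), perimeter `P`, and circularity `4πA/P²`, clipped at 1
(the continuous supremum, reachable from above by discrete estimates).
Posture classes are cut at fixed circularity values: coil strictly
above 0.6, omega turn in (0.4, 0.6], sinusoidal at or below 0.4. The
coil cut-off at 0.6 separates the abnormal coiler phenotype from normal
crawl and turning postures, whose circularity regimes sit near 0.2 and
0.5 respectively.

Two discrete-geometry choices matter and are isolated behind
`SegmentationConfig` flags:

* **Perimeter estimator.** `P` is the Crofton (multi-direction
  intercept) contour length, not a boundary-pixel count; pixel counting
  biases `P` upward and depresses circularity. With this estimator,
  rasterised discs of radius ≥ 15 px score in [0.95, 1.0] and the
  estimate is scale-stable within 2% across dilation factors 1–4.
* **Coil holes.** A tightly coiled worm is an annulus. `A` is the body
  area (the hole is not filled), but `P` is measured on the hole-filled
  silhouette, i.e. the outer contour only. This combination keeps tight
  coils above the 0.6 cut-off (a closed loop of a 10:1
  length-to-width worm scores ≈ 0.73) while leaving open postures
  unaffected.

Segmentation is Otsu thresholding (dark-on-light by default, invertible
by flag), 8-connected labelling, and an area filter at
[0.25×, 2.5×] the nominal worm silhouette area `length × width`.
Blobs above the upper bound are treated as worm–worm collisions and
dropped for that frame, logged; dropping ambiguous frames trades a
little data for unambiguous per-animal shape values.

### Tracking and endpoints

Linking is greedy nearest-neighbour within `max_disp` px per frame of
gap (default 2× the expected per-frame displacement), with tracks
closed after `max_gap` (default 2) missed frames. Greedy assignment can
swap identities during close encounters; this is tolerated because both
population endpoints are swap-invariant: the coiler score pools frames
across animals (a per-animal averaging mode exists behind a flag), and
the average speed is the duration-weighted mean of per-track speeds,
identically total path length over total tracked time. Normalisation to
a control group is a ratio to the control mean (fold-of-control), not a
difference.

## Literature ranking

Tokenisation is lowercase whitespace splitting; the vocabulary keeps
the `K` most frequent terms (default 20 000, ties lexicographic).
Document weights are `tf·idf` with `tf = count/len(doc)` and
`idf = ln((1+N)/(1+df))` (add-one smoothing avoids division by zero;
raw-count tf and unsmoothed idf are config switches). Entity centroids
are arithmetic means of document vectors; similarity is cosine
truncated at 0 (negative values cannot arise from nonnegative TF-IDF
but are guarded); a zero centroid is isolated (similarity 0 to
everything, including itself).

Ranking is a random walk with restart on the row-normalised similarity
matrix: `s ← α·e + (1−α)·Wᵀs`, restart mass `e` uniform over the known
set, `α = 0.15`, iterated to L1 change < 1e-10 (rows with zero sum
teleport their mass back to `e`). RWR is adopted as the canonical
published graph-diffusion ranking method; the direct linear solve
`(I − (1−α)Wᵀ)s = α·e` serves as the test oracle and agrees with the
iteration to < 1e-8 L∞ on graphs of up to 50 nodes. Scores conserve
mass (sum to 1), so candidate ranks are comparable across runs. Dense
diffusion is the default; a kNN-sparsified graph was considered and
rejected at the scales exercised here (hundreds of entities), where
dense linear algebra is both simpler and faster.

Leave-one-out validation moves each known entity to the candidate pool
in turn and records its rank. ROC/PR curves treat held-out knowns as
positives; negatives are the never-known candidates scored once under
the full known set, which keeps exactly one score per negative.

## RT-QuIC calling

The positivity threshold is the mean plus 5 sample standard deviations
(divisor n−1) of background fluorescence, pooling **all timepoints of
all diluent wells**; per-timepoint thresholds are available behind a
flag, and with realistic background well counts the pooled estimate is
the stabler of the two. A replicate is positive iff its reading at the
last timepoint at or before 60 h strictly exceeds the threshold
(equality is negative); a max-over-time mode exists but is non-default
because late endpoints, not transients, define the assay readout. A
sample is positive iff at least one of its replicates is. Mean kinetic
curves average positive replicates for positive samples and negative
replicates for negative samples. Group comparison emits a 2×2
positives/negatives table and a two-sided Fisher exact p-value
(point-probability convention, the mainstream software definition).

## Statistics

`stats` wraps scipy/sklearn behind a contract-checked surface: Fisher
exact (point probability), one-tailed Wilcoxon rank-sum (exact by
enumeration for `n+m ≤ 12` without ties, else normal approximation with
tie and continuity corrections — the crossover balances runtime against
exactness), trapezoidal ROC/AUC with tie-grouping (equivalent to
Mann–Whitney concordance with half credit for ties), and step-sum
average precision. The test suite checks each against an independent
brute-force oracle: exhaustive margin-preserving table enumeration,
permutation enumeration, and concordant-pair counting.

## Synthetic data

The generators define the study conditions the pipeline is validated
under; all are driven by a single integer seed and are reproducible
bit-for-bit.

**Recordings.** Ten worms per population, 2 frames/s, arena defaulting
to 1936 × 1456 px. Worms are midline curves rendered by stamping discs
of radius `width/2` (dark 0.2 on light 0.9 background, Gaussian pixel
noise σ = 0.02, so segmentation is exercised nontrivially). Posture is
drawn per frame per worm from `(coil_prob, turn_prob)`; an optional
geometric dwell time is provided but defaults to one frame (i.i.d.
draws), as no dwell-time statistics are available to calibrate it.
The sinusoidal crawl uses two full body waves so the continuous
centroid coincides with the body centre at every phase (keeping
measured path length close to truth); the omega turn is rendered as a
closed loop of 3/4 body length with the remaining quarter as an
outward tail — an open horseshoe cannot reach the ~0.5 circularity
regime under an outer-contour perimeter at realistic aspect ratios,
whereas the head-over-body loop lands there naturally. Worms advance at
`mean_speed` with Gaussian heading noise, reflect at the arena margin
(standing in for the copper-ring chemorepellent of the real assay), and
by default steer apart when within 1.3 body lengths so that collisions
— which the segmenter would drop or merge — stay rare.

Tests and the recovery suite run this generator at a reduced problem
size — 360 × 270 px arena with 60 × 6 px worms — preserving the 10:1
aspect ratio and therefore the circularity regimes (~0.2 sinusoidal,
~0.5 turn, ~0.75 coil) while keeping 20-seed × 720-frame recovery
sweeps tractable; this scaling is a deliberate package choice and the
suite asserts the regimes hold at it.

What the generator does **not** emulate: undulatory mechanics, body
self-occlusion, egg/debris clutter, illumination gradients, and
posture dwell-time correlation (by default). Passing recovery tests
therefore show the measurement chain is unbiased under clean but
noisy-imaging conditions, not that segmentation is robust to arbitrary
real-world footage.

**Corpora.** The vocabulary splits into a topic block (10%) and a
background block, each with a Zipf profile. Knowns and planted positive
candidates draw document word counts from
`separation·topic + (1−separation)·background`; other candidates draw
from the background alone. At separation 1 the blocks are disjoint, so
retrieval must be perfect; at 0 all entities are exchangeable and LOO
AUC sits at chance. Scale defaults (15 knowns, tens of candidates, 5
docs each, 100 tokens per doc) mirror a screen's known/candidate design
at desk scale; documents are token streams, not natural language.

**Plates.** Background wells are Gaussian around `background_mean`
(default 1200 rfu, SD 400 rfu, which puts the +5 SD threshold near
3200 rfu, a realistic scale for the assay). Seeded replicates add a
logistic rise (default amplitude 50 000 rfu, midpoint 20 h, rate
0.5 h⁻¹, per-replicate midpoint jitter SD 2 h); readings every 45 min
to 60 h. The generator does not model lag-phase kinetics beyond the
logistic, protein-concentration effects, or plate-edge artefacts.

## Numerical and degenerate-input conventions

* Circularity inputs must be positive; classification requires
  circ ∈ (0, 1].
* Coordinates are 0-based pixels, x = column, y = row, origin top-left.
* Empty frames and frames with no surviving component yield empty
  detection lists, not errors; zero tracked frames, empty known sets,
  all-tied rank-sum samples and zero-margin tables raise or warn as
  documented per function.
* A control group with zero mean cannot define a fold-change and raises
  with guidance to report raw scores.
* Vocabulary and ranking ties break lexicographically so outputs are
  deterministic.

## Known limitations

Greedy linking under-performs optimal assignment in dense recordings;
the coiler score tolerates this, but per-animal trajectories from
crowded arenas should not be over-interpreted. The diffusion ranker's
behaviour on corpora whose entities have wildly unequal document counts
is untested beyond the centroid averaging that defines it. The RT-QuIC
caller deliberately estimates no kinetic parameters (lag time, maximum
slope); it answers only the positivity question.
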