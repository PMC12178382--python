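# Methods

## Pipeline model

A whole slide image is represented by the bag of its patch feature vectors
`{x_1 … x_n} ⊂ R^d`. The pipeline has four stages, each behind its own
module seam:

1. **Patch preparation** (`patches`). Non-overlapping square tiles
   (default 512 px) on a row-major grid with 0-based, half-open pixel
   coordinates; partial edge tiles are discarded. Two exclusion rules
   remove non-tissue tiles: a *blankness* rule (drop when the fraction of
   pixels with all RGB channels ≥ 220 strictly exceeds 0.5 — both numbers
   configurable, since any fixed whiteness cutoff is scanner-dependent)
   and a *low-content* rule. Low content is at heart compressibility: a
   tile whose compressed file is under 80 KB holds no tissue fragment, so
   the byte size is used whenever the tile came from a file; for in-memory
   rasters the mean local (8×8) pixel standard deviation stands in with
   its own threshold, because file size depends on the storage dialect.
   Slides retaining fewer than 64 patches are dropped entirely — the
   boundary is inclusive (≥ 64) and configurable. Multilabel diagnostic
   strings are simplified to six classes by a priority rule list (normal ≻
   acute leukemia ≻ myelodysplastic syndrome ≻ plasma cell neoplasm ≻
   lymphoproliferative disorder ≻ myeloproliferative neoplasm) over a
   configurable keyword map; unmatched labels map to an `unmapped`
   sentinel that callers discard. Pure descriptors like "hypercellular"
   never decide a class alone.

2. **Feature extraction** (`features`). A registry of extractors mapping
   equal-sized RGB tiles to an `(n, d)` float32 matrix. Deep backbones
   (DenseNet-121, KimiaNet, HIPT ViT-16/256, DINO ViT-S/16) attach as
   named adapters whose weights are external; requesting an unregistered
   one raises a capability error rather than silently substituting. The
   built-in extractor (channel histograms + local-variance statistics +
   gradient moments, pushed through a frozen-seed Gaussian random
   projection) is pure — same bytes, same row — and defaults to d = 384 to
   match the transformer backbones, keeping PCA profiling comparable.
   Bags round-trip through an HDF5 container (float32 matrix + JSON
   manifest) with a JSON cohort index.

3. **Binary patch grouping** (`bpg`). The profiling sample takes up to 96
   patches per slide uniformly without replacement (slides with fewer
   contribute all; the held-out reference slide contributes none; no
   slide-quality filter applies — profiling is independent of the
   representation pipeline). k-means with k = 2 (Lloyd, Euclidean on the
   raw feature space, 10 restarts, best inertia) fits the two centroids.
   k is fixed at 2 deliberately: the stage separates a signal population
   from a noise population, and more clusters would fragment the boundary.
   No feature scaling is applied by default; the extractor's geometry is
   taken as-is. The reference slide's patches are assigned to the two
   centroids for human inspection, and the single designation of the
   target cluster is recorded immutably (timestamp + note). All later
   filtering is **nearest-centroid assignment with the profiling
   centroids** — never a per-slide re-clustering, which would detach
   cluster identities from the one-time designation. Ties go to centroid
   0. If filtering would empty a bag, the unfiltered bag is returned with
   a warning: every slide must yield a representation.

4. **Pooling** (`pooling`). Average pooling is the elementwise mean
   (computed in float64; p = d). Attention pooling is single-head
   learnable-query attention — the minimal parameterization of weighted
   instance pooling `y = Σ α_i F_proj(x_i)`: scores `β·q⊤Kx_i`, softmax
   weights, value projection V, with β = 1/√k (k = query dim, default 64)
   and p = d by default so both poolings are comparable. Its parameters
   are trained by supervised contrastive loss (temperature τ = 0.1) over
   L2-normalized slide outputs, batches of 32 slides, averaged over
   anchors that have at least one same-label slide in the batch.
   Optimization is plain SGD with momentum 0.9, lr 1e-3, 50 epochs by
   default; gradients are closed-form (hand-derived backpropagation
   through the attention softmax, projections and normalization) and are
   checked against central finite differences in the test suite. The
   lowest-epoch-loss checkpoint is returned; training is bit-deterministic
   under a fixed seed.

## Evaluation

*Retrieval*: the database is ranked by ascending cosine distance
`D_C = 1 − cosΘ` (ties broken by slide id), the query's own vector is left
out, and the top-10 scored by `mAP@10 = (1/10) Σ_{i=1..10} P(i)` with
`P(i)` the precision at rank i when rank i is a hit and 0 otherwise. Note
the fixed 1/10 prefactor — the score is not normalized by the number of
relevant items, so a query whose class has fewer than 10 other members
cannot reach 1. Optionally vectors binarize to Min-Max barcodes
(bit_j = 1 iff v_{j+1} > v_j, strict, so constant runs give 0) compared by
Hamming distance; the codes depend only on consecutive-component order and
are invariant to strictly monotone transforms. Real-vector cosine is the
default metric; binarization is a flag.

*Classification*: distance-weighted k-NN with weights `1/(D_C + 1e-12)`
(an exact duplicate therefore dominates), k selected on the training half
by stratified inner cross-validation (5 folds, reduced to the smallest
class if needed) over the odd grid 1…19, maximizing weighted-F1 with ties
to the smaller k. Scores use per-class precision/recall/F1 with the 0/0→0
convention and class-support weights.

*Harness*: five-repeat Monte-Carlo cross-validation. Each repeat shuffles
and halves every class independently (floor to train, remainder to test,
so 633 slides split 316/317); all settings share the identical splits, so
per-repeat metric differences are paired. Significance is a one-tailed
paired t test of H1: mean difference > 0, with an exact sign-flip
permutation variant for ≤ 12 pairs; zero-variance differences
short-circuit (all positive → p = 0, all negative → p = 1, all zero is an
error). The attention pooler is retrained on each repeat's training half
only; the patch-grouping model is fit once globally, since its preparation
is independent of the representation pipeline. The overall filter effect
is the mean of per-setting improvements, absolute and relative. A PCA
profile reports the smallest component count reaching 95% cumulative
explained variance and its ratio to d.

## Synthetic cohorts

The generator emulates the feature-space geometry of bone marrow biopsy
bags: a class-informative tissue component and a class-independent
bone/fat/blank component.

- Class means sit on a regular simplex (scaled basis vectors), every pair
  exactly `signal_separation` apart; signal patches are isotropic Gaussian
  around the slide's mean with sd `signal_sd`.
- Each slide adds a random offset (sd `slide_sd`, confined to the
  class-mean subspace) to its class mean: same-diagnosis slides differ, as
  patients do. Without this, averaging ≥ 64 patches collapses within-class
  spread to ~1/60 of the class separation and every pipeline variant
  saturates both metrics at exactly 1.0, leaving nothing to compare.
- Noise patches share one mean for all classes, offset `noise_offset`
  along an axis orthogonal to the class simplex, with sd `noise_sd`. The
  noise component is deliberately broader than the signal
  (`noise_sd = 3 × signal_sd`) and far out (`noise_offset = 8 ×
  noise_sd`): bone, fat, blank glass and hemorrhage differ among
  themselves far more than marrow disease classes do, and the 8× ratio
  keeps the two populations cleanly separable so the k = 2 grouping
  recovers the ground-truth patch flags essentially perfectly.
- Per-slide noise fractions are uniform on a configurable range; per-patch
  flags are Bernoulli; bag sizes uniform on a range; one spawned RNG
  substream per slide makes any prefix of the cohort reproducible.

The reference study conditions (`reference_cohort_spec`) are 6 balanced
classes × 30 slides, d = 384, bags of 64–200 patches, noise fraction
0.3–0.5, separation/signal_sd = 6, slide_sd = 1.25. The evaluation harness
and the acceptance script use 20 training epochs for the attention pooler —
enough for the loss to plateau on these cohorts — and seeds derived from a
single master seed.

What passing on these cohorts does **not** show: robustness to real stain
and scanner variation, to non-Gaussian or multimodal noise (a single
shared noise mode is itself an idealization), to patch populations that
are not cleanly binary, or to feature extractors whose geometry differs
from the isotropic model. Tile images from `generate_tile_images` are
texture stand-ins for filter tests, not histology.

## Numerical and degenerate-input choices

Softmax scores are max-shifted; slide-vector norms are floored at 1e-12
before normalization; k-NN vote weights use the same floor. Equidistant
centroid assignments go to index 0; retrieval distance ties break
lexicographically by slide id; equal inner-CV scores prefer smaller k.
Degenerate inputs fail loudly: all-identical profiling rows, zero vectors
in cosine distance, constant matrices in PCA profiling, single-class
contrastive training, singleton classes in stratified splitting.

## Known limitations

- Attention pooling partially subsumes the patch filter. Because the
  recovery requirement forces the signal and noise populations to be
  nearly linearly separable, a trained linear attention score can learn to
  down-weight noise patches on *unfiltered* bags. On the reference
  conditions the filter's retrieval gain survives for both poolings
  (ranking is sensitive to residual attention leakage), but its
  classification gain under attention pooling is small with
  seed-dependent sign — only average pooling shows a stable
  classification gain. Practically: the filter buys the most where
  aggregation is nonparametric or training budget is limited.
- The k = 2 premise is modeled, not tested: cohorts whose irrelevant
  patches form several well-separated modes would break both the filter
  and the attention short-cut, and are out of the generator's scope.
- Deep-backbone adapters are interface-only here; all quantitative
  statements use the built-in extractor or raw synthetic features.
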