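# Methods

`herdid` implements gallery-based open-set re-identification of individual
animals from face crops: a metric-learning objective that shapes an embedding
space, a dynamic reference gallery matched by cosine similarity, and the
evaluation machinery for systems that must both label enrolled individuals
and reject unseen ones.

## Model and objective

A backbone maps a face crop to a fixed-dimension global feature (a ViT-Base
CLS token is the canonical choice, emitting 768 dimensions; any callable with
an `extract(images) -> (B, feature_dim)` method can be plugged in).  An
embedding head projects this feature into the matching space:

    768 → Linear → 512 → BatchNorm → ReLU → Dropout → Linear → 64 → BatchNorm

Inference embeddings are L2-normalized, so all comparisons are angular.

Training minimizes a weighted dual objective

    L = λ₁ · L_SAL + λ₂ · L_center,   λ₁ = 1, λ₂ = 0.5 (defaults)

**Sub-center ArcFace (L_SAL).**  Each class *j* owns K unit-norm sub-center
vectors W_j^k; the class angle for sample *i* is
θ_ij = arccos(max_k W_j^kᵀ x̂_i).  The loss is the additive angular-margin
softmax, batch-averaged:

    L_SAL = −(1/N) Σᵢ log [ e^{s·cos(θ_iy + m)} / ( e^{s·cos(θ_iy + m)} + Σ_{j≠y} e^{s·cosθ_ij} ) ]

Defaults: margin m = 28.6°, scale s = 64, K = 3 sub-centers.  The margin is
accepted in **degrees** and applied in radians (28.6° = 0.4992 rad, the
canonical ArcFace ≈ 0.5 rad); a bare "28.6" only makes sense on that scale.
Multiple sub-centers let a multimodal class (pose, lighting, growth stage)
occupy several modes without an intra-class penalty.

**Center loss.**  L_center = Σᵢ ‖x_i − c_{y_i}‖², pulling embeddings toward
their class centers.  The printed form is a batch **sum** and that is the
default reduction; a batch-mean variant is available
(`center_reduction="mean"`) since the sum couples the effective λ₂ to the
batch size.

Numerical choices:

* Cosines are clamped to [−1 + 1e−7, 1 − 1e−7] before any arccos.
* cos(θ + m) is computed through the identity cosθ·cos m − sinθ·sin m with
  sinθ = √(1 − cos²θ); no "easy-margin" correction is applied — the loss is
  exactly the stated formula.
* L_SAL is averaged over the batch (the per-sample formula does not fix a
  reduction; the mean keeps gradients batch-size-independent).
* Class centers are ordinary trainable parameters optimized jointly with the
  network by the same Adam optimizer — the simplest faithful choice; the
  classic exponential-moving-average center update is deliberately out of
  scope.
* Sub-center weights are initialized as unit-normalized isotropic Gaussian
  draws and re-projected onto the unit sphere after every optimizer step.
* Degenerate cases: a single class makes the angular-margin softmax vanish
  identically (the rival sum is empty), so training requires ≥ 2 classes;
  a training batch of one sample is rejected because batch-norm statistics
  are undefined.

All gradients come from a small reverse-mode autodiff engine over numpy
(`herdid.autograd`), validated against central finite differences to 1e−4
relative tolerance in the test-suite.

## Backbone and training at desk scale

The pretrained transformer backbone sits behind the `BackboneContract`
interface and is not part of this package.  For self-contained runs the
package ships `TinyConvBackbone`: three fixed 3×3 conv + ReLU + 2×2 max-pool
blocks followed by a seeded random projection to 768 features.  Its filters
are random and **frozen**; only the head, the sub-center bank and the class
centers train.  This mirrors the transfer-learning setting — a fixed
pretrained extractor with a trained metric head — and random convolutional
features are a classical frozen-extractor baseline that is entirely adequate
for the procedural synthetic identities the generator produces.

The reference optimization setting is Adam at 1e−5 with step decay, 200
epochs, batch 128, and that remains the config default.  Desk-scale runs
(the test-suite and the acceptance script) train a from-scratch head for 30
epochs at 1e−3 with batch 64 — a from-random-init head needs the larger
rate, and 30 epochs suffice at this problem size (8 identities × 30 training
images).  ImageNet normalization constants (mean [0.485, 0.456, 0.406], std
[0.229, 0.224, 0.225]) apply only when a pretrained backbone is used;
synthetic images stay in [0, 1].

## The feature gallery

The gallery stores, per enrolled identity, `n_img` unit-norm reference
embeddings (conceptually an (N_class, N_img, D) array; `n_img` defaults to
30, the size at which the gallery-size study plateaus).  The stored dimension
follows the active extractor (64 for the trained head).  Matching is 1:N
cosine similarity against **every** stored vector; the identity holding the
single highest score wins (max aggregation; a mean-per-identity pooling is
available for top-k display).  Decision rule: best score ≥ θ accepts the
matched identity; strictly below θ the query is UNKNOWN.  The boundary
accepts — only scores that *fall below* the threshold reject.

Dynamic registration consumes a stream of query groups (one group per
putative individual; the grouping comes from the input — no clustering of
unknowns is attempted).  A group whose best score stays below θ receives a
fresh `novel_<n>` ID (monotone integers beyond the largest existing numeric
suffix, deterministic in stream order) and its registration embeddings are
enrolled; an already-known individual maps to its existing ID and the
gallery is unchanged, making resubmission idempotent.

No default threshold is shipped: the operating point is dataset- and
model-dependent, and the F1-Open sweep exists precisely to choose it.

## Evaluation

Closed-set (no rejection, known queries only): CSA (argmax accuracy), macro
precision/recall/F1, AMI/NMI between true and predicted partitions, the
confusion matrix, and retrieval metrics (precision@1, R-precision, MAP@R
with R = the per-query count of same-identity gallery items; a query ranking
its own gallery excludes itself).

Open-set, at threshold θ:

* CCR(θ) = P(correct argmax AND accepted | known query),
* FAR(θ) = P(accepted | unknown query),
* F1-Open(θ): per known class, a rejected or mispredicted known query is a
  false negative, an accepted unknown a false positive of the predicted
  class; the reported value is the **macro** average over known classes (a
  micro variant is behind a flag).  The macro convention was chosen because
  the companion closed-set precision/recall/F1 are macro-averaged; reports
  state which convention produced them.
* OSCR: trapezoidal area under the CCR-vs-FAR curve swept over all observed
  scores (plus sentinels).  The sweep is traversed in descending-threshold
  order so that points tied in FAR keep the attainable (highest-CCR)
  operating point.
* AUROC / AUPR on the best score with known as the positive class (rank
  formulation; step-wise precision-recall summation).

The threshold sweep evaluates F1-Open/CCR/FAR at every unique observed
score; the selected threshold maximizes F1-Open, ties breaking toward the
smaller threshold.  FAR and CCR are non-increasing in θ by construction and
that invariant is asserted in tests on every sweep.  Argmax ties in matching
break toward the lexicographically smallest identity, for reproducibility.

Standard scalar metrics (ROC-AUC, average precision, AMI, NMI, macro P/R/F1,
confusion counts) are computed via scikit-learn; the open-set machinery
(CCR/FAR, OSCR, F1-Open, sweep, retrieval) is implemented here and checked
against independent oracles (O(n²) pair counting for AUROC, fine-grid
integration for OSCR, hand confusion tables for F1-Open).

## Synthetic identities

Two fidelity levels, both driven by one seeded generator stream:

* **Embedding level** — each identity is a von Mises–Fisher cluster on the
  unit sphere: mean directions drawn with a minimum pairwise angle (default
  25°; rejection sampling with a diagnostic on infeasible packings) and
  samples at concentration κ.  κ = 0 degenerates to uniform draws — no
  identity signal, the null condition.  Sampling uses
  `scipy.stats.vonmises_fisher`.
* **Image level** — each identity is a procedural pattern (seeded sinusoidal
  texture plus a constellation of colored Gaussian blobs) on a 48 px canvas;
  same-identity images differ only by nuisance draws: brightness scaling,
  integer translation, a square occluder covering a configurable area
  fraction, and pixel noise.

The five-way protocol mirrors the study design: known-identity train /
gallery-registration / test splits plus unknown-identity registration and
test splits.  Full-scale defaults are 56 known and 9 unknown identities with
30 gallery images each; the desk-scale preset used throughout the fast tests
is 8 known / 3 unknown / 10 gallery images.  Unknown identities never appear
in known splits and every generated item belongs to exactly one split
(property-tested over 20 seeds).

Generator conditions used by the acceptance script, chosen once as the
regimes each study exercises:

* *End-to-end recovery*: image protocol at desk scale with pixel noise 0.05
  and 10 % occlusion — enough nuisance that the untrained features are
  imperfect and training has something to recover.
* *Registration arithmetic (56 + 9 → 65)*: embedding protocol at κ = 200
  with 40° minimum separation — the well-separated regime that trained
  embeddings occupy in deployment (same-identity scores far above
  cross-identity ones), which is the condition threshold-gated registration
  is designed for.
* *Gallery-size study*: κ = 45 with 5 training-free seeds — clusters broad
  enough that closed-set accuracy sits in the mid-90 % range and the benefit
  of more reference images is measurable.
* *Null ablation*: κ = 0, where AUROC should be 0.5 up to Monte-Carlo error.

What the generator does **not** model: real pose articulation, illumination
physics, background clutter, inter-animal resemblance structure, or
morphology of any particular species.  Passing tests therefore demonstrate
that the machinery is correct and recovers planted identity structure, not
that any particular accuracy will transfer to real livestock imagery.

## Known limitations

* The autodiff engine is deliberately minimal (float64, no fusion, no
  GPU); training beyond a few thousand images calls for swapping in a real
  deep-learning stack behind `BackboneContract`.
* The frozen-backbone setting means image-level performance is bounded by
  random-feature quality; fine-tuning a backbone is out of scope.
* Group-level dynamic registration aggregates a group's queries by max,
  which inflates scores for large groups of broad clusters; in marginal
  regimes the operating threshold should be swept on group-level scores.
* No tracking across frames, no gallery pruning, no unsupervised clustering
  of unknowns.
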