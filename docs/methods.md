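# Methods

## Model

The grading embedding is learned by three cooperating, label-free
constraints over mini-batch graphs.

**Encoder.** `r(·; θ)` maps an RGB image to a `feature_dim`-vector. The
default `small_conv` backbone is three conv(3×3)→ReLU→avgpool(2) blocks with
channel widths (8, 16, 32), global average pooling, and a linear head to 16
features. A normalization-free bottleneck residual stack with the standard
[3, 4, 6, 3] stage plan is available as `architecture="residual_50"` for
full-scale experiments; the method is architecture-agnostic and nothing in
the tests depends on the large backbone. All arithmetic is float64; the
backward pass is written by hand and validated against central differences.

Input images are standardized per image (subtract mean, divide by std)
before the first convolution (`EncoderConfig.standardize_input`, default
on). This is the one preprocessing step taken: without it, the features of a
randomly initialized encoder are almost pure brightness detectors
(correlation ≈ 0.97 with mean intensity on the synthetic benchmark), the
KNN graph groups images by illumination, and the shared-neighbor
pseudo-labels start at chance — the unsupervised bootstrap then cannot
recover the pathology signal at all.

Biases are initialized uniform(−0.01, 0.01) rather than zero. Zero biases
put every all-zero input patch (black background around the fundus field)
exactly on the ReLU kink, where the loss is not differentiable and
finite-difference checks legitimately disagree with any subgradient choice;
tiny random biases remove this measure-zero degeneracy without affecting
learning.

**Graph.** Per batch, each sample is connected to its K nearest neighbors in
Euclidean feature space (ties broken by lowest index; duplicate rows are
therefore legal). The directed adjacency is symmetrized by logical OR,
self-loops are added (config flag, default on — symmetric normalization is
undefined on zero-degree nodes), and propagation uses
`D^{-1/2} A D^{-1/2}`. The default GCN has one layer, width equal to
`feature_dim`, and **no ReLU on the output layer**: the losses measure
Euclidean geometry of Z, and clamping to the non-negative orthant would
halve the usable embedding space.

**Pseudo-labels.** `l(k,j) = 1` iff the K-neighbor sets of k and j share
strictly more than λ members (λ defaults to ⌊K/2⌋). The estimator is
symmetric, excludes self-pairs, and is monotone in shared neighbors. Labels
and adjacency are discrete selections: they are recomputed every step from
the current features and receive no gradient.

**Losses.** Graph-center: `½ Σ_kj A_kj ‖Z_j − Z_k‖²` on the zero-diagonal
symmetrized adjacency (an unnormalized sum over edges — it dominates early
training and shrinks as neighborhoods tighten). Pseudo-contrastive:
`(1/(2N)) Σ_pairs [l·d² + (1−l)·max(m−d, 0)²]` where N is the number of
unordered pairs in the batch (reading the normalizer as the dataset size
would make the per-batch loss vanish at scale). Transform-invariant: the
mean *unsquared* distance `‖Z_k − Z'_k‖` between the embeddings of each
image and a randomly rotated copy, both propagated through the **same**
graph built from the original view (a squared variant and per-view graph
rebuilding exist behind config flags). Total: `L_pc + α·L_gc + β·L_ti`.

## Parameter defaults

| parameter | default | why |
|---|---|---|
| α, β, margin m | 0.1, 0.1, 1.0 | balance/margin values are not dictated by the method; these moderate settings keep all three terms active |
| K / λ | 3 / ⌊K/2⌋ = 1 | small neighborhoods keep batch KNN precise; λ follows the half-K rule |
| batch size B | 8 | ~2–3 same-class images per batch suffice for the estimator, and smaller batches double the optimizer updates per epoch, which proved decisively more reliable |
| optimizer | Adam, lr 1e-3 | the objective mixes an unnormalized edge sum (gc) with pair-averaged bounded terms (pc, ti); fixed-lr SGD with momentum either collapses the embedding or oscillates, while per-parameter adaptive steps converge across seeds. SGD+momentum remains available (`optimizer_name="sgd"`) |
| epochs | 15 | the benchmark budget; loss plateaus within it at desk scale |
| transform family | rotation uniform in ±180° | fundus images carry no canonical orientation, so the full rotation group is label-preserving; the stronger invariance constraint also stabilizes the unsupervised bootstrap, where a ±30° family is marginal |
| feature_dim / GCN | 16 / 1 linear layer | smallest sizes that carry the 5-grade structure |

Unsupervised bootstrap caveat: success depends on the randomly initialized
features exposing *some* class structure to the KNN graph — pseudo-label
precision must start above chance for self-training to amplify signal
rather than noise. This is seed-dependent; on the synthetic benchmark a
majority of seeds recover grades and the test suite asserts exactly that
(majority over three seeds), not per-seed success.

## Prediction and evaluation

Gallery images (few per class, with trusted grades) are embedded in
evaluation mode over a gallery-internal KNN graph. Each query is embedded in
a graph over {query} ∪ gallery — never over other queries — and matched
against the gallery embeddings *from the same propagation pass*; predictions
are therefore deterministic, label-blind, and independent of query ordering
or batching. A query whose encoder features coincide bitwise with a gallery
row is matched to it at distance exactly zero (the duplicate node would
otherwise perturb KNN tie-breaking).

The continuous score behind the ROC is the distance margin: distance to the
nearest non-referable gallery embedding minus distance to the nearest
referable one (config-switchable to the negative distance-to-referable).
Confidence intervals are Wilson score at 95%. Two-dimensional visualization
is delegated: evaluation exports an embeddings TSV for external t-SNE/UMAP.

## Synthetic benchmark

The generator emulates the structure of DR screening data, not its
photorealism: a circular fundus field with radial falloff, an optic-disc
blob, four vessel-like quadratic curves, and lesions as small bright
(exudate-like) or dark (hemorrhage-like) Gaussian blobs. Lesion counts are
Poisson with grade means (0, 2, 5, 9, 14) — grade 0 is defined as lesion
free — under ±25% brightness jitter, ±25% contrast jitter, and ±4 px center
shifts at 64 px. These nuisance ranges are deliberately strong enough that
raw pixel statistics are illumination-dominated.

What a green benchmark run does establish: the pipeline can recover a
severity grading from unlabeled images whose class signal is lesion load
under nuisance illumination/contrast/viewpoint, beating the same pipeline
with untrained weights by a wide margin. What it does not establish:
performance on real fundus photographs (camera variety, resolution, lesion
taxonomy, class imbalance, inter-grader disagreement are all absent), or
the behavior of the 50-layer backbone.

The 3-grade benchmark uses grades (0, 2, 4) — both ends and the middle of
the severity scale — so the referable binarization (grade ≥ 2) contains
both classes.

## Numerical choices

* float64 throughout; checkpoints are a deterministic binary container
  (JSON header + raw array bytes) so identical runs are byte-identical.
* KNN ties break to the lowest index; `argmin` tie-breaks likewise.
* The hinge and the unsquared ti norm are non-differentiable at isolated
  points; subgradient 0 is used at exactly-zero distances.
* One global seed fans out through `numpy.random.SeedSequence.spawn` into
  independent streams for initialization, shuffling, and transform
  sampling; checkpoints store the bit-generator states, so resumed training
  reproduces the uninterrupted trajectory exactly.
* The final partial batch of each epoch is dropped (fixed B keeps the KNN
  graph and pair normalizers well-defined).

## Known limitations

* Desk-scale only: dense B×B graphs, numpy conv — minutes per benchmark
  run, not suitable for 10⁵-image corpora.
* No batch normalization in either backbone; the residual stack is provided
  for completeness but untested at scale.
* Pseudo-label quality, and hence everything downstream, degrades when
  batches are class-imbalanced or when nuisance variation dominates the
  encoder's initial geometry; the per-image standardization default
  addresses illumination but nothing else.
* Grades are treated as nominal classes; the ordinal structure of the
  severity scale is not exploited.
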