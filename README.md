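# dgcn — annotation-free retinal image grading

Diabetic retinopathy (DR) is screened from macula-centered fundus
photographs and graded on the five-level International Clinical Retinopathy
Scale (0 none, 1 mild, 2 moderate, 3 severe, 4 proliferative). Supervised
deep learning graders need large expert-annotated image sets; this package
implements a **deep graph correlation network (DGCN)** that learns a grading
embedding from *unlabeled* images and needs only a handful of labeled
"gallery" images at prediction time.

## Method

Each image `I_k` in a mini-batch is mapped to a feature vector
`F_k = r(I_k; θ)` by a convolutional encoder. A K-nearest-neighbor graph
over the batch features defines a binary adjacency `A` (edges to the K
nearest neighbors, OR-symmetrized, self-loops added), which is propagated by
graph convolution

    X^(l) = σ( D^{-1/2} A D^{-1/2} X^(l-1) W^(l) ),    X^(0) = F_b,

yielding graph representations `Z`. Training minimizes

    L = L_pc + α·L_gc + β·L_ti

with three label-free terms:

* **graph-center loss** `L_gc = ½ Σ_kj A_kj ‖Z_j − Z_k‖²` — pulls
  graph-connected embeddings together;
* **pseudo-contrastive loss** `L_pc` — a margin contrastive loss over all
  batch pairs, driven by pairwise pseudo-labels
  `l(k,j) = 1 ⇔ |K_k ∩ K_j| > λ` (two images sharing more than λ of their K
  nearest neighbors are presumed to be the same grade);
* **transform-invariant loss** `L_ti = (1/B) Σ_k ‖Z_k − Z'_k‖` — penalizes
  embedding change under a random label-preserving rotation `I'_k = T(I_k)`.

A query image is graded by the label of its nearest gallery embedding
(Euclidean distance). Evaluation reports the multi-class confusion matrix
and — on the *referable* binarization (grade ≥ 2) — sensitivity
`TP/(TP+FN)`, specificity `TN/(TN+FP)`, accuracy with Wilson 95% CIs, and
the ROC/AUC.

The whole differentiable stack (conv encoder, GCN, losses, Adam/SGD) is
implemented in numpy with hand-written reverse-mode gradients in float64, so
analytic gradients can be (and are) verified against central finite
differences.

Because real screening sets are external and GPU-scale, the package ships a
synthetic fundus generator: circular fundus field, optic disc, vessel-like
curves, and a Poisson number of bright/dark lesion blobs whose expected
count rises with grade, under brightness/contrast jitter and viewpoint
shifts. It is first-class, tested code with held-out ground truth.

## Worked example

```python
import numpy as np
from dgcn import (DGCNModel, SyntheticSpec, TrainConfig,
                  generate_dataset, split_gallery_query)

data = generate_dataset(SyntheticSpec(n_per_grade=60, image_size=64,
                                      grades=(0, 2, 4), seed=0))
gallery, query = split_gallery_query(data, 5, np.random.default_rng(1))

results = DGCNModel(data.images, TrainConfig(seed=0)).fit()
gset = results.build_gallery(gallery.images, gallery.grades)
report = results.evaluate(query.images, query.grades, gset)
print(results.summary(evaluation=report))
```

This (the pipeline `scripts/acceptance.py --seed 0` runs) prints:

```
Deep Graph Correlation Network — run summary
====================================================
encoder            small_conv (d=16)
gcn layers         1 (self-loops=True)
batch / K / lambda 8 / 3 / 1
alpha / beta / m   0.1 / 0.1 / 1.0
optimizer          adam lr=0.001 momentum=0.9
epochs / steps     15 / 330
total loss         1.0949 -> 0.2204
  pc               0.1785 -> 0.1768
  gc               9.1128 -> 0.4117
  ti               0.0508 -> 0.0244
----------------------------------------------------
queries            165
5-class accuracy   0.836
referable accuracy 91.5% (95% CI 86.3–94.9)
sensitivity        87.3% (95% CI 79.8–92.3)
specificity        100.0% (95% CI 93.5–100.0)
AUC                0.992
```

Reading it: training never saw a grade, yet 83.6% of 165 held-out queries
receive the exact grade of their nearest labeled gallery image (chance is
33%), and the referable/non-referable decision reaches AUC 0.992. The
graph-center term dominates the loss drop (9.11 → 0.41) as neighborhoods
tighten; the invariance term halves as rotations stop moving embeddings.
Runs are seed-dependent: some initializations bootstrap weaker pseudo-labels
and land lower — the test suite asserts a majority of seeds succeed.

## Command line

```bash
dgcn synth    --out data/ --n-per-grade 60 --image-size 64 --seed 0
dgcn train    --data data/ --out run/ --seed 0          # never reads labels
dgcn predict  --checkpoint run/checkpoint.bin --gallery gal/ \
              --gallery-manifest gal/manifest.tsv --query q/ --out pred.tsv
dgcn evaluate --checkpoint run/checkpoint.bin --gallery gal/ \
              --gallery-manifest gal/manifest.tsv --query q/ \
              --truth q/manifest.tsv --out metrics.json
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
regenerates the synthetic benchmark, trains the network label-free from
scratch, grades the disjoint query set against a 5-per-class gallery, and
prints the full evaluation summary. The package has no numeric acceptance
targets, so the JSON written to `--out` is an empty object; the run itself
exercises generation, training, gallery matching, and every metric.

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
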