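# histokey

Unsupervised discovery of interpretable, outcome-associated image features
from unannotated pathology slides — built around the oral lichen planus
(OLP) immunosuppressive-therapy setting, and exercisable end-to-end on
synthetic pseudo-slides.

Many patients with OLP respond poorly to immunosuppressive therapy, and
pathologists have no annotated atlas of which tissue appearances predict
response. `histokey` implements a label-light workflow that finds such
features automatically: slides are cut gaplessly into 128×128 patches,
low-quality patches are filtered out, a convolutional autoencoder embeds
each patch into a 2048-number latent vector, and k-means groups the
latents into *features* (clusters), one per training slide by default.
Each patch inherits the binary response label of its slide (positive =
effective therapy), and each cluster k is scored by

- positive rate  r₊ₖ = (positive patches in k) / n₊
- negative rate  r₋ₖ = (negative patches in k) / n₋
- impact score  Iₖ = r₊ₖ / (r₊ₖ + r₋ₖ)  ∈ [0, 1]
- weight  Wₖ = 1 + |0.5 − Iₖ|  ∈ [1, 1.5]

Clusters with Iₖ > 0.5 are enriched in responders (*positive features*),
Iₖ < 0.5 in non-responders. A *key feature* is a cluster with Wₖ > 1.1
whose morphology is tissue-driven ("histology") rather than a tiling
artifact ("shape"). For prediction, each slide becomes a length-k vector
of Wₖ-weighted cluster-occupancy fractions, fed to logistic-regression or
linear-SVM classifiers under stratified 10-fold cross-validation with
ROC/AUC reporting. A clinical module computes the 11-site OLP sign score
(lesion-type weights 1 / 1.5 / 2) whose >10 % decline between the first
and third visit defines the "effective" label.

Everything is testable without clinical data: `histokey.synthetic`
generates labeled pseudo-slides from procedural texture classes whose
label-conditional composition gives every cluster a known ground-truth
impact score ρ = p/(p+q).

## Worked example

Six labeled patches (4 positive, 2 negative) in two clusters — cluster 0
holds 3 positives + 1 negative, cluster 1 holds 1 positive + 1 negative:

```python
import histokey as hk
from histokey.scoring import select_key_features

scores = hk.compute_scores([0, 0, 0, 0, 1, 1], [1, 1, 1, 0, 1, 0], k=2)
fm = select_key_features(scores, morphology={0: "histology", 1: "histology"})
print(fm.frame()[["cluster", "size", "n_pos", "n_neg", "r_plus", "r_minus",
                  "I_k", "W_k", "polarity", "is_key"]].to_string(index=False))
```

```
 cluster  size  n_pos  n_neg  r_plus  r_minus      I_k      W_k polarity  is_key
       0     4      3      1    0.75      0.5 0.600000 1.100000 positive   False
       1     2      1      1    0.25      0.5 0.333333 1.166667 negative    True
```

Cluster 0's impact 0.6 means its patches come disproportionately from
responders; its weight 1.1 sits exactly at the key threshold (not above
it, so it is not key). Cluster 1 (I = 1/3, W ≈ 1.167) is a key negative
feature.

The same calculus applied to the published 38-cluster reference table
shipped with the package (`histokey.load_reference_clusters()`)
reproduces the reference analysis:

```python
from histokey.scoring import load_reference_clusters, weight_from_impact

ref = load_reference_clusters()
over = ref[weight_from_impact(ref.impact_score) > 1.1]
print("clusters with W_k > 1.1:", sorted(over.cluster.tolist()))
print("key features:", over[over.morphology_class != "shape"].cluster.tolist())
```

```
clusters with W_k > 1.1: [2, 9, 15, 17, 27, 30, 31, 33]
key features: [33, 15, 9, 2, 27, 30]
```

Eight clusters exceed the weight threshold; removing the two tiling-shape
clusters (17, 31) leaves the six key features — three positive
(lymphocyte-associated clusters 33, 15, 9) and three negative (vessels 2,
loose connective tissue 27, lymphocyte-poor epithelium 30).

## End-to-end on synthetic slides

```python
import histokey as hk

cohort = hk.make_cohort(n_slides=20, grid=(6, 6), seed=1)   # 10 responders / 10 non
result = hk.discover_features(cohort.slides, latent_dim=64, epochs=5,
                              n_clusters=4, seed=1)
print(result.features.scores_)          # estimated I_k per cluster
cv = result.crossvalidate(family="logistic", n_folds=10, seed=1)
print(cv.mean_accuracy, cv.auc)
```

On this cohort the recovered cluster impact scores land within ±0.05 of
the designed enrichments (0.8, 0.6, 0.4, 0.2) and cross-validated
accuracy is 1.0 — the compositions are deliberately separable.

A CLI mirrors the stages: `histokey synth | tile | qc | discover |
predict` (see `histokey --help`).

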