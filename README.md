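# slidemil

Multiple-instance-learning (MIL) pipeline for classifying epithelial ovarian
cancer subtypes — HGSC, EC, CC, LGSC, MC — from whole-slide images (WSIs),
with a focus on what actually drives performance under severe class
imbalance: the patch feature quality, the bag aggregator, and flat
five-class versus hierarchical two-stage classification.

A WSI is treated as a bag of patch embeddings `X ∈ R^{N×d}` (N ranges from a
few hundred to tens of thousands per slide). The package implements:

* **Six MIL aggregators** behind one interface — mean/max pooling, gated
  attention (ABMIL), CLAM-SB (attention plus per-class instance heads),
  DSMIL (dual instance/bag streams), and **DTP-TransMIL**: a transformer
  aggregator with *dynamic top-proportion* instance selection

      k_eff(N) = min(N, clamp(⌊0.25·N⌋, K_min=100, K_max=2000)),

  which gates the selected instances by sigmoid attention scores and feeds
  them, with a learnable CLS token, through a 2-layer, 8-head encoder.
  `count_parameters` / `count_flops` give exact complexity accounting.
* **Imbalance-aware training** — focal loss `−w_y (1−p_y)^γ log p_y` with
  γ = 2 and inverse-frequency class weights `w_c ∝ (1/f_c)^p`, p = 1.5;
  Adam with linear warmup + cosine annealing, gradient clipping, early
  stopping, stratified five-fold cross-validation, and a γ×p sensitivity
  sweep harness.
* **Flat vs. cascade evaluation** — a binary HGSC-vs-rest stage thresholded
  at each validation fold's Youden-J optimum routes slides either to an
  immediate HGSC call or to a four-class second stage; everything is scored
  out-of-fold. This guards the majority class against *majority
  suppression*: heavy minority upweighting in a flat five-class model
  depressing recall of the most prevalent (and most lethal) subtype.
* **Small-sample statistics** — exact Wilcoxon signed-rank (full 2^m sign
  enumeration; the one-sided floor at five folds is 1/32 ≈ 0.031),
  Holm–Bonferroni step-down, paired Cohen's d, Friedman omnibus.
* **Attention interpretability** — NAAR (mean attention inside an annotated
  region over mean attention across all tissue; |NAAR−1| measures departure
  from spatial randomness regardless of annotation polarity) and AMR (the
  fraction of top-q attention patches inside the annotation, baseline =
  annotated area fraction), with paired cross-feature comparisons.
* **A synthetic cohort generator** reproducing the statistical structure of
  a 510-slide imbalanced ovarian cancer cohort (42.5/23.1/18.2/8.0/8.0%
  prevalence; per-slide patch counts 228–34,412, median 7,864) with a
  class-separation knob ρ that emulates feature-extractor quality, plus
  synthetic slide images with exact tissue masks for the preprocessing
  pipeline (HSV saturation thresholding at 15, 7×7 elliptical
  closing/opening, 256×256 patch grid, >20% tissue filter, <10-patch QC).

The neural layers run on a compact numpy reverse-mode autodiff engine
(`slidemil.autodiff`, `slidemil.nn`), so the whole pipeline is pure
scientific Python with no deep-learning framework dependency.

## Worked example

Cascade versus flat on a synthetic 150-slide cohort with weak feature
separation (ρ = 0.6), mean-pooling aggregator, five shared stratified folds:

```python
import numpy as np
from slidemil.synthetic import CohortConfig, generate_cohort
from slidemil.training import TrainConfig, build_fold_assignment
from slidemil.cascade import train_stage_models, evaluate_cascade, evaluate_flat
from slidemil.aggregators import AggregatorSpec

cfg = CohortConfig(n_slides=150, seed=0, separation=0.6, embed_dim=64,
                   patch_count_range=(16, 64), patch_count_median=32)
bags, manifest = generate_cohort(cfg)
feats = [b.features.astype(np.float64) for b in bags]
labels = np.array([b.label for b in bags])

folds = build_fold_assignment(labels, k=5, seed=0)
train_cfg = TrainConfig(epochs=6, warmup_epochs=1, patience=6, lr=1e-3, seed=0)
agg = AggregatorSpec(name="meanpool", in_dim=64)
s1 = train_stage_models(feats, labels, "stage1", folds, agg, train_cfg)
s2 = train_stage_models(feats, labels, "stage2", folds, agg, train_cfg)
fl = train_stage_models(feats, labels, "flat", folds, agg, train_cfg)
cascade = evaluate_cascade(feats, labels, folds, s1, s2)
flat = evaluate_flat(feats, labels, folds, fl)
```

which prints (about a minute on one CPU):

```
class counts: [64, 35, 27, 12, 12]
cascade: balanced accuracy 0.558, HGSC recall 0.969 (2 missed)
flat:    balanced accuracy 0.515, HGSC recall 0.938 (4 missed)
```

The cohort carries the study's imbalance (64 of 150 slides are HGSC). At
this weak separation the flat five-class model — trained with heavy
inverse-frequency weights — misses twice as many HGSC slides as the
cascade, whose first stage optimizes HGSC detection as an explicit binary
objective; the minority LGSC/MC classes (12 slides each) are not yet
learnable at all. Raising `separation` toward 4 drives both strategies to a
balanced accuracy near 1.0 and the gap closes.

Architecture accounting for the transformer aggregator:

```bash
$ slidemil aggregator-info --name dtp_transmil --in-dim 1024 --classes 4
dtp_transmil: 4,996,869 parameters, 42.744 GFLOPs at N=7864
```

The CLI also exposes `simulate-cohort`, `simulate-slides`, `preprocess`,
`train` and `stats-compare`; see `slidemil --help`.

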