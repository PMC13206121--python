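# Methods

## Problem setting

Each whole-slide image is a bag `X ∈ R^{N×d}` of patch embeddings with a
single slide-level subtype label in {HGSC, EC, CC, LGSC, MC} (encoded
0–4; HGSC is class 0 throughout). Embeddings come from a frozen patch
encoder; the package is agnostic to which one, and ships a deterministic
synthetic embedder so no pretrained weights are ever needed. The cohort is
severely imbalanced (42.5% HGSC down to 8.0% LGSC and MC), and per-slide
bag sizes span two orders of magnitude, which is what motivates both the
imbalance-aware training protocol and the dynamic instance selection of
the transformer aggregator.

## Preprocessing model

`segment_tissue` downsamples the RGB slide by an integer factor (default
32) with exact block averaging, quantizes to 8 bits at each stage (so the
threshold has exact integer semantics, as in integer-image pipelines),
converts to HSV and calls foreground where saturation (0–255 scale)
**strictly** exceeds 15, then applies morphological closing followed by
opening with a 7×7 elliptical element, two iterations each. Erosion treats
the region outside the image as foreground, the common convention that
prevents a fully-tissue slide from being eaten at its borders.
`extract_patches` walks the non-overlapping 256×256 level-0 grid anchored
at (0,0); a tile is kept when the foreground fraction of its aligned 8×8
block in the downsampled mask strictly exceeds 0.20 (so 13/64 passes and
12/64 fails); partial edge tiles are discarded; slides with fewer than 10
tissue patches are dropped. Tissue fractions are evaluated at mask
resolution because 256/32 gives exact block alignment, making the
computation deterministic and cheap. Patches destined for embedding are
bilinearly resized to 224×224 and standardized with the ImageNet
per-channel mean and standard deviation.

## Aggregators

All six heads share an input projection fc1 (`in_dim→512`, ReLU, dropout
0.25). The architecture internals are fixed by exact parameter accounting:

| head | structure above fc1 | parameters (in=1024, C=4) |
|---|---|---|
| mean/max pooling | pool → 512→256→C classifier | 657,156 |
| ABMIL | gated attention (V,U: 512→256, w: 256→1) → 512→C | 789,765 |
| CLAM-SB | ABMIL + C instance heads 512→2 | 793,869 |
| DSMIL | instance head 512→C, query 512→128, bag head 512→C | 594,568 |
| DTP-TransMIL | scorer 512→256→1 (tanh), pre/final LayerNorm, CLS token, 2-layer encoder (d=512, 8 heads, FFN 1024), 512→256→C | 4,996,869 |

Notable consequences of the accounting: the pooling heads use the
two-layer 512→256→C classifier while ABMIL/CLAM use a single 512→C affine
— the only integer-consistent decomposition given the totals and the
attention share (~33% for V+U); the DTP encoder holds 84.2% of its
parameters and fc1 10.5%; CLAM exceeds ABMIL by exactly 4·(512·2+2) =
4,104. DSMIL's published layer sizes are not recoverable from totals
alone; the implementation here uses an identity value map and a per-class
bag scorer, and its count is reported but not treated as a reference
value. Dropout rates (fc1 0.25, classifier/encoder 0.1) follow common MIL
defaults and contribute no parameters.

DTP selection: `k_eff(N) = min(N, clamp(⌊0.25·N⌋, 100, 2000))` with floor
semantics (so N = 400 is the first bag size whose proportional share
reaches the K_min floor, and saturation begins exactly at N* = 2000/0.25 =
8000). Ties in the score ranking break toward the lower instance index,
making selection deterministic; token order is score rank and there is no
positional encoding. The scorer runs on every instance, so attention maps
cover the full bag whether or not an instance was selected.

FLOP accounting uses the convention: an affine map in→out over T tokens
costs 2·in·out·T; each elementwise activation, pooling reduction or
attention weighting costs 1 per element; softmaxes and attention score
maps are counted per element; biases and dropout are not counted. Under
this convention mean pooling at N = 7,864 and in_dim 1024 costs 8.254
GFLOPs. Transformer FLOP conventions vary more across the literature
(whether both attention matmuls, the softmax and the residual/norm
elementwise work are included); the DTP figure reported by `count_flops`
(42.7 GFLOPs at N = 7,864) is internally consistent with the stated
convention but, unlike the pooling figure, has no convention-independent
reference value.

## Training protocol

One bag per optimization step (batch size 1). Loss is focal,
`−w_y (1−p_y)^γ log p_y` with γ = 2.0 by default, where the class weights
are inverse-frequency with exponent p = 1.5, renormalized to mean 1 so the
loss scale is comparable across p (the renormalization is this package's
choice; it does not change relative class emphasis). CLAM adds 0.3× an
instance-level cross-entropy on the 8 highest- and 8 lowest-attention
instances under the true class's head. Adam (β = 0.9/0.999, ε = 1e-8 —
standard defaults) with weight decay 1e-4, gradient clipping at global
norm 1.0, and a schedule that ramps linearly to the base rate over the
warmup epochs — reaching it at the last warmup epoch, so the cosine phase
that follows is continuous — then anneals as
`lr·½(1+cos(π(e−w)/(E−w)))`. Early stopping monitors AUROC for the binary
stage and balanced accuracy otherwise, restores best-epoch weights, and
stops after `patience` improvement-free epochs. Reference defaults: lr
1e-4, 150 epochs, 15 warmup, patience 30. Everything (initialization,
shuffling, dropout masks) is driven by a single seed, so identical
configurations give bitwise-identical loss histories.

Fold assignments are stratified, deterministic in the seed, and shared
across methods: binary stratification over all slides for stage 1,
four-class stratification over non-HGSC slides for stage 2, five-class
for flat (the flat scheme is this package's choice; the two staged
schemes define the protocol). The γ×p sensitivity sweep trains one model
per grid cell per fold and emits a long-format table.

## Cascade evaluation

Stage 1 scores every slide out-of-fold; each fold's operating threshold
maximizes Youden's J over the observed scores of that validation fold
(ties toward the smallest threshold, favoring sensitivity; positive call
at score ≥ τ). Slides at or above the threshold are labeled HGSC
immediately. Non-routed non-HGSC slides are classified by their own
stage-2 out-of-fold model. Non-routed HGSC slides — stage-1 false
negatives, which by construction belong to no stage-2 fold — use the
stage-2 model sharing their stage-1 fold index (a deliberate convention;
any fixed choice only affects which wrong non-HGSC label they receive).
Note the Youden threshold is tuned on the same validation fold that is
scored out-of-fold, a mild optimism inherent to the protocol and
implemented as stated rather than "fixed". Metrics: 5×5 confusion,
per-class precision/recall/F1, balanced accuracy (unweighted mean of
per-class recalls), HGSC recall and missed count.

## Statistics

With five folds there are only five paired observations per comparison, so
`wilcoxon_exact` enumerates the full 2^m sign-assignment distribution of
the signed-rank statistic (zeros dropped, average ranks on ties); the
one-sided floor at m = 5 is exactly 1/32 = 0.03125, and Holm over five
simultaneous tests maps it to 0.15625. Beyond 15 nonzero pairs (used only
by the interpretability comparisons, which involve dozens of slides) the
tie-corrected normal approximation with continuity correction takes over.
Holm is the standard step-down with a cumulative max, which enforces
monotonicity of adjusted values. Paired Cohen's d uses the sample standard
deviation (n−1); zero spread with zero mean is reported as d = 0, zero
spread with nonzero mean as undefined (not infinite). The Friedman
statistic uses the classical `12n/(k(k+1)) Σ(R̄_j−(k+1)/2)²` form without
a tie-correction factor, with a χ²(k−1) reference distribution.

## Attention-alignment metrics

NAAR = mean attention inside the annotation / mean attention over all
valid tissue. Its ratio form is invariant to positive rescaling, so the
display-only min-max normalization of heatmaps never affects it, and
|NAAR−1| is polarity-agnostic: a model that concentrates on tumor scores
NAAR > 1 against a tumor annotation and NAAR < 1 against a normal-tissue
annotation, but departs from 1 in both cases. AMR at threshold q is the
fraction of the top ⌈qN⌉ patches (by score, ties toward lower index that
makes the set deterministic) inside the annotation; its expectation under
random allocation is the annotated area fraction. AMR is defined here as
a count fraction rather than an attention-mass share — both have the same
random baseline, and the count version is deterministic under ties.
Metrics use raw per-patch scores: sigmoid scorer outputs over all patches
for DTP, softmax weights for ABMIL/CLAM, bag-stream attention for DSMIL.
Cross-feature comparisons restrict to slides evaluable under every
condition and run paired Wilcoxon tests on |NAAR−1|.

## Synthetic cohort generator

The generator is the package's study bed and defines what passing tests
demonstrate. Labels are apportioned by the deterministic largest-remainder
method from the prevalence vector (42.5/23.1/18.2/8.0/8.0%; the printed
percentages sum to 99.8% due to rounding and are renormalized internally
— apportioning 510 slides still yields exactly 217/118/93/41/41), then
shuffled under the seed. Per-slide patch counts are log-normal with the
median forced to the cohort median (7,864 by default) and σ = 0.63 chosen
from the cohort's mean/median ratio (9,593/7,864 = 1.22 = exp(σ²/2)),
clipped to [228, 34,412]. Each bag mixes "tumor" instances
`~ N(ρ·μ_c, σ_n² I)` around a fixed unit-norm class centroid μ_c with
"background" instances `~ N(0, σ_n² I)`; the tumor fraction is
Beta(8, 2)-distributed (mean 0.8 — most of a slide's tissue patches carry
subtype signal; the cohort itself reports no per-class tumor-fraction
statistics, so this is a free modeling choice). The separation knob ρ is
the feature-quality dial: ρ = 0 carries no class information at all and
any classifier is at chance (0.2 balanced accuracy for five classes),
while large ρ makes bag means nearly linearly separable. Centroids come
from a fixed internal seed so all cohorts share class geometry.

What the generator does **not** emulate: stain and scanner variation,
spatial correlation of tumor regions (tumor flags are spatially random
within a bag), non-isotropic or heavy-tailed embedding noise, and any
morphological realism in the synthetic slide images (elliptical saturated
blobs on white, with exact ground-truth masks). Passing tests therefore
demonstrate the correctness and the qualitative behavior of the
*algorithms* — imbalance handling, cascade routing, selection rules,
alignment metrics — not performance on real histopathology.

## Desk-scale problem sizes

The simulation checks run the full protocol at sizes chosen for a single
CPU. The cascade-vs-flat check uses 510-slide cohorts with the reference
class proportions at separation ρ = 1.0 ("moderate": individual bags are
informative but fold-level errors remain), d = 64, bags of 16–128 patches
(median 48), and a shortened protocol (lr 1e-3, 5 epochs, 1 warmup) —
five cohort seeds, asserting cascade HGSC recall ≥ flat HGSC recall in at
least four. The separation-monotonicity check trains on 150-slide cohorts
at ρ ∈ {0, 1, 4} across three seeds. The reference protocol (lr 1e-4, 150
epochs) remains the default configuration; the shortened settings are
explicit arguments of the tests.

## Numerical and engineering choices

The aggregators and training loop run on an in-repo reverse-mode autodiff
engine over float64 numpy arrays (`slidemil.autodiff`): broadcasted
arithmetic, batched matmul, softmax/log-softmax and layer normalization as
fused primitives, max-reductions routing gradient to the argmax, and
differentiable row gathering for instance selection (gradients flow to
selected instances through the sigmoid gate; the ranking itself is
treated as constant, as is standard for top-k selection). Dropout is an
inverted mask drawn from the model's own generator, so training is
reproducible from the seed. Adam re-binds parameters as views into one
contiguous buffer and updates in place, which keeps the single-CPU step
time flat. The fp16 flag is accepted for configuration parity but
arithmetic stays in full precision. Degenerate inputs (empty annotations,
zero attention mass, single-class splits, all-zero difference vectors)
raise informative `ValueError`s rather than producing NaNs.
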