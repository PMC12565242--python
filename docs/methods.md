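# Methods

`ctslider` implements a two-stage pipeline for screening progressive
fibrosing interstitial lung disease (PF-ILD) from a small number of chest-CT
slices: (1) anatomy-anchored selection of representative slices (RS) driven
by a slice classifier and peak slice mining, and (2) a case-level classifier
built from a frozen vision transformer with small trainable slice-level 3D
adapters. Everything is exercised end to end on synthetic CT phantoms with
known ground truth.

## Position markers and peak slice mining

Three anatomical position markers (PMs) are defined per axial series
(superior → inferior, 0-based indices):

* **upper** — the first slice with aerated lung parenchyma in either
  hemithorax (tracheal air is ignored);
* **middle** — the first slice where the trachea has split into two
  bronchial lumens separated by a soft-tissue wall;
* **lower** — the slice exactly three slices superior to the level where
  aerated parenchyma disappears bilaterally. The clinical rule allows three
  *to four* slices; this implementation fixes three so that ground truth is
  deterministic.

A four-class slice classifier (upper / middle / lower / non-PM) is trained
on a rebalanced dataset: non-PM slices are randomly downsampled by 75%
(retain 25%) and each PM class is oversampled — replicas flagged for light
augmentation (sub-pixel shifts plus noise) — until it matches the retained
non-PM count. On the balanced set the inverse-frequency class weights are
uniform; the weights remain configurable.

At inference, peak slice mining (PSM) selects one slice per PM class from
the case's confidence matrix c ∈ R^(M×C): each class column is
softmax-normalised **along the slice axis** and the argmax slice is taken,
ties to the smallest index. Selection operates on raw logits — the slice
softmax is a monotone per-column transform, so it cannot change the argmax;
it is kept to report calibrated per-slice probabilities. Feeding
class-softmax probabilities instead was measured to be strictly worse on
the phantom benchmark (probability plateaus create ties across the
bifurcation run). No ordering constraint is imposed across classes; a
disordered selection triggers a warning, and the pipeline falls back to
population-typical marker fractions (8% / 40% / 79% of the stack) when a
selection cannot support RS extraction.

Marker extraction is scored with 1-Up-Down accuracy, the fraction of
predictions within one slice of truth, reported per class and averaged.

## Representative-slice geometry

With markers r_u < r_m < r_l:

* **3-RS** = { r_u + round((r_m−r_u)/3), r_m, r_m + round((r_l−r_m)/3) }
* **5-RS** = slices at 1/3 and 2/3 of both intervals plus r_m
* **9-RS** = the 3-RS slices and their immediate neighbours (±1)

Fractions are measured from the superior end of each interval; fractional
indices are rounded half away from zero (the rounding mode of the original
description is not determinable, so one was fixed and documented). The 3-RS
lower slice defaults to one third *below the bifurcation*; a
`lower_anchor="diaphragm"` flag selects the alternative reading (one third
above the diaphragm marker). 9-RS neighbours are clamped to the volume and
post-clamp duplicates are an error rather than silently repaired — note a
3-RS slice lying exactly on a volume boundary therefore always rejects.

## Preprocessing

HU windowing uses the inclusive range [level − width/2, level + width/2]
mapped affinely to 0–255 with round-half-away-from-zero quantisation. The
identification pathway fuses three fixed windows into an RGB composite:
enhanced lung (−700/700), PE-specific (100/700), mediastinal (40/400), each
resized to a square input (518 px for the production composition; smaller
for CPU-scale tests). The default order is window-then-resize (bilinear on
the 8-bit image); a resize-then-window order is available behind a flag.
The marker pathway uses the single enhanced-lung window at 256 px
(test-scale: 64 px).

The scanner mask harmonises non-anatomical regions across scanners: pixels
that never exceed the −1500 HU outside-field-of-view sentinel in a
reference dataset are forced to −1024 HU (air) everywhere. The mask
heuristic (largest connected FOV region) is a stand-in; vendor FOV metadata
would be authoritative where present.

## The slice-level 3D adapter

A bottleneck adapter transforms token features X ∈ R^(L×d) as

    Adapter(X) = X + f(X W_down + b_down) W_up + b_up,

with bottleneck p = d/δ and f = GELU. The slice-level variant ("Slider")
inserts a depth-wise 3D convolution in the bottleneck: the down-projected
tokens of the T slices are reshaped to a T×H×W×p volume (H, W the patch
grid, row-major token order) so a per-channel kernel (k_t, k_h, k_w) can
mix across neighbouring slices and patches:

    Slider(X) = X + f(3DConv(X W_down)) W_up.

The default kernel (3,1,1) mixes along the slice axis only. One adapter is
applied to the patch tokens at the input of every transformer block; the
class token bypasses the adapter unchanged. W_up (and all adapter biases)
start at zero, so at initialisation the model computes exactly the frozen
backbone + head function; the depth-wise kernel starts as the identity tap.
Convolution uses zero padding, stride 1, "same" output size.

### Parameter accounting

Counts use the closed forms (verified against an instantiated model):

* adapter: (d·p + p) + (p·k_t·k_h·k_w + p) + (p·d + d) per block
* backbone block: qkv (3d² + 3d) + attention out (d² + d) +
  MLP (8d² + 5d) + two layer norms (4d) + two layer-scale vectors (2d)
* full backbone additionally: patch embed (14²·3·d + d), positional table
  ((37² + 1)·d), class token (d), final norm (2d)
* head: d·n_classes + n_classes.

With d = 768, 12 blocks, patch 14, input 518 these reproduce the published
counts exactly: slider δ ∈ {1,2,4,6,8,12} → 14.21 / 7.11 / 3.56 / 2.38 /
1.79 / 1.19 M; full 86.58 M; partial (last block) 7.09 M; linear probe
1538 ≈ 0.0015 M. Adapter placement does not affect the counts.

### Case-level model and training

The case representation is a d-vector pooled from the final-norm outputs
over the T slices, followed by a single linear head (d×2 + 2 parameters in
every mode, preserving the printed linear-probe count). Two poolings are
provided: the mean of the per-slice class tokens (`"cls"`, the right choice
when the backbone is a pretrained foundation model whose class token
summarises the image) and the mean over patch tokens (`"patch_mean"`). The
CPU-scale default is `patch_mean`: with a *randomly initialised* frozen
backbone the class token is nearly input-independent and starves the head;
this is a deliberate deviation from the class-token design for the tiny
test backbone only.

Two numerical choices matter for trainability of the tiny configuration and
were adopted after the plain setup demonstrably underfit (loss pinned at
ln 2): the per-block layer-scale vectors are initialised at 1e-5 (the
DINOv2 convention — blocks start near identity), and a frozen per-feature
standardisation (mean/std buffers computed once from the training stacks
before any updates — not tunable parameters) is inserted between pooling
and head. Neither changes the parameter counts nor the identity-at-init
property.

Fine-tuning modes: `slider` (adapters + head trainable), `full`
(everything), `partial` (last block + head), `linear_probe` (head only).
Frozen parameters are never passed to the optimiser and are verified
bitwise-unchanged by a training step.

Training defaults mirror the reference protocol: Adam, initial learning
rate 2e-4 with cosine annealing, 80 epochs, batch 8, dropout 0.3 on the
pooled features, class-weighted cross-entropy with weights 1 : 1.5
(negative : positive), every value overridable. The CPU-scale experiments
below use learning rate 1e-3 (the tiny random backbone needs a larger step
than a pretrained one). The marker CNN uses Adam at 3e-3, batch 64, 10
epochs, weighted cross-entropy. All training is implemented on a small
numpy reverse-mode layer library (`ctslider._nn`) whose backward passes are
finite-difference-checked in the test suite; training is exactly
reproducible from the seed.

## Synthetic phantoms

The phantom generator emulates the geometry the markers are defined on, at
cartoon fidelity (default 75 slices at 4 mm, 256 px; tests use 64 px — the
documented minimum that guarantees the marker geometry renders):

* circular soft-tissue body (+20 HU) in a −2000 HU outside-FOV field, with
  a neck-to-thorax radius gradient and shoulder masses above the apex;
* two aerated-lung ellipses (−850 HU) whose cross-section rises like √ of
  the distance from the apical onset, plateaus, and declines over the last
  eight aerated slices while a diaphragm dome carves them into superior
  crescents; a liver-like dome and a z-localised gastric air bubble (apex
  at the upper-diaphragm level) occupy the basal slices;
* a tracheal lumen splitting into two bronchial lumens at the bifurcation,
  with separation growing caudally;
* positive cases receive an additive band-limited subpleural texture
  (+200 to +400 HU times `fibrosis_severity`, with an apicobasal gradient,
  sparing the two most caudal aerated slices so thin crescents always keep
  sub −500 HU parenchyma).

Every cue is tied to the marker positions, so slice appearance determines
position — that is what makes the recovery experiments well-posed, and it
is also the phantom's central limitation: real CTs carry no such clean
one-to-one mapping, and passing the recovery tests demonstrates that the
pipeline machinery is correct, *not* that the method reaches any particular
accuracy on hospital data. The phantom likewise omits scanner physics,
dose/noise structure, pathology heterogeneity and annotation noise.
Ground-truth markers are re-derivable from voxel content alone (first
aerated slice outside the mediastinal column and above the diaphragm line;
first two-lumen mediastinum; disappearance − 3), and the generator is
tested against that re-derivation across jitter.

Cohorts draw labels Bernoulli(prevalence), fibrosis severity uniform in
[0.7, 1.0] for positives (the "strong contrast" study condition), and
jitter the three landmarks by ±2/±3/±3 slices. All randomness flows from a
single cohort seed.

## Study-scale choices

CPU-scale experiment sizes are fixed as the package's study conditions:
marker recovery trains on 80 phantoms and evaluates 1-Up-Down accuracy on
20 held-out phantoms (10 epochs); identification trains on 90 of 120
phantoms (5-RS stacks at 56 px, tiny ViT: d=32, 2 blocks, 4 heads, patch
14) and evaluates AUROC on the held-out 30. The production-scale settings
(256 px marker inputs, 518 px RGB composites, ViT-B/14) remain the
defaults of the respective components.

## Evaluation statistics

Threshold metrics come from the confusion matrix at score ≥ 0.5 (boundary
inclusive); zero-denominator ratios are NaN, never 0. AUROC is the
pairwise probability that a positive outranks a negative with ties counted
½; AUPRC is step-wise average precision over descending unique thresholds
(no interpolation). Both are computed by scikit-learn, which implements
exactly these estimators, and are cross-checked against brute-force
oracles in the tests.

Paired model comparison:

* **stratified paired bootstrap** — cases resampled with replacement within
  each label stratum, identical indices applied to both models; percentile
  95% CI of Δ = metric_A − metric_B (percentile rather than BCa, the
  simpler choice in the absence of a stated variant);
* **DeLong's test** for correlated AUROCs via placement values; degenerate
  zero-variance comparisons are flagged and report z = 0, p = 1;
* **within-case score-swapping permutation test** for the AUPRC: each
  case's (A, B) pair is swapped independently with probability ½; sampled
  p uses the add-one estimator (1 + #{|Δ*| ≥ |Δ|})/(1 + B); an exact mode
  enumerates all 2^N patterns for small N.

The positive class is PF-ILD (y = 1) and is ranked above negatives — the
standard convention.

## Known limitations

* The neural components run on numpy; they are CPU-sized research models,
  not a GPU training stack, and no pretrained foundation-model weights are
  distributed or loaded.
* The scanner-mask heuristic and the phantom are cartoons (see above).
* The split rounds the validation/test fractions per label stratum to the
  nearest integer (613 cases at 70/15/15 → 429/92/92).
* Clinical performance figures from the source cohorts are not reproducible
  here; only the tunable-parameter counts are recomputed exactly.
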