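# Methods

## Problem and model

`viewseg` addresses joint **segmentation and detection** of brain tumors in
2-D MRI slices.  Two observations drive the design: (i) the three
anatomical orientations — axial, coronal and sagittal — present very
different geometry, so a single generalist segmentation network must
average over heterogeneous appearance; and (ii) pure segmentation does not
answer the clinical question "is a tumor present?", while pure
classification does not delineate it.  The framework therefore combines:

1. a **view classifier** `g` that assigns each slice a view label
   `v ∈ {0 axial, 1 coronal, 2 sagittal}`;
2. three **view-specific segmentation networks** `f_v`, U-Net-style
   encoder–decoders with skip connections producing a single-channel logit
   map at input resolution;
3. a **classification header** `h` per network that converts the predicted
   map into one tumor-present/absent label per image;
4. a **routing pipeline**: `v ← g(I)`, `S ← f_v(I)`, `p ← h(S)`, so each
   image is handled by the model specialised for its predicted view.

## Objectives

The view classifier minimises inverse-frequency **weighted cross-entropy**

    CE = −Σ_i w_i g_i log s_i ,   s = softmax(o),   w_i = N / n_i ,

with class counts `n_i` taken from the training split only.

The segmentation-classification networks minimise a composite loss

    L_total = (1 − λ) L_seg + λ L_cls
    L_seg   = w · L_Dice + (1 − w) · L_Tversky(α, β)
    L_cls   = γ · L_BCE + (1 − γ) · L_IoU

with soft (sigmoid-probability) overlap terms

    L_Dice    = 1 − (2Σ o·g + ε) / (Σo + Σg + ε)
    L_Tversky = 1 − (TP + ε) / (TP + α·FN + β·FP + ε)
    L_IoU     = 1 − (Σ p·t + ε) / (Σp + Σt − Σ p·t + ε)

and the numerically stable BCE-with-logits `log(1+e^{−p}) + p(1−t)`.
Defaults are `w = 0.4, α = 0.7, β = 0.3, γ = 0.7, λ = 0.2` (the package's
tuned operating point) and `ε = 1e−6`.
`α > β` weights false negatives more, which favours recall on small
tumors.  Setting `λ = 0` removes the classification term entirely (the
"no classification head" ablation); `freeze_encoder` reproduces the
"without fine-tuning" ablation.

Numerical conventions chosen where the method description leaves them
open:

* **Smoothing** `ε = 1e−6` in every overlap term, so an all-background
  prediction on an all-background truth scores a perfect 0 loss / 1.0
  score.  This is essential for tumor-free slices with all-black masks.
* **Batch reduction**: overlap terms are computed per image and averaged,
  so empty-vs-empty images contribute 0 instead of diluting foreground
  sums of other images in the batch.
* **Soft losses during training**: the decoder's sigmoid probabilities
  enter the overlap losses; the 0.65 threshold is used only at evaluation
  and inference.
* **Classification-loss operands**: with the default parameter-free
  header, `L_BCE` and `L_IoU` are evaluated on the segmentation maps
  against the ground-truth mask (element count batch × height × width).
  With a learned header they are evaluated on the head's image-level
  logits/probabilities against the tumor labels.  Both readings are
  implemented because the header is genuinely ambiguous (see below).

## Classification header

Two header modes are provided:

* **mask-rule** (default): a parameter-free area rule — label 1 iff at
  least `A_min` pixels of the probability map reach the 0.65 threshold,
  with `A_min` = 0.1 % of the image (minimum one pixel).  This directly
  "analyses the segmented tumor region" and introduces no extra
  parameters; 0.1 % suppresses single-pixel speckle without hiding small
  tumors at 64–512 px scales.
* **learned**: a dense layer over globally pooled bottleneck features
  emitting one logit, thresholded at 0.5.

The λ-sensitivity experiment is run in **learned** mode: only there does
λ trade spatial supervision against image-level supervision, which is
what the sweep is meant to probe.  At λ = 1 the decoder receives no
gradient and held-out Dice collapses while detection recall/precision
stay high — the expected failure signature.  In mask-rule mode both loss
groups are spatial and λ has little effect.

## Networks

All networks are built on a compact NumPy layer stack (`viewseg.nn`):
3×3 same-padding im2col convolutions, ReLU, 2×2 max pooling,
nearest-neighbour 2× upsampling, dense layers, AdamW, with hand-written
backward passes verified against finite differences in the test suite.
Arrays are channels-last float32; initialisation is He-normal from a
seeded generator, so builds and training runs are bit-reproducible.

* **View classifier**: three conv-relu-pool stages (widths 6/12/24 at the
  desk-scale default), global average pooling, dense layer to 3 logits.
* **Segmentation network**: encoder of `depth` (default 3) conv-relu-pool
  stages with widths doubling from `base_channels`, a bottleneck conv,
  and a mirrored decoder that upsamples and concatenates the matching
  encoder activation before each conv; a 1×1 conv emits the logit map.
  Input sizes must be divisible by `2^depth`.
* Encoders are pluggable in principle; the `small` scratch preset is the
  only one shipped (no pre-trained weights are bundled).

## Preprocessing and augmentation

Images are resized to a square target (bilinear; masks nearest-neighbour
so they stay binary) and normalised per channel with mean 0.5 / std 0.5 —
the inputs are synthetic, so natural-image statistics would be
meaningless.  For classifier training, each image receives a random
rotation θ ~ U(−10°, +10°) followed by a random affine transform
(rotation ±5°, translation ±5 %, scale 0.95–1.05, shear ±5°), applied in
a centre-origin x-right/y-up convention with zero fill.  Segmentation
training uses resize + normalise only by default; enabling geometric
augmentation for segmentation warps image and mask with the identical
composed transform.

## Synthetic phantoms

The generator emulates the structure of the clinical datasets without any
patient data.  Each phantom is an elliptical "brain" on black background
with view-specific geometry (axial: wide ellipse with two dark ventricle
lobes; coronal: tall ellipse with a midline groove; sagittal: off-centre
profile with a posterior notch and an anterior–posterior intensity
gradient), smooth radial shading, per-seed shape jitter, and additive
Gaussian noise (σ = 0.03 by default).  Tumors are bright Gaussian blobs
(amplitude 0.45 over tissue) whose half-max radius is drawn uniformly
from 5–15 % of the image side; the ground-truth mask is the region at or
above 50 % of blob peak — a disc of the drawn radius — placed so the disc
lies strictly inside the tissue.  Tumor-free phantoms have all-zero
masks.  Datasets support arbitrary per-view proportions and tumor
prevalence with largest-remainder rounding, and an 80-10-10
train/validation/test split.

What the phantoms do **not** model: MRI physics (bias fields, k-space
artefacts, partial volume), anatomical variability beyond ellipse jitter,
non-blob tumor shapes, multi-focal disease, or 3-D context.  Passing the
phantom-recovery tests therefore demonstrates that the losses, networks,
training loops and routing logic are implemented correctly and can learn
an easy, well-posed instance of the task — not that the trained toy
models would transfer to clinical images.

## Desk-scale study conditions

All tests and the acceptance script run on CPU with a deliberately small
problem: 64×64 phantoms, 300 per orientation, 70 % tumor prevalence,
`base_channels = 6` networks (≈34 k parameters), AdamW, segmentation for
15 epochs at batch 8 / lr 1e−3, the classifier for 12 epochs at batch 16
/ lr 3e−3 with weight decay 0.05.  The package also records a
full-scale schedule intended for clinical-resolution training with
pre-trained encoders (512×512 inputs, classifier 30 epochs / batch 16 /
lr 1e−5 / decay 0.05; segmentation 20 epochs / batch 3 / lr 1e−3) as
`classifier_defaults()` / `segmentation_defaults()`, but those are not
exercised at desk scale.  Under the desk-scale conditions
the per-view models reach held-out Dice ≥ 0.8 and detection F1 ≥ 0.9, and
the view classifier ≥ 0.95 accuracy, across three seeds — these are the
quantities the acceptance suite asserts and `scripts/acceptance.py`
recomputes.

## Evaluation

Probability maps are binarized at 0.65 (boundary inclusive).  IoU is the
standard Jaccard index — an alternative "printed" normalisation that
divides by the plain sum of the masks (half the Dice value) is exposed
behind `iou_score(..., form="printed")` for auditability.  Per-image
IoU/Dice are averaged over the test set (macro aggregation; both-empty
pairs score 1.0 by smoothing).  Detection quality is reported as
image-level precision/recall/F1/accuracy; the pixel-level F1 over the
pooled test set is reported alongside, clearly labelled, since either
convention appears in the literature.

## Known limitations

* The NumPy stack is single-threaded and CPU-bound; it is sized for
  64–128 px experiments, not 512 px clinical training.
* No pre-trained encoders are shipped; the "encoder fine-tuning"
  ablation therefore compares training vs freezing a *randomly
  initialised* encoder.
* The learned header is trained jointly from scratch; no staged
  (segmentation-first) schedule is implemented.
* Tie-breaking in `maxpool` backward distributes gradient equally over
  tied maxima; exact ties are measure-zero for continuous inputs.
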