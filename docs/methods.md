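# Methods

This note records the models, numerical conventions and design choices
behind `voljepa`, and what the synthetic phantoms can and cannot show.

## The objective

Vol-JEPA is a latent-prediction objective for 3D volumes. Each volume is
tokenized into non-overlapping 4×16×16-voxel patches restricted to the
foreground (the head); the token set is partitioned into a small visible
context `x` and a larger masked target `y`. A student transformer `E_θ`
encodes the context; a predictor `P_φ`, queried with a single shared
learnable mask token `Δy` added to each target position's code, predicts
the latent of every target token; a teacher `E_θ̄` — an exponential moving
average of the student that receives no gradients — encodes the full token
set to supply the targets. The loss is the elementwise smooth-L1 distance
(quadratic below β=1, linear above), averaged over elements, between
predictions and stop-gradient teacher latents. Predicting in latent space
(rather than reconstructing voxels) removes the need for voxel-level
augmentations, negative pairs or decoders.

Two masking configurations are mixed equally per batch:

* **multiblock** — blocks with per-axis half-extents uniform in
  [0.15, 0.45] of the grid extent are grown around foreground-token
  centroids until ≥85% of tokens are masked; the complement is the
  context. The half-extent range is a package choice (the stopping rule is
  the primitive): it makes 2–6 blocks typically reach 85%.
* **smallcrop** — a contiguous crop with per-axis span uniform in
  [0.4, 1.0] of the grid extent is sampled; round(ratio · crop tokens)
  tokens inside it (25% MRI, 20% CT) form the context and everything else
  is target. The span distribution is likewise a package choice.

A context-dropout step then moves each context token to the target
independently with probability 0.2 (the emptied-context guard restores the
lowest-index dropped token). Token grids are truncated to ≤20 patches per
axis during training only; position codes are the pre-truncation patch
coordinates, so truncation never re-centres positions. CT samples draw one
of three Hounsfield windows per step with probabilities 0.7/0.15/0.15
(brain/blood/bone); at inference all three windows are embedded and their
token sets concatenated.

## Preprocessing

Volumes are trilinearly resampled to 1×1 mm in-plane and 4 mm along the
acquisition axis (nearest-neighbour for label grids); output shape is
round(extent/spacing) per axis, sampling at voxel centres. MRI intensities
are clipped to the volume-wide 0.5–99.5th percentiles and mapped linearly
to 8 bits; CT volumes are clipped to [level−width/2, level+width/2] per
window — brain (80/40, 8-bit), blood (200/80, 4-bit), bone (2800/600,
4-bit) — and quantized likewise. Rounding is everywhere nearest-integer
with ties away from zero, chosen for cross-platform reproducibility.
Foreground masks remove air only (no skull stripping): Otsu on a 256-bin
histogram for MRI, a fixed −500 HU threshold for CT, both with slice-wise
hole filling; the exact threshold parameters are package choices. For
model input, quantized values are scaled to [0,1], the per-(modality,
window) mean of scaled foreground training voxels is subtracted, and
background voxels are zeroed. Percentiles are computed over all voxels
(not foreground only) and recorded in provenance. 4-bit volumes are stored
as packed nibbles (low nibble first); shard round trips are byte-exact and
CRC-guarded.

## Architecture and optimization

There is no `torch` dependency: a small numpy reverse-mode autodiff engine
(`voljepa.nn`) implements exactly the operator set the models need, and
its gradients are tested against central finite differences. The encoder
is a pre-norm ViT with exact-GELU MLPs and factorized 3D sinusoidal
position codes; the predictor is a narrower transformer
(predictor_dim = embed_dim/2, depth 4 by default). Variable-length
batches are packed into one flat sequence with a block-diagonal additive
attention mask; the packing contract — tokens of different samples never
attend to each other — is enforced by testing the packed path against a
per-sample reference path to 1e-10. Optimization is AdamW with linear
warmup and cosine decay. Default sizes (embed_dim 192, depth 6) are
desk-scale stand-ins, not the production scale of this model family.

The EMA momentum schedule is linear from 0.996 to 1.0 over the run by
default. The 200-step smoke benchmark overrides the start to 0.9: over 200
steps a 0.996-momentum teacher retains ≈45% of its random initialization,
so its features would be dominated by the init rather than by what the
student has learned; at 0.9 the teacher tracks the student while still
smoothing it. Checkpoints serialize parameters, optimizer moments and RNG
state, and resumed runs reproduce the uninterrupted loss trajectory
bit-for-bit.

## Evaluation heads

The **attentive probe** pools all tokens of a study with one
cross-attention block (a single learnable query per head, 4 heads) and
applies a linear multi-label head, trained with class-weighted BCE
(weight_k = N_neg/N_pos); inputs are z-scored per dimension over the
training tokens. Decision thresholds maximize Youden's J on a validation
split. One pooled vector is shared across classes. The architecture is a
package choice; the protocol (frozen encoder, all tokens, class-weighted
BCE, validation thresholds) is the primitive.

The **AB-MIL grounding head** reverses the usual aggregate-then-classify
order: an instance MLP ψp produces K logits per instance, an attention MLP
ψm produces K scores normalized by softmax across instances, and bag
logits are the attention-weighted sums of instance logits. Both MLPs are
2-layer with hidden width equal to the feature dimension. Attention maps
broadcast α uniformly over each token's voxels (no smoothing by default);
the pointing game scores a hit iff the attention-argmax voxel (ties to the
lowest linear index) lies in the lesion mask. The laterality check flips
the left-right axis and summarizes ΔR − ΔL as an AUROC against the true
side.

## Statistics

AUROC uses midranks (ties count ½) and is cross-checked against an O(n²)
pairwise oracle. Platt scaling is a ridge-penalized (λ=1e-6) logistic fit
of labels on logits; F1 is computed at probability 0.5 after calibration.
Scaling fits regress F1 on log₁₀(n_pos) per encoder via OLS with HC3
standard errors, excluding classes with <30 training or <10 test
positives. ANCOVA tests the encoder×log₁₀(n_pos) interaction at α=0.05 and
pools a shared slope when non-significant. The label-equivalence fold is
10^(Δintercept/slope) with a class-level bootstrap percentile CI
(paired resampling when the encoders share a class set, which makes
self-equivalence exactly 1 in every replicate). Subgroup ΔAUC uses paired
study-level bootstrap percentile CIs (10,000 replicates by default;
eligibility ≥10 positives and negatives) and reports the separation index
S = |Δg| / CI-half-width, with S > 1 iff the CI excludes 0, against a
±0.05 equivalence band. Co-occurrence is min-normalized:
M_ij = |i∩j| / min(|i|, |j|), zero and flagged for empty labels.

## The phantom generator

Phantoms are nested ellipsoids (scalp ⊃ skull ⊃ brain ⊃ two ventricles)
with optional ellipsoidal lesions inside the brain, rendered per modality:
CT in Hounsfield units (air −1000, brain ≈35, blood ≈65, bone ≈1000) with
Gaussian noise (σ=2 HU); MRI on an arbitrary T1-like scale (CSF and bone
dark, scalp bright) with a low-order multiplicative bias field (amplitude
0.15) emulating coil non-uniformity, which the percentile clipping must
tolerate. Lesion kinds map to a 6-label toy ontology through a declarative
table (with triage classes and optional laterality constraints); cohorts
draw labels as independent Bernoullis, so long tails and co-occurrence
arise from unequal prevalences. Rarity-weighted resampling weights each
study by the inverse prevalence of its rarest label. Paired CT/MRI studies
share one geometry and label vector, giving ground truth for cross-modal
transfer. All randomness flows through one seeded generator per call.

What the phantoms do *not* emulate: realistic tissue texture, pathology-
specific appearance, partial-volume effects, scanner artifacts, or the
anatomical variability of real cohorts. Tests passing on phantoms show the
algorithms are implemented correctly and behave as specified under known
geometry — not that the learned representations transfer to clinical data.

One phantom-specific interaction worth knowing: because MRI quantization
clips at per-volume percentiles, a lesion brighter than every other tissue
shifts the whole volume's intensity scale and thereby leaks its presence
into every token. The grounding benchmark therefore uses a lesion below
the scalp's intensity ceiling, so only lesion-overlapping tokens carry
signal and attention must genuinely localize.

## Problem sizes and the smoke benchmark

The canonical smoke benchmark (`voljepa.benchmarks.lesion_probe_benchmark`)
pretrains a tiny encoder (embed 64, depth 3, heads 4; predictor 32×2;
batch 16, lr 3e-3) for 200 steps on 64 MRI phantoms of 16×64×64 voxels
(~56 foreground tokens each), then fits the attentive probe (400 steps,
lr 2e-3) on 60 training / 60 test studies of an easy two-class lesion task
(tumor-like lesion, radius 5–7 voxels in-plane, +120 intensity offset).
At seed 0 this halves the smoothed loss (0.36 → 0.003), keeps the
per-dimension teacher-embedding variance above 1e-4 (no collapse), and
reaches test AUROC 0.96 vs 0.83 for the same probe on a random-init
encoder. These problem sizes were chosen so the whole suite runs in
minutes on one CPU; the task design (lesion size/contrast and probe
budget) was fixed after verifying the trained-vs-random margin is stable
across pretraining seeds 0–2.

## Known limitations

* The autodiff engine is single-threaded numpy; it is a correctness
  reference, not a performance path.
* Encoder/probe hyperparameters were tuned only to desk scale; nothing
  here speaks to behaviour at production scale (batch hundreds, ~10⁵–10⁶
  steps).
* The phantom ontology is a 6-label stand-in for a clinical one two
  orders of magnitude larger; statistics involving "classes" exercise the
  machinery, not clinical difficulty.
* `cluster_parenchyma` fits k-means on the first sliding window, so the
  first window must contain representative tissue; on phantoms it always
  does.
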