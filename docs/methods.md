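# Methods

## Model and procedure

The package implements metric-based few-shot classification for 3D
volumes. An encoder E maps a preprocessed volume to a D-dimensional
embedding. For a 2-way k-shot episode, the per-class prototype is the
unweighted arithmetic mean of the k support embeddings (computed on raw,
unnormalised embeddings; an optional flag L2-normalises each embedding
before averaging). A query q is classified by arg min over classes of the
Euclidean distance ‖E(q) − p_c‖₂, ties broken toward class 0 — the
conservative "intact" call in a clinical reading. The continuous score used
for ROC analysis is the distance margin d₀ − d₁ (positive ⇔ closer to the
positive prototype). A softmax over negative distances is offered as an
alternative score; for two classes it is a strictly monotone function of
the margin, so every rank-based quantity (in particular AUC) is identical.

### GE2E loss

Training batches are arranged as N labels × M samples (default N = 2,
M = 4, i.e. 8 volumes per step). With centroids C_k = (1/M) Σ_j f_kj,
similarities S_ji,k = w·cos(f_ij, C_k) + b, the loss is

    L = Σ_ij [ −S_ji,i + log Σ_k exp(S_ji,k) ].

Defaults implement this formula literally: fixed w = 1, b = 0, no
self-exclusion, sum reduction. The refinements of the original
speaker-verification formulation — learnable scale/bias and excluding f_ij
from its own centroid in the S_ji,i term — exist as `GE2EConfig` options,
off by default, because the plain cosine form is the primary definition
here; the options enable ablations. The reduction (sum vs mean over the
N·M terms) only rescales the gradient and is exposed because the batch-level
aggregation is a genuine free choice; sum is the default.

The gradient of L with respect to the embeddings is derived analytically,
including the dependence of each centroid on its members (and the
per-query excluded centroid when self-exclusion is on). The log-sum-exp
uses a max shift. Degenerate inputs fail loudly: zero-norm embeddings or
centroids raise an error rather than producing NaN cosines.

### Encoders

`tiny3d` (default): stages of 3×3×3 convolution with stride 2 and ReLU
(channels 8, 16, 32), a 1×1×1 projection to `embedding_dim` (default 32)
channels, and global adaptive average pooling — so the network ends in a
pooling layer emitting the embedding directly and has no classification
layer. ~19k parameters; sized so GE2E training converges in minutes on one
CPU core. `resnet_style` inserts identity-skip blocks after each stage for
scale-up. Supervised pre-training attaches a temporary linear head
(embedding → 2 logits) trained with softmax cross-entropy; detaching the
head leaves the trained trunk.

The engine is a ~300-line numpy layer stack with explicit forward/backward
methods and Adam. Convolution uses strided patch extraction and `einsum`;
its backward pass scatters patch gradients with one strided add per kernel
offset. Every layer's gradient, the cross-entropy head and the full GE2E
gradient are pinned by central-difference tests (observed agreement ~1e-9).
Inference mode caches nothing and is a pure function; train/inference is an
explicit argument, never ambient state.

## Data handling

Axis convention (depth, height, width), depth = slice axis, matching
MRNet-style per-exam arrays. Manifests are CSV with columns `exam_id,
patient_id, label, path`; labels strictly {0, 1}; duplicate exam ids and
out-of-range labels are hard errors naming the row. Volumes load from
NIfTI-1 or single 3D `.npy` files; 2D arrays are promoted to depth 1, >3D
rejected. Preprocessing maps any volume to a fixed target shape (default
16×32×32) by symmetric center crop/pad (default) or per-axis linear
resampling, then per-volume z-scoring (constant volumes map to zeros rather
than dividing by zero). Crop/pad was preferred as the default because it is
exactly invertible on the retained region and introduces no interpolation
smoothing; both policies are deterministic.

## Episodes and metrics

Episodes draw exactly k support samples per class with a seeded generator;
queries default to all remaining samples, excluding every exam of any
patient represented in the support set (patient-level disjointness, on by
default, prevents a patient's own anatomy from serving as its reference).
A fixed query count is available for matched-power comparisons across k.
`evaluate_many` gives episode e the seed `base_seed + e` and reports
per-episode metrics plus mean and SD across episodes; it embeds the pool
once, which is exact because inference is deterministic and per-sample.

ROC-AUC is computed exactly as the Mann–Whitney probability via midranks
(ties credit 0.5), not by trapezoidal interpolation — at episodic sample
sizes exactness matters and the rank form is directly testable against a
brute-force pair count. Sensitivity or specificity with an empty
denominator is reported as null, never silently 0.

## Synthetic data

The generator emulates the *structure* of a two-class volumetric MRI task:
per-patient grouping (all exams of a patient share a class), Gaussian
background noise, and for positives a localized intensity elevation of
`lesion_contrast` noise-SD units inside a ground-truth mask. Two geometries
— a focal anisotropic ellipsoid ("task A") and a through-plane slab
("task B") — stand in for two related but distinct injury types, making
pre-train-on-B / few-shot-on-A transfer testable offline. Lesion centres
jitter by ≤10% of each dimension so the task is not a fixed-voxel lookup
yet remains learnable by a tiny encoder. Defaults: 16×32×32 voxels,
contrast 3, in-plane radius 5 voxels, balanced classes.

What the phantom does **not** model: anatomy, multi-plane series, scanner
intensity non-uniformity, inter-patient anatomical variability, class
overlap from ambiguous pathology (e.g. partial tears), or label noise.
Passing tests therefore demonstrate that the machinery — loss, gradients,
episode protocol, metrics, transfer plumbing — behaves correctly and that
the qualitative phenomena (AUC growing with k, domain-matched pre-training
beating random initialisation, GE2E matching or beating cross-entropy
embeddings) emerge when signal is genuinely present; they do not certify
performance on clinical images.

## Problem sizes and defaults

The shipped study conditions were chosen once as a desk-scale experiment a
practitioner could run while reading the docs: task A 240 patients (one
exam each, 50/50 patient-level split), task B 120 patients, GE2E schedule
N = 2, M = 4 (batch 8), 300–400 Adam steps at learning rate 1e-3, k swept
over {2, 20, 40} with 20 evaluation episodes (10 per transfer arm). Under
these conditions the k-sweep reaches mean AUC ≥ 0.9 and cross-entropy
pre-training on task B beats random initialisation on task A by ~0.1–0.2
AUC.

## Design choices where the design was open

- **Score definition.** Only a hard nearest-prototype rule is implied by
  the classification definition; ROC analysis needs a continuous score.
  The distance margin is the minimal assumption and is what `score`
  reports.
- **Embedding normalisation.** Embeddings are not L2-normalised at the
  encoder: the cosine inside GE2E is scale-free anyway, and prototype
  distances on raw embeddings keep magnitude information. Normalisation
  before prototype averaging is a flag.
- **One series per exam.** Multi-plane fusion is out of scope; a run
  consumes one series per exam.
- **Seeding.** Every source of randomness flows from an explicit
  `numpy.random.Generator`; no global RNG state anywhere. Evaluation is
  bit-reproducible given seeds; training is reproducible to ~1e-3 in
  reported metrics on one platform (floating-point reduction order).

## Known limitations

- The engine is CPU-bound and single-threaded by design; the `resnet_style`
  variant is provided but large backbones are outside its performance
  envelope.
- 2-way episodes only; N-way > 2 would need a generalised score definition.
- The synthetic phantom's separability saturates quickly with contrast:
  oracle AUC is near 1 already at contrast ≈ 1 on default volumes, so
  contrast sweeps probe the low range (0–1) for graded difficulty.
- `preprocess` is idempotent to ~1e-6 (re-z-scoring an already-normalised
  volume perturbs at machine precision), so repeated preprocessing is safe
  but not bit-stable; embedding of identical input is bit-stable.
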