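# Methods

This note documents the model, the default parameters and why they are
set as they are, what the synthetic phantoms do and do not emulate, and
the numerical choices a maintainer would want to know.

## Model and assumptions

The classifier rests on three assumptions about breast-ultrasound
texture:

1. **Local structure carries class information.** Benign and malignant
   lesions differ in small-scale speckle statistics (internal echo
   pattern, posterior behavior), so m x m patches are informative even
   in isolation.
2. **A small vocabulary suffices.** Common local structures recur across
   lesions; k + r prototype patches ("local references"), learned by
   within-class clustering, can anchor a description of any lesion.
   Because references are class-tagged, similarity *to* them carries
   class evidence.
3. **Patch votes aggregate simply.** If each patch can be judged
   benign-looking or not, a majority vote over the per-patch bits
   classifies the image; no second-stage classifier is needed, which is
   exactly what makes the method viable on small datasets.

The pipeline is: cluster references per class (Lloyd on raw flattened
intensities), train a tied-parameter siamese CNN to score
patch-reference relatedness with class-agreement pair labels, binarize
each patch's mean similarity to the *benign* references at 0.5, and
threshold the bit fraction l at 0.5 (strictly) for the image decision.

The benign-block reading of the per-patch statistic deserves a note: the
bit is defined as "this patch looks benign", which is only computable
from class-tagged similarities, so p averages the similarities to the k
benign references and ignores the malignant block. The alternative —
averaging a class-signed similarity over all references — is isolated
behind `semantic.semantic_bit` if a different reading is ever wanted.

Two boundary conventions are deliberately asymmetric: a patch with
p exactly 0.5 votes benign (>= threshold), while an image with l exactly
0.5 is called malignant (strict >). The image-level tie going to
malignant is the conservative direction for a cancer screen.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| m | 16 px | patch side; large enough for three 2x2 poolings (16->8->4->2), small enough to be "local" at 128 px image scale |
| stride | m/2 | 50% overlap multiplies the patch count on small datasets |
| roi_min_frac | 0.5 | a patch belongs to the lesion when at least half its pixels are inside the delineated boundary |
| k, r | 10, 10 | references per class at the desk-scale study size; a config key (larger vocabularies suit larger datasets) |
| learning rate / momentum / weight decay | 0.001 / 0.9 / 1e-6 | the SGD setting the method is specified with |
| batch size / epochs | 64 / 30 | conventional minibatch size; 30 epochs is past loss plateau on the synthetic study |
| pairs_per_epoch | 2048 | ~5 presentations per training patch over 30 epochs on the default study; balanced 50/50 related/unrelated |
| hidden widths | 64, 64 | similarity-head capacity; config-overridable |
| train fraction | 0.8 | stratified 80/20 split |

Every stochastic stage (synthesis, split, clustering init, encoder init,
pair sampling) takes an explicit seed; two runs with the same config are
byte-identical, including the serialized report.

## The neural network

The backbone (three 3x3/32-filter conv blocks with batch norm, ReLU and
2x2 max pooling, global average pooling to a 32-vector) and the
two-hidden-layer similarity head are implemented directly in NumPy with
hand-written backpropagation (`lrscnet.nn`), checked against central
finite differences in the test suite. Choices:

* **Same padding**, so the spatial halving schedule is exact for m=16.
* **Two-unit softmax output**: a softmax on a single scalar is
  degenerate, so relatedness is a 2-way output and s is the "related"
  unit's probability; a zero-initialized final layer yields s = 0.5.
* **Tied parameters are structural**: there is one parameter set, so
  patch and reference embeddings are the same function by construction,
  and s(x, l) = s(l, x) follows from |a - b| symmetry exactly.
* **Batch norm**: batch statistics in training (running stats updated
  with momentum 0.1), running statistics at inference — all encoding is
  deterministic. Reference inputs use the same statistics as patches.
* **Weight decay** applies to conv/FC weight matrices only, not biases
  or batch-norm affine parameters (standard practice).
* **float32** parameters and activations in the hot path (the loop is
  memory-bound; this halves epoch time); every layer follows its input
  dtype, so gradient checks run the identical code in float64.
* Conv biases are retained although train-mode batch norm cancels them;
  their gradient is exactly zero through the batch-mean subtraction.

References are frozen during encoder training: clustering precedes
similarity learning in the pipeline, and no joint refinement is done.

## Clustering details

* Distances are squared Euclidean on raw flattened intensities — no
  whitening or per-patch standardization, because references are plain
  means of patches and must remain valid [0, 1] images.
* Assignment ties break to the lowest reference index.
* Convergence is declared when the assignment is unchanged between
  consecutive iterations (centroid floating-point equality is fragile);
  max_iter 300 caps pathological cycles.
* An emptied cluster is re-seeded with the in-class patch farthest from
  its nearest current reference. The repair cannot raise the objective:
  it only replaces a centroid that contributes no terms, after which
  reassignment can only decrease the sum. The per-iteration objective
  trace is recorded and asserted non-increasing in the tests.
* Initialization samples k (r) distinct patches per class without
  replacement, with an independent seeded stream per class, so each
  class's references are a function of that class's patches only
  (swapping the two pools swaps the two reference sets exactly).

## Synthetic phantoms

`lrscnet.synth` emulates exactly the statistics the method feeds on:

* **Fully developed speckle**: squared magnitude of a complex Gaussian
  field smoothed at the class's correlation length, log-compressed as a
  B-mode display would. Benign 5.0 px, malignant 1.5 px — the smooth
  vs coarse texture contrast, placed in *texture statistics rather than
  brightness* so a mean-intensity threshold cannot succeed (a
  `mean_shift` flag adds a brightness cue for fast smoke tests only).
* **Lesion geometry**: a central hypoechoic region (interior scaled by
  0.5) bounded by a Fourier radius-perturbed closed curve; perturbation
  amplitude 0.1 (benign) vs 0.4 (malignant) mimics margin irregularity.
  The mask doubles as the ROI.
* Default study size: 128 px images, 100 per class, stratified 80/20.

Not emulated: attenuation and shadowing, depth-dependent resolution,
device-specific post-processing, operator variability, and the full
heterogeneity of real lesion interiors. Passing tests on phantoms
therefore demonstrate that the pipeline extracts and uses second-order
texture differences end to end — not that clinical-grade accuracy is
achieved on real BUS data.

Phantom generation is exactly reproducible given (seed, class, index);
cross-platform byte equality additionally depends on the platform's
libm rounding of transcendental functions.

## Problem sizes and determinism in the tests

The test suite exercises the full learning loop at the default study
size (100 images per class) over three seeds, and all unit/property
tests on smaller instances (6-15 images per class at 64 px, 1x1-pixel
patches for clustering arithmetic). The clustering oracle enumerates all
partitions exhaustively, which bounds those instances to <= 10 patches
and k, r <= 3. Hypothesis-based property tests are seeded/derandomized.

## Known limitations

* The continuous ROC score (mean pre-threshold p) is a package choice;
  the hard decision path uses only the bits.
* Undefined metrics on degenerate splits (e.g. PPV with no benign
  predictions) are reported as null, so downstream consumers must
  handle missing values.
* k and r are not selected automatically; the vocabulary size is a
  tuning parameter with a dataset-dependent optimum.
* The NumPy training loop is single-threaded BLAS-bound; it is sized
  for desk-scale studies (minutes), not for large clinical corpora.
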