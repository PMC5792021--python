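# Methods

## Problem setting

Taxonomic specimen repositories photograph each mounted individual in three
standard views — a frontal **head** shot, a top-down **dorsum** shot and a
lateral **profile** shot — and label it with its genus, one of `L` classes.
Two classification tasks arise:

* **Type 1** (per picture): given any single picture, predict the genus;
* **Type 2** (per specimen): given one picture of each view, predict the genus.

`antsemble` implements a multi-view late-fusion approach to Type 2 built from
Type 1 convolutional classifiers trained under three regimes, plus the
evaluation and diversity machinery needed to analyse the resulting ensembles.

## Data model and splitting

A dataset is a list of specimens, each holding `N_h`, `N_d`, `N_p` grayscale
pictures per view (any of which may be 0 or > 1).  Genus labels are contiguous
integers `1..L`.  Cardinality summaries report, for the six standard
constraints (at least one picture; exactly one per view; at least one in every
view; at least one head / profile / dorsum), the specimen count and its rate
over the total.

The split is 70/20/10 over specimens by default, stratified by genus with
largest-remainder apportionment of the per-genus quotas (deterministic;
remainder ties go to the earlier fraction, ordered train, validation, test).
Validation and test are drawn only from specimens with **exactly one picture
per view** — the Type 2 contract — while every remaining specimen, including
all extra pictures, stays in train.  A genus without enough one-per-view
specimens gets a reduced (possibly zero) validation/test quota and a warning.
Fractions are interpreted over specimens, not pictures, consistent with the
one-per-view restriction being a property of specimens.

## Architecture descriptors and the shape calculus

Architectures are declarative layer lists.  The spatial side after a
convolution or pooling layer is

    H_out = floor((H_in − k + 2P) / S) + 1,    W_out = H_out,

where `k` is the receptive-field side, `P` the zero-padding and `S` the
stride.  The reference network is AlexNet-style for 256×256 grayscale input:
an 11×11/4 convolution (96 channels), three 3×3/2 max-pool stages, two local
response normalizations, dimension-preserving convolutions of 256, 384, 384
and 256 channels, two 4096-wide fully connected layers with dropout 0.5, and
a softmax output over `L` labels.  Its shape chain is
63 → 31 → 31 → 15 → 15 → 15 → 15 → 7 spatially, then 4096, 4096, `L`.

Three details of the reference network are not fully determined by its public
description and are recorded as assumptions in the descriptor metadata:

* the first convolution's padding is 2 — the only value that yields 63 from
  256 under floor division;
* the dimension-preserving convolutions use the AlexNet kernel sizes
  5, 3, 3, 3 with stride 1 and padding `(k−1)/2`;
* pooling is max pooling and normalization is across-channel local response
  normalization with `n=5, α=1e-4, β=0.75, k=1`.

Integer division is floor for convolution and pooling alike; the printed
pooling chain divides exactly, and floor is the only rule consistent with
256 → 63.  `scaled_architecture(input_size, n_labels, width_factor)` keeps
the layer pattern and scales all channel and fully-connected widths by
`width_factor` (ceiling, floor of 8); the chain requires roughly 64×64 input
or larger — smaller inputs collapse at the third pooling stage and raise.

## The numpy network engine

No GPU or deep-learning framework is required: `antsemble.nn` is a compact
float32 CPU engine implementing exactly the layer set the descriptors
declare — im2col convolution, overlapping max pooling, local response
normalization, fully connected layers, ReLU, inverted dropout and a fused
softmax/cross-entropy.  Every layer's backward pass is verified against
central-difference numerical gradients in the test suite (tolerance 5e-3 at
float32 precision), and the convolution/pooling forward passes against
nested-loop oracles.  All randomness (He-initialised weights, batch
shuffling, dropout masks) derives from a single seed via spawned
`SeedSequence`s, so a run is bit-reproducible on a fixed numerical backend.

## Training regimes

* **General**: trained on the pooled per-picture stream of all views.
* **Specific**: trained from scratch on one view's pictures only.
* **Transfer**: weights initialised exactly to the trained general model's,
  then fine-tuned on one view.  At zero iterations the child equals the
  parent bit-for-bit.

The optimizer is SGD with momentum 0.9, weight decay 1e-4 and step
learning-rate decay (×0.5 every 250 iterations).  "Iterations" are mini-batch
steps (batch 16 by default).  Validation top-1 accuracy is evaluated every
`validation_interval` steps and at the final step; the returned model is the
checkpoint with the best recorded validation accuracy, ties resolved to the
earliest iteration.  When no validation data exists the final weights are
kept.  Defaults: learning rate 0.01 for from-scratch training; fine-tuning in
the examples and tests uses 0.004, the usual practice of reducing the step
size when continuing from a good solution.  Rates above ~0.02 were observed
to diverge on the desk-scale problem, which motivated the conservative
default.  Dropout is active only in training (inverted convention — inference
needs no rescaling).

Inputs are padded to square, bilinearly resized to the architecture's input
side, and centred by subtracting 0.5.  Penultimate features are the post-ReLU
activations of the second-to-last fully connected layer (4096-wide in the
reference network), the standard off-the-shelf descriptor choice.

## Ensembles

An ensemble member is a (regime, view) pair; a specimen with exactly one
picture per view is scored by every member on its designated view and the
softmax vectors are **summed** element-wise (no renormalization — ranking is
scale-invariant, and the summed mass equals the member count, a useful
invariant).  Kinds: `G` (the single general model applied to all three
views), `S` (three specific models), `T` (three transfer models), `All` (all
nine members).  A specimen with zero or multiple pictures in a view is
refused rather than silently resolved.  No member filtering is applied before
aggregation: every trained member enters the sum (the identity selection),
noted in report metadata by construction.

## Metrics and diversity

The top-t list is the `t` highest-scoring labels, ties broken toward the
lower label index — which makes every top-t list a prefix of the top-(t+1)
list and all correctness-derived quantities non-decreasing in `t`.  A
prediction is correct when the truth is anywhere in the list.

Per-label precision for list predictions counts label `g` as predicted for a
sample whenever `g` appears in the sample's list; precision is hits over
predictions with 0/0 defined as 0, so a never-predicted label scores zero
rather than dropping out of the average.  This definition reduces to standard
precision at `t=1` and needs nothing beyond the lists.  Reports carry
accuracy, the unweighted (macro) mean of per-label precisions over the labels
present in the truth set, and their minimum — the worst-genus guarantee.

Pairwise diversity over correctness vectors: both-correct `bc`, both-fault
`df`, some-correct `sc`, only-one-correct `oc`, with `sc = bc + oc` and
`bc + oc + df = 1` holding exactly.  Ensemble-level diversity is the
unweighted mean over all `C(m,2)` member pairs.

## Synthetic data generator

The generator emulates the statistical structure the method exploits, not the
appearance of real specimens.  Each genus is an *archetype*: 5 shared
parameters (body-ellipse axes, orientation, intensity, vertical offset) plus
4 parameters per view (head: eye-spot separation/height/radius/intensity;
dorsum: transverse stripe frequency/phase/sharpness/intensity; profile: the
same family as vertical banding).  A picture is an analytic render of the
body plus the view's pattern at a jittered pose (rotation ±0.05 rad,
translation ±0.03 in unit coordinates), with optional additive Gaussian noise
clipped to [0,1].  Archetypes are rejection-sampled to keep pairwise
parameter distance ≥ 0.9 in the 17-dimensional unit cube.

Controls relevant to testing:

* `view_informativeness[v]` scales view `v`'s parameters before rendering, so
  at 0 every genus renders the same pattern in that view;
* `complementary=True` builds three genus groups that share body and
  non-assigned-view parameters and differ only in one assigned view each —
  a single-view classifier can fully separate only its own group;
* `noise_sd=0` guarantees that nearest-template matching recovers the genus
  of every picture (verified as an invariant);
* `extra_picture_prob` (default 0.12) gives a view a second picture, making
  the expected pictures-per-specimen 3·(1+p) ≈ 3.35, matching the average of
  large public specimen repositories.  The default informativeness ordering
  (head 1.0 > profile 0.8 > dorsum 0.6) mirrors the per-view difficulty
  ordering reported for real photographs.

Per-picture seeds come from `SeedSequence((seed, genus, specimen, view,
picture))`, so generation is order-independent and byte-reproducible (PNG
output quantizes to 8 bits).

What the generator does **not** model: mounting hardware, lighting, pose
variation beyond small rigid jitter, intra-genus morphological variation
(all specimens of a genus share one archetype), or class imbalance.  Passing
pipeline tests on this substrate demonstrates the machinery — regimes,
fusion, metrics — behaves as designed, not that any particular accuracy
would transfer to real photographs.

## Desk-scale study conditions

The pipeline-level properties are exercised at: 5 genera × 60 specimens,
64×64 images, width factor 1/8 (channels 12/32/48/48/32, fully connected
512), 400 iterations for the general model and 250 for specific/transfer,
five seeds for the stochastic comparisons.  These sizes keep a full sweep of
35 models in a few minutes of CPU time while leaving the qualitative
structure intact: the general model clears 3× chance comfortably, transfer
matches or beats from-scratch specific training per view (median over
seeds), and on complementary views the nine-member ensemble dominates every
single specific member.

## Known limitations

* Determinism is contract-level: same seed, same BLAS backend → same result;
  across backends bit-equality is not guaranteed.
* The engine is CPU-only and unoptimised beyond im2col; it is not intended
  for full-scale (256×256, tens of thousands of iterations) training.
* Per-label precision for `t ≥ L` degenerates to label prevalence (every
  label is in every list); reports are meaningful for `t` well below `L`.
* The empty-validation edge case keeps final weights, so checkpoint selection
  silently becomes "last" — intentional but worth knowing.
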