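# Methods

## Problem and model

A teledermatological consultation starts from a patient-taken photograph;
a substantial fraction of such photographs are undiagnosable. `dermaqx`
frames quality triage as multi-task classification: a four-way quality
verdict (`lesion`, `no_skin`, `healthy_skin`, `poor_quality`) plus five
binary poor-quality explanations (`bad_framing`, `bad_light`, `blurry`,
`low_resolution`, `too_far_away`).

The network is a convolutional feature extractor followed by two *linear
blocks* (linear layer → batch normalisation → dropout; width 64, dropout
0.2 by default). Block A feeds a 5-unit sigmoid explanation head; block B's
output is concatenated with the five **post-sigmoid explanation
probabilities** and feeds the 4-way softmax quality head. Concatenating
probabilities (rather than logits or hard bits) keeps the model
differentiable end to end while conditioning the verdict on the predicted
defects; the quality head's input width is therefore
`linear_block_width + 5`.

The objective is `L = λ_D·L_D + λ_C·L_C` with `λ_D = 1.0`, `λ_C = 5.0`:

* `L_D` — categorical cross-entropy on the quality label, each sample's
  term multiplied by the weight of its *true* class and averaged over the
  batch. Weights are `w_c = min(n_max/n_c, clip)` with `clip = 10.0`,
  computed from the training split only; the modal class always has weight
  exactly 1.
* `L_C` — binary cross-entropy averaged over the five explanation bits and
  the batch, unweighted. All samples contribute; images whose reference
  class is not `poor_quality` use all-zero targets. Averaging (not summing)
  over the five bits keeps `λ_C` comparable if the explanation taxonomy
  ever changes.

Design choices where the design was genuinely open: class weights apply to
`L_D` only (they are derived from the four quality classes and address
quality-label imbalance, not explanation imbalance); the BCE term is not
frequency-weighted per explanation; explanation bits produced by the union
rule are retained on images fused to a non-poor class, and the all-zero
target rule above decides how training uses them.

### Backbone

The bundled `tiny_cnn` backbone has four stride-2 3×3 convolution stages
(16/32/64/64 channels, batch-norm, ReLU) and **flattens** the final feature
map instead of global average pooling. Flattening preserves spatial layout,
which matters here: `bad_framing` is defined by *where* the lesion sits, a
signal global pooling would erase. At the default 64×64 input the flattened
feature is 64·4·4 = 1024-dimensional. An `efficientnet_b0` configuration is
named in `ModelConfig` for API compatibility but `build_model` rejects it:
it requires ImageNet-pretrained weights and a GPU-class framework, neither
of which this self-contained NumPy implementation assumes. Network, AdamW
and the cosine-warm-restart schedule are implemented in `dermaqx.nn` as a
small explicit-backprop engine; the same backward pass serves training and
Grad-CAM (gradient seeds on the pre-activation scores, with activation
gradients captured at every convolutional stage).

Inputs are resized to the configured square size and normalised to
[-1, 1] per channel ((x/255 − 0.5)/0.5).

## Training protocol

AdamW (decoupled weight decay) with cosine annealing and warm restarts.
Defaults in `TrainConfig`: 39 epochs, lr 1e-4, weight decay 1e-2, batch 32,
initial restart period 10 epochs with period doubling, floor 1e-6, no early
stopping (final-epoch checkpoint), no augmentation (a hook exists, off by
default). The lr default suits fine-tuning a pretrained backbone; the
from-scratch experiments below use 1e-3, which is the conventional AdamW
rate for a small randomly initialised CNN. Every source of randomness —
initialisation, shuffling, dropout — derives from the run seed, so a run
is bit-reproducible; multi-run aggregation uses per-run seeds
`seed + run_index` and reports mean ± population-std per table cell.
Batches with fewer than two samples are skipped (batch statistics are
undefined there).

## Annotation fusion

Raw verdicts are an ICD-10 code (syntactic pattern: letter, two digits,
optional dotted extension) or one of `poor_quality` / `healthy_skin` /
`no_skin`. Every ICD-10 code collapses to `lesion`; unrecognised tokens are
parse errors naming the record. Per image:

* **Quality:** plurality vote over collapsed verdicts. Tie-break is a fixed
  priority `poor_quality > no_skin > healthy_skin > lesion` — when a panel
  is split, prefer the verdict that withholds the image from diagnosis.
  Panels of any size ≥ 1 are accepted and `n_raters` is recorded.
* **Explanations:** union rule — a bit is set iff at least one rater
  discarded the image as poor quality with that tag; independent of the
  fused class.

Duplicate (rater, image) pairs are rejected. Inter-rater agreement is the
pairwise F1: for each unordered pair of raters, per-class F1 on the images
both rated (F1 is symmetric under swapping reference and prediction, since
that swaps FP and FN), then mean ± std over pairs. Pairs sharing fewer than
`min_overlap` images (default 10) are excluded and reported: with panels of
"up to 12" raters, co-rating can be sparse and tiny intersections give
degenerate F1 values. Degenerate 0/0 metric ratios return 0.0 and are
flagged in the report rather than propagating NaN. Count-distribution
tables report column totals and the arithmetic mean over the listed classes
(sum divided by the number of rows).

## Synthetic data generator

The generator emulates the *structure* of teledermatology photographs, not
their appearance: a skin-tone base (six tones, light to dark) with
low-frequency mottling and fine grain; lesion scenes add a soft-edged
pigmented ellipse darker than the surrounding skin, with the exact ellipse
mask as ground truth; `no_skin` scenes render a cool-toned striped texture.
Scenes are deterministic given (spec, seed), and a JSONL manifest of scene
plus resolved degradation specs regenerates a dataset bit-exactly.

Five degradation operators map severity ∈ [0, 1] to a physical parameter,
with severity 0 the exact identity and the parameter non-decreasing in
severity:

| operator | physical parameter | mapping |
|---|---|---|
| `blurry` | Gaussian σ (px) | σ = 4·severity |
| `bad_light` | gain g | g = 2^(±2·severity), direction drawn once |
| `low_resolution` | downsample factor | 1 + round(7·severity), nearest upsample |
| `bad_framing` | centroid offset | lesion centroid moved to (0.25 + 0.2·severity)·min(H,W) past centre |
| `too_far_away` | zoom-out scale | 1 + 3·severity, border-colour canvas |

Geometric operators (`bad_framing`, `too_far_away`) transform the lesion
mask consistently and are ordered before photometric ones when datasets are
sampled (scene framing precedes sensor degradation); `apply_degradation`
itself applies operators in the order given. A clean lesion scene places
its centre inside the central ~24% of the frame — a diagnosable photo is
framed on the lesion — so `bad_framing`, which pushes the centroid outside
the central 50% window (partial truncation allowed), is identifiable from
geometry alone.

An operator sets its explanation bit when its severity exceeds a
per-operator *diagnosability threshold* (default 0.3, configurable): no
published quantification exists of when dermatologists call a defect
undiagnosable, so the threshold is a package constant, and the quality
class flips to `poor_quality` exactly when at least one bit is set (the
only semantics consistent with severity-0 being the identity and with
poor-quality images carrying ≥ 1 explanation).

Dataset sampling draws operators for each poor-quality image independently
per operator with the inclusion probabilities in `degradation_mix`
(co-occurring defects are realistic and allowed), rejecting empty draws.
Note the conditioning: with two operators at probability 0.5 each, the
marginal inclusion becomes 0.5/(1 − 0.25) = 2/3. The default mix
(0.111/0.294/0.314/0.227/0.054) follows the relative prevalence of the five
tags in a large published annotation campaign, normalised to one expected
tag per image; how often tags truly co-occur per image is not published, so
the mix is exposed as configuration.

The rater simulator draws each annotator's verdict from a per-rater 4×4
row-stochastic confusion matrix (row = true class); emitted lesion verdicts
carry a placeholder ICD-10 code from a fixed list purely to exercise the
collapse rule, and emitted poor-quality verdicts report each true bit with
the rater's sensitivity and each absent bit with their false-alarm rate.
With identical symmetric raters the expected raw agreement has the closed
form Σ_c p(c)·Σ_k M[c,k]², which the tests verify by simulation.

**What passing synthetic tests does and does not show.** The generator's
scenes are procedural: no real skin texture, hair, shadows, or camera noise
beyond the five modelled defects, and the defect–pixel relationship is
noiseless by construction. Recovery results therefore validate the
*pipeline* — that the architecture, loss, weighting and training can
extract these labels when they are recoverable — and say nothing about
accuracy on clinical photographs.

## Grad-CAM

For any of the nine outputs, gradients of the pre-softmax class score or
pre-sigmoid explanation score (pre-activation scores avoid saturation) are
backpropagated to a convolutional stage (default: last stage, the coarsest
semantic map). Channel weights are the spatially averaged gradients; the
map is the rectified weighted sum of activations, bilinearly upsampled to
the image grid and normalised to max 1. An all-zero rectified map is kept
all-zero and flagged (`is_empty`) instead of being renormalised. The map is
invariant to positive scaling of the target score, and for a target equal
to the mean of one feature channel it reduces analytically to that
channel's rectified activation map — both are tested.

## Experiment scales and numerical choices

The test suite's end-to-end recovery study uses 2,000 images (500 per
class, 64×64), uniform operator inclusion 0.35, severities U(0.6, 1.0)
("strong degradations" — all above the diagnosability threshold), a 75/25
stratified split, and 20 epochs at lr 1e-3 from scratch (about a minute on
one CPU core); it requires held-out quality macro F1 ≥ 0.85 and every
explanation F1 ≥ 0.60. Unit tests train far smaller models (32×32,
8/16/16/16 channels). Tolerances: metric oracle equivalence to 1e-12
(float64 arithmetic), loss closed forms to 1e-9, probability simplex checks
to 1e-6 (float32 forward pass). Dropout masks come from a dedicated
generator owned by the model so that evaluation never consumes training
randomness.

## Known limitations

* Only the from-scratch `tiny_cnn` backbone is runnable; no pretrained
  feature extractor is bundled, so results on real photographs would
  require training data and likely a stronger backbone.
* Soft-label fusion, rater-quality estimation (Dawid–Skene style), skin
  segmentation preprocessing, and agreement coefficients beyond pairwise
  F1 (e.g. Cohen's κ) are out of scope.
* The synthetic `bad_light` operator clips at the 8-bit range, so its
  mean-intensity statistic saturates at extreme severities (monotone, not
  strictly increasing).
* Checkpoints are NumPy `.npz` archives with a JSON config sidecar; no
  mobile/quantised export is provided.
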