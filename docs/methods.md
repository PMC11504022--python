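# Methods

`cmbscreen` implements a two-stage screening pipeline for cerebral microbleeds
(CMBs) on susceptibility-weighted MRI (SWI), together with the synthetic
phantom data that makes every stage trainable and testable offline. This note
records the models, the choices made where the design was genuinely open, and
what the desk-scale experiments do and do not demonstrate.

## Box geometry and the Wasserstein loss

Boxes are continuous, 0-based, corner-format `(x1, y1, x2, y2)` rectangles
(`x` = column); area uses the continuous convention `w·h`, and rasterization
contexts treat boxes as half-open. The IoU family (IoU, GIoU, DIoU, CIoU)
follows the standard definitions.

The normalized Wasserstein distance (NWD) models a box as a 2-D Gaussian with
the box center as mean and `diag(w/2, h/2)²` as covariance. The similarity is

```
NWD(A, B) = exp( −√(Δcx² + Δcy² + ((wA−wB)/2)² + ((hA−hB)/2)²) / C )
```

with `C = 12.8` and a stability constant `δ = 1e−7` added inside each squared
difference, so the similarity of a box with itself is strictly below 1 and the
gradient never stalls at coincidence. A published rendering of this formula
multiplies the x- and y-center differences instead of summing their squares;
that product form is blind to any single-axis offset (similarity saturates at
1) and cannot reproduce the worked small/standard-box comparison, so the
Gaussian–Wasserstein form above is the implementation and the product form is
kept behind `literal=True` for comparison only.

The detector's regression loss is `(1−mix)·(1−CIoU) + mix·(1−NWD)` with
`mix = 0.5` by default. The mixing weight is a config field, not a constant,
because no principled single value exists; `mix = 0` reduces exactly to the
CIoU loss. The differentiable tensor implementation is cross-checked in the
tests against the independent closed-form scalar functions.

Two cells of the worked comparison table (the small-pair "C" and the
standard-pair "F" predictions) admit no (size, offset) configuration
consistent with all printed similarity values simultaneously; they are
treated as non-normative and not asserted. Likewise the printed DIoU/CIoU
value for the small pair (0.29) equals the plain IoU, while the definitions
give 0.22; the tests assert only the internally consistent cells
(0.29, 0.16, 0.92, 0.85 at 2 d.p.; 0.9 at 1 d.p. for both NWD cells).

## Saliency attention block

The block forms query tokens by adaptive **max** pooling of the feature map
(max pooling picks out extreme, salient responses) and key/value tokens by
adaptive **average** pooling (a smoothed "background board"), relates them
with multi-head attention, and adds the attended map back residually after
bilinear interpolation to the input grid. Open choices and their resolution:

* Token grids, not single vectors: a single global query would make attention
  degenerate (one softmax row), so queries form a 4×4 grid and keys/values an
  8×8 grid by default; grids are clamped to the feature-map size at insertion.
* The output projection is zero-initialized by default, making a freshly
  inserted block an exact identity — safe insertion into any backbone stage.
* Interpolation back to the grid is bilinear; nearest is available.

Its learnable-parameter count is exactly `4·(C² + C)` (four C×C projections
with biases), verified against module enumeration.

## Detector

A small anchor-free single-stage detector: stem + three downsampling stages
with residual conv blocks (a simplified C2f pattern), a top-down fusion neck,
and decoupled heads at strides 4 and 8 — two fine levels because targets
occupy 4–32 px. Each head cell predicts an objectness logit and softplus-
positive left/top/right/bottom offsets in stride units. Attention blocks sit
after the last two backbone stages and after each neck merge. Scales N/S/M/X6
reuse the conventional depth/width multipliers; matching any published
parameter count is a non-goal, and tests assert only orderings.

Training: center-based assignment (the cell containing the box center plus
in-box neighbours within 1.5 cells; boxes under 24 px side go to stride 4),
balanced binary cross-entropy over all cells, the combined box loss on
positives, Adam with gradient clipping, fully seeded. Inference: per-slice
decoding, class-agnostic greedy NMS at IoU 0.5 with deterministic tie-breaks
(score, then slice, then lexicographic coordinates), clipping to image
bounds, and a global per-patient truncation to the 100 highest-scoring
candidates. The score threshold is applied before the cap.

Flip equivariance of detection is a property of the decode+NMS machinery,
not of a learned CNN (correlation kernels are not flip-symmetric), so the
tests exercise it with a flip-equivariant intensity-threshold scoring stub.

## Text prompts and encoding

Each candidate is described by ordered statements: demographics
(`This is a {gender} patient with {age} years old.`), geometry (`Target
length and width are {L} and {W} pixels.`, with length mapped to box height
and width to box width, rounded half-up — the wording itself does not fix the
axis mapping), and the detection status of the previous/next slice at the
same position ("same position" = center within `max(box side, 5 px)`,
computed on the raw detection set before classification, since the prompts
describe the detector's state). Optional history/lifestyle statements are
appended only when data exists.

Statements are encoded to 768-wide vectors by any callable; the built-in
encoder is deterministic feature hashing (lowercase word tokens plus
character bigrams, signed blake2 hashing, L2 normalization), so the whole
repository builds and tests offline and byte-identically across runs. A
pretrained sentence encoder can be plugged in by passing the callable; none
is bundled.

## Multimodal classifier

Input is a `(3, 4, H, W)` candidate volume: the SWI slices below/at/above the
detection plus the phase slice, ordered `(S_{i−1}, S_i, S_{i+1}, P_i)`,
grayscale replicated to three channels, scaled to `[0, 1]`; missing neighbour
slices at stack edges are zero-padded and flagged.

* **Image branch** (volumetric): two 3-D conv blocks with spatial stride 2
  (temporal stride 1); batchnorm+GELU after the first, batchnorm after the
  second; channel schedule 3→128→512 (only the endpoints are fixed by the
  architecture contract: a 64×64 crop ends at spatial side 16 with 512
  channels); a learned additive position embedding; then channels×slices are
  merged into a token-channel axis and space is flattened —
  `(B, 2048, 256)` for the 64-px crop.
* **Text fusion**: each statement vector is linearly projected to the
  token-channel width, statements are mean-aggregated (output shape is
  independent of their number), LayerNormed, broadcast along the token axis,
  concatenated channel-wise with the image tokens and mixed by a kernel-1
  1-D convolution, then reshaped back to a `(B, C, T, H′, W′)` volume. The
  LayerNorm matters: the hash embeddings are unit-norm, so without it the
  projected text features are an order of magnitude weaker than the
  batchnormed image tokens and the fusion path trains far too slowly.
* **Head**: a 3-D convolution, flattening to tokens, a class token plus
  sinusoidal position encoding, `depth` pre-LN transformer encoder blocks
  (S: depth 4, B: depth 8; widths give a clear S<B parameter ordering), and
  a sigmoid readout of the class token. Decision threshold 0.5, configurable.
* **Variants**: `with_text=False` bypasses fusion entirely (a distinct code
  path, not a zeroed input). `image_branch_mode="averaged2d"` averages the
  four slices first and runs 2-D convolutions — the comparison variant whose
  averaging destroys the phase cue. `crop_mode` is `fixed32`/`fixed64`
  (window of ~2× box side, resized bilinearly) or `dynamic` (native window
  padded to a multiple of 4; position encoding falls back to the sinusoidal
  form because token counts vary). SWI and phase planes are cropped and
  resized jointly.

Training uses class-weighted binary cross-entropy, a stratified validation
split, Adam, and per-epoch validation TPR/TNR/accuracy; single-class inputs
are rejected with guidance.

## Evaluation metrics

Sensitivity, specificity and precision are exact ratios with zero
denominators reported as explicit `None` markers, never 0. `FPavg` is total
false positives over patients. The patient-level accuracy has two modes
because its defining formula and the prose disagree: the *literal* rule
scores a CMB-negative patient correct iff the true-positive count is zero
(vacuously true regardless of false positives), the *strict* rule requires
zero positive predictions of any kind. The strict value is the default
report and the literal value is always reported alongside;
`literal ≥ strict` holds for every input. Region-level classification TPs
require IoU ≥ 0.5 overlap with a ground-truth box on the candidate's center
slice (the matching criterion is otherwise unspecified). Detection mAP uses
greedy score-ordered one-to-one matching and 101-point interpolated AP over
the 0.50:0.05:0.95 IoU grid, cross-checked against a rasterized brute-force
matcher.

The per-patient inference-time model is closed-form:
`(slices·D_image + 100·C_image)/1000` seconds with the candidate budget fixed
at 100; wall-clock is never used for reported timing. Rounding is half-up to
2 decimals.

## Phantom generator

The generator emulates the statistical structure the pipeline assumes, not
anatomy or physics (no brain geometry, no k-space model):

* Background: level 150 with a smooth bias field (σ≈18, cubic-upsampled 5×5
  grid) and Gaussian noise (σ=6) in SWI; the phase background is flat (phase
  images are high-pass filtered in practice) with the same noise.
* CMBs: Gaussian-smoothed disks, diameter 4–32 px (scaled down with the image
  side in tests), spanning 1–3 slices with partial-volume tapering (0.6 at
  the ends), dark in SWI **and** phase. Counts are zero-truncated Poisson for
  positive patients (~37% of patients are positive by default).
* Calcification mimics: rendered through the *same* SWI appearance path as
  CMBs (tests verify that no simple SWI statistic separates the classes) but
  phase-bright — except a `phase_ambiguity` fraction (0.35 by default)
  rendered with a CMB-like dark phase signature, emulating
  filtering/partial-volume artefacts; these are resolvable only through the
  metadata prior. Vessels are elongated capsules persisting over ≥ 4 slices.
* Metadata: positive patients draw ages ~N(66/64, 9) (male/female), negative
  ~N(57/59, 9); 61% male. Calcification frequency is multiplied by
  `exp(effect·(0.04·(60−age) + ±0.8))` — mimics are relatively more frequent
  in younger female patients, which is the demographic where image-only
  classification is reported to fail. `metadata_effect` (default 1) scales
  the coupling.
* Ground-truth boxes enclose CMBs only and are measured from the rendered
  footprint (threshold 0.3 of peak), so an 8-px implant yields a 7–10 px box.
* Poisson draws are truncated to an area-based object cap; genuinely
  infeasible geometry raises with diagnostics. Datasets are generated in
  disjoint seeded splits with a manifest that regenerates them exactly.

## Desk-scale experiments: sizes and what they show

All experiments run on one CPU with seeds; the sizes are the package's
choices for a desk-scale demonstration, and none of them attempts to
reproduce full-scale clinical performance figures.

* **Detector recall** — ~200 phantom slices (50 four-slice patients, 96 px),
  a narrow N-scale model, 8 epochs; held-out recall at IoU 0.3 must reach
  0.7. On this phantom the detector typically saturates near recall 1.0
  within a few epochs; the floor demonstrates trainability, not clinical
  sensitivity.
* **Loss stability** — 3×3-px targets (diameter 2.6–3.4), 200 matched
  training steps; the variance of the box-loss trace with `mix=0.5` must not
  exceed the pure-CIoU variance. This isolates the loss property the
  Wasserstein term is for; pilot variances differ by ~2×.
* **Text ablation** — 100 six-slice patients with `calcification_rate=2.0`
  and `phase_ambiguity=0.5`, a regime where phase-ambiguous mimics and true
  CMBs have comparable mass among phase-dark candidates, so the metadata
  prior is decisive rather than marginal. Both arms train two matched seeds
  for 16 epochs; the statistic is the mean of the best-epoch validation
  accuracies (early-stopping selection). Only the direction (with-text above
  without-text) is asserted.
* **2D-vs-3D image branch** — mimics all phase-distinguishable
  (`phase_ambiguity=0`), text off in both arms; slice averaging destroys the
  phase cue, so the volumetric branch must not classify worse.
* **Saliency response** — a two-conv toy backbone trained (600 steps) to mark
  a dark blob whose background level varies per image; because a local
  receptive field cannot tell blob interior from a dark background without a
  global reference, the average-pooled background board inside the attention
  block carries the missing signal. The backbone with the block inserted must
  show a higher blob-vs-background response ratio in its output map than the
  same backbone without it (direction only). A within-net pre-/post-module
  contrast is *not* used: the trained block's additive component is globally
  conditioned but spatially near-uniform, so single-image deviation contrast
  cannot see it.

Passing these shows the machinery is correct and trainable under the
generator's assumptions. It does not show robustness to anatomy, scanner
variation, annotation noise, or any real-data property the phantom does not
model.

## Known limitations

* The neural stack is a compact numpy autograd implementation; it is exact
  (gradient-checked) but slow compared to GPU frameworks, so model scales in
  tests are small.
* The bundled text encoder is a hashing encoder, not a pretrained language
  model; the encoder interface accepts any callable producing 768-vectors.
* The phantom's mimic/metadata coupling is a stylized stand-in for clinical
  priors; absolute accuracies on it are not meaningful, only contrasts.
* `dynamic` crop mode pads per candidate, not per batch, when candidates in
  a batch disagree in size after rounding to multiples of 4.
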