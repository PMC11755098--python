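# Methods

This note records the models implemented by `alsseg`, their assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Network blocks and parameter accounting

The segmenter is a single-stage, prototype-based instance segmentation
network assembled from a declarative 25-layer graph (`alss_yolo_seg.yaml`).
All forward passes are inference-mode NumPy: convolution by im2col and one
matrix product per group, batch normalization frozen at its running
statistics, SiLU activations.  Training-time behaviours (BN statistic
updates, dropout, augmentation, losses, label assignment) are out of scope;
the package builds and runs the architecture and accounts for it exactly.

Parameter-count conventions, which the per-layer reports rely on:

* **CBS** = convolution *without* bias + batch norm with 2 learnable
  parameters per channel + SiLU.  Count: `k²·C_in·C_out + 2·C_out`
  (divide the weight term by `C_in` for depthwise).  This is the only
  convention that reproduces the reference table's convolution rows
  (232, 1184, 2336, 3504, 20832, 69872) exactly.
* **SPPF** (fast spatial pyramid pooling): 1×1 CBS to `C/2`, three chained
  5×5 stride-1 max-pools (padding 2, −inf padding value so pads never win),
  concatenation of the four stages, 1×1 CBS back to `C`.  At `C = 176` this
  gives `(176·88 + 2·88) + (352·176 + 2·176) = 77 968`.
* **MSCA** (multi-scale channel attention): 3×3 bias-free reduction
  `C → r`, `r = max(1, ⌊C/32⌋)` (the compression `C/32` is non-integral at
  `C = 136`; the floor is what the printed count implies), four
  adaptive-pool + depthwise branches at sizes (1, 3, 3, 5), bias-free 1×1
  expansion `4r → C`, sigmoid.  No biases, no batch norm, no activation
  after the reduction or depthwise convolutions — the only configuration
  giving 7248 parameters at `C = 136`.  The two identical 3×3 branches are
  implemented literally as specified; whether the duplication is intentional
  is unknowable from the architecture description alone, and the parameter
  count confirms kernel sizes (1, 3, 3, 5).
* **Upsample / Concat** contribute zero parameters.
* **ALSS** internals are only sketched in the source architecture
  ("adaptive channel splitting", "bottleneck structure", channel shuffle)
  and are fully defined elsewhere; the printed per-layer counts constrain
  but do not determine them.  The implementation here splits the input into
  a shortcut path and a main path (shortcut width =
  `min(round(C_in·split_fraction), C_out/2)`, split_fraction 0.5 by
  default), routes the main path through a 1×1-reduce / 3×3-strided /
  1×1-expand CBS bottleneck (bottleneck ratio 0.5), downsamples the
  shortcut with a depthwise 3×3 at stride 2, concatenates, and
  channel-shuffles with 2 groups.  Shapes match the reference table for
  every ALSS row; the parameter counts are reported but deliberately not
  asserted.
* **Segmentation head**: decoupled per-level branches.  Hidden widths are
  not published; the implementation uses the field-standard choices of
  `4·reg_max` for the box branch and the smallest level width (48) for the
  class and coefficient branches, with a prototype branch of
  3×3 CBS → 2× nearest upsample → 3×3 CBS → 1×1 conv to `k` maps at
  160×160.  This lands at 928 211 parameters against the published 918 811
  (≈1 % apart); the head is reported, not gated.

MACs are accounted per layer as `k²·(C_in/groups)·C_out·H_out·W_out`; the
printed GFLOPs column uses the 2×MAC convention, consistent with the first
layer's `216·320²` MACs ≈ 0.04 GFLOPs.

## Head decoding

* **Box decoding (DFL)**: each side distance is the expectation of a
  softmax over `reg_max = 24` bins, scaled by the level stride (8/16/32);
  distances therefore lie in `[0, 23·stride]`.
* **Coefficients** are tanh-squashed to realize the stated [−1, 1] range.
* **Mask assembly**: `σ(Σ_j c_j P_j)` is cropped to the (prototype-scale)
  box *before* thresholding at a strict `> 0.5` (ties break to background),
  then upsampled to image resolution by nearest neighbour.
* **Post-processing**: score filter (default confidence 0.3), per-class
  greedy NMS, ties broken by (score descending, flattened cell index
  ascending) so the output is invariant to candidate enumeration order.
* **Letterboxing**: aspect-preserving resize, gray pad 114/255, top-left
  anchored, scale and offsets returned for back-mapping.

## Annotation loop

Boxes are 0-based with inclusive max corners (a minimum bounding box is a
min/max over member pixels, which is inherently inclusive); the half-open
normalized convention appears only in the YOLO file formats, where the
pixel width picks up the `+1`.

The convergence criterion `|B(t+1) − B(t)| < ε` leaves the norm open; this
package defines it as: greedily match the two rounds' boxes per image by
descending IoU at ≥ `match_iou` (default 0.5), take the mean over matched
pairs of the maximum absolute corner difference, and force +∞ if any box on
either side is unmatched — an appearing or disappearing instance is a
change, not noise.  Defaults: ε = 2 px (pixel-scale stability is the
natural notion of "boxes stopped moving"), five iterations maximum
(matching the workflow the loop models), detector retrained from scratch
each round under a fixed seed for bit-for-bit reproducibility (warm
starting is an unstated alternative; from-scratch was chosen for
determinism).  Seed images and manually corrected images are flagged *fine*
and never overwritten by detector output.  An infinite ε accepts any
change, so the loop then runs exactly one iteration.

## Synthetic scenes and backends

The generator produces the *geometric and statistical* structure the loop
and the metrics need, not photorealism: smooth blob instances (randomized
low-order harmonic boundaries), 3–8 px occluder strips spanning the frame
that are subtracted from instance masks, small background clutter blobs
that never count as foreground, texture noise, and a per-scene radius
multiplier drawn from {1.0, 2.4} emulating the 12 m vs 5 m altitude ratio.
Default frame 192×192 with 4 instances of base radius 8–13 px — small
enough that the multi-seed loop simulation runs in seconds on one CPU while
preserving realistic instance/occluder/clutter proportions; the loop logic
itself is resolution-independent.  All randomness descends from one seed
through seed-sequence spawning with fixed per-stream keys, so e.g. an
occluder-free re-render of the same seed has an identical layout.

The **oracle segmenter** answers a box prompt with the ground-truth mask of
the best-overlapping instance, optionally boundary-perturbed by thresholding
the signed distance transform shifted by a smooth random field (σ in
pixels); point prompts select the instance holding the majority of positive
points, vetoed if a negative point falls inside it.  The **mock detector**
returns the true boxes minus Bernoulli(miss_rate) drops, with Gaussian
corner jitter and Poisson(fp_rate·n) spurious boxes; `train()` moves
(miss_rate, jitter) along a learning-curve schedule keyed by labeled-set
size — default (0: 0.5/4 px, 8: 0.25/2 px, 16: 0.1/1 px, 24: 0.0/0.5 px).
No quantitative error model for real promptable segmenters or detectors is
available, so these noise bands are this package's own constructs; passing
simulations demonstrate the *mechanics* of the loop (feedback, convergence,
the more-labels→better-masks trend), not performance on real imagery, which
additionally involves appearance ambiguity, correlated errors and prompt
sensitivity that the oracle does not emulate.

The loop simulation used in the tests runs 30 scenes, a 20 % prompt seed,
five rounds with ε = 0.01 px so every round executes (the residual 0.5 px
jitter keeps the delta above any smaller tolerance), across seeds 0–2.

## Metrics

* Greedy score-ordered matching with a single-claim rule per ground truth;
  the matcher is the de-facto standard since none is prescribed.
* P, R, F1 use the explicit 0/0 → 0 convention.
* AP integrates the all-point precision envelope (AP is written as an
  integral, so no 11-point or 101-point sampling); the envelope equals a
  brute-force "max precision at recall ≥ r" integration to 1e−9 in tests.
* mAP ranges default to 0.50–0.90 step 0.05, matching the labelling of the
  reference experiments; the COCO 0.50–0.95 convention is a parameter away.
* mIoU pools pixels per class over the evaluated image set (it is a
  per-category formula, not a per-image one); with a single class, pooled
  and per-class values coincide.  The per-image filtered report (mean over
  images above a floor, default 0.75, plus the excluded count) mirrors the
  reporting style used for zero-shot plantation evaluations.
* Classes with no ground truth have undefined AP and are excluded from mAP
  (logged); classes empty on both sides are excluded from mIoU (logged).

## Numerical choices and degenerate inputs

* float32 feature maps; float64 softmax expectations in box decoding.
* Max-pool padding value −inf; adaptive average pooling partitions input
  bins as `[⌊iH/s⌋, ⌈(i+1)H/s⌉)`.
* Empty masks are rejected by bounding-box extraction; masks emptied by
  occlusion are dropped at generation time; empty prompt sets and untrained
  detectors raise immediately.
* Weight initialization is He-normal from a per-network seeded generator;
  forward passes are bit-deterministic given (spec, seed, input).

## Known limitations

* No training: shipped networks are randomly initialized, so `model
  forward` demonstrates the inference pipeline, not a trained segmenter.
* ALSS internals and head widths are this package's reconstruction; their
  parameter counts are close to but not equal to the published per-layer
  numbers (table rows that are fully determined match exactly).
* The published benchmark results on real plantation/scene datasets require
  those datasets, pretrained promptable-segmenter weights and GPU training,
  none of which desk-scale simulation can or should stand in for.
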