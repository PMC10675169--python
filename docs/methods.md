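# Methods

## Data model

A recording is seven synchronized 50 Hz streams, one per body placement
(sternum, left/right wrist, left/right thigh, left/right lower leg), each
carrying three-axis acceleration in g and three-axis angular velocity in
deg/s. Values are saturated at the configured measuring ranges (±8 g,
±1000 deg/s) — clipping, not rejection, because that is what a saturating
sensor does. Timestamps may arrive as epoch milliseconds or seconds; the
loader tells them apart by magnitude (>1e10 ⇒ milliseconds), since both are
common vendor exports and the two are unambiguous at modern dates.

Streams are resampled onto a phase-aligned uniform grid (grid points at
integer multiples of 1/rate) by componentwise linear interpolation, with no
extrapolation beyond the recorded span. Synchronization takes the
intersection of the seven time spans; how the original sensors' clocks were
reconciled is unknowable from the data model alone, so intersection plus
linear interpolation is this package's own choice. Inter-sample gaps up to
0.5 s are bridged by the interpolation; longer gaps should be split into
segments (`split_on_gaps`) rather than fabricating motion across them.
Orientation-aware (quaternion) interpolation is deliberately not used: the
classifier consumes raw component streams, so that is what resampling should
preserve.

## Frame encoding

One second of recording becomes a 2 × 21 × 50 value grid (channels ×
rows × columns; presented as image resolution 50 × 21 × 2 in column × row ×
channel order). Row = 3·sensor_index + axis with the canonical sensor order

```
0 STERNUM, 1 LEFT_WRIST, 2 RIGHT_WRIST, 3 LEFT_THIGH,
4 RIGHT_THIGH, 5 LEFT_LOWER_LEG, 6 RIGHT_LOWER_LEG;  axes x, y, z
```

Any fixed order works if used consistently; the order is therefore recorded
in frame, dataset and model-checkpoint metadata, and prediction refuses
frames whose declared order differs from the checkpoint's. Values are
normalized by the full-scale ranges (acc/8, gyr/1000) so that saturation
maps to exactly ±1; the encoding is exactly invertible (`decode_frame`).
Windows are non-overlapping by default (hop = 1 s); the hop is configurable
but nothing in the package assumes overlap.

## Synthetic sessions

The simulator replaces the scripted human wearer used to create supervised
data. A script is a list of whole-second segments, each one posture or
walking plus a set of moving extremities (walking requires both lower
extremities — enforced at validation). Per segment and sensor:

* **Gravity.** The accelerometer reads a posture-specific unit vector:
  all sensors "anterior" (x) when lying; thighs and forearms horizontal but
  trunk and shanks vertical when sitting; everything vertical when standing
  or walking. These orientations are the physical mechanism that makes the
  three static postures separable, mirroring how real sensor attitudes
  differ between postures.
* **Gait** (walking): 1.8 Hz sinusoidal swing, 200 deg/s on the sagittal
  gyro axis and 0.4 g fore-aft on thigh and lower-leg sensors, antiphase
  left vs right, plus a 0.1 g sternum bob at twice the cadence. 1.8 Hz and
  200 deg/s are ordinary comfortable-walking magnitudes.
* **Extremity movement:** a band-limited burst (sum of 3 sinusoids with
  random frequencies in 2–5 Hz and random phases) on the wrist (hands) or
  thigh+lower-leg (legs) sensors, 120 deg/s gyro and 0.3 g accel peak.
* **Noise:** white Gaussian, σ_acc = 0.02 g, σ_gyr = 2 deg/s — roughly two
  orders of magnitude below the activity signals, so classes are separable
  by construction but not trivially noise-free.

All amplitudes sum to well under the measuring ranges, so no generated value
is ever clipped. One seeded generator drives every random draw; the same
script and seed reproduce bit-identical streams. Burst parameters are drawn
in canonical extremity order (RH, LH, RL, LL), which makes the noise-free
signal exactly mirror-symmetric under a left/right swap of script and sensor
locations — except for walking, whose antiphase legs are mirror-symmetric
only up to a half-period time shift.

The balanced dataset enumerates the 52 admissible label combinations
(3 static postures × 2⁴ extremity subsets + walking × 2² hand subsets) and
allocates windows as evenly as possible (counts differ by ≤ 1); the default
size is 10,000 one-second frames. The exact combination inventory used in
the original protocol is not recoverable, so full enumeration is this
package's reconstruction of "covering different label combinations".

What the simulator does *not* model — and therefore what passing tests do
not show about real data: biomechanically realistic gait, soft-tissue and
mounting artifacts, sensor bias/drift, movement pathology, transitions
blurred across window boundaries (segments change state on whole seconds),
and externally caused (passive) movement. Results on synthetic data bound
the pipeline's correctness, not its field accuracy.

## Classifier

Architecture (all config-driven via `NetworkConfig`): a 3×3 convolution stem
(8 channels), an optional 2×2 average pool directly after the stem (default
on), then one residual stage per entry of `widths` — each stage a VGG-style
double 3×3 convolution block with identity skip (1×1 projection when widths
change) and 2× average-pool downsampling between stages — global average
pooling, and a dense 8-unit head read through sigmoids. Default widths are
(16, 32). This embodies the ResNet + VGG hybrid at a size a single CPU
trains in about a minute per thousand windows; deeper/wider variants are a
config change, and a config whose feature map shrinks below the kernel is
rejected at construction.

The engine itself (im2col convolutions, backprop, Adam) lives in
`posturekit.nn`, in float32. The convolution input-gradient is computed as a
same-padded correlation with the spatially flipped kernel (valid for odd
kernel sizes), which keeps the backward pass BLAS-bound; it is verified
against finite differences in the test suite.

Training: mean per-label binary cross-entropy (the natural multilabel loss
for eight independent binary variables), Adam at 3e-3, batch 64, at most 25
epochs with early stopping on held-out loss (patience 5) and best-epoch
parameter restoration. The 90/10 split is stratified by the full 8-label
combination with largest-remainder allocation, so the held-out set is
exactly 10% and every combination is proportionally represented. Everything
is deterministic given the network seed (initialization, batch order,
dropout) and the split seed. The learning rate and epoch budget were chosen
for fast, stable convergence of this small float32 network; posture
exclusivity is *not* in the loss.

Labels that are single-class in the training split are flagged untrainable
with a warning and listed in the training report, but remain in the loss: a
constant target simply drives the head bias toward that constant, which is
both harmless and what makes degenerate datasets (identical frames and
labels) trainable to zero loss.

Post-processing: extremities thresholded at 0.5; exactly the arg-max posture
is set, ties broken toward the later label in LY < SI < ST < WA order (an
all-zero score vector therefore yields WA — a deliberate, documented
tie-break; such seconds are low-confidence by definition); a walking second
forces RL = LL = 1. The output of post-processing satisfies the credibility
rules for arbitrary score inputs, which the suite fuzz-tests.

## Annotation scheme and metrics

Per-second codes are `POSTURE[/EXT EXT ...]` (e.g. `SI/RH`, `WA/RL LL`) or
`?` for out-of-scheme seconds. Parsing is case- and whitespace-tolerant and
order-independent in the extremity list; formatting canonicalizes (posture,
extremities in RH LH RL LL order), and parse ∘ format is the identity on all
52 admissible combinations. The flat `second,code` CSV is the supported
interchange; the annotation tool's native format is out of scope because the
scheme, not the tool, is the content. Seconds marked `?` in either track are
dropped pairwise before any metric.

Metric conventions: "mean accuracy" and "mean IoU" are macro averages over
the eight labels, with pooled (micro) figures reported alongside, since
either reading is defensible. Confusion rates are truth-conditional (TP/FN
normalized over truth-positives, TN/FP over truth-negatives). AUROC uses the
rank/concordance formulation (ties ½), computed via scikit-learn and checked
against an all-pairs brute-force oracle in the tests. The headline κ of two
multilabel tracks is defined here as the unweighted mean of per-label κ
values (a single multilabel κ has no standard definition); per-label values
are always reported, and labels on which both tracks are constant are
undefined (NaN) and excluded from the mean. The κ interpretation band
between weak (0.40–0.59) and strong (0.80–0.90) carries no name in the
source scale — an apparent typesetting omission — and is labelled
"moderate" here.

## Behavior summaries

Credibility checking reports, per second, violations of posture exclusivity
and of the walking ⇒ both-lower-extremities rule; extremity labels during
static postures are always admissible. Summaries treat seconds with no
posture label as unlabelled time: they are counted and reported but excluded
from every percentage denominator. Transitions are counted between adjacent
labeled seconds only (an unlabelled stretch breaks the run), and timelines
are run-length encodings of the per-second state sequence. Relative
extremity usage is reported within limb pairs (RH vs LH, RL vs LL) — the
asymmetry signal of interest in unilateral impairment. Wear-time feasibility
means: no inter-sample gap above 60 s (a default; "continuous" is otherwise
qualitative) and total duration ≥ 24 h.

## Problem sizes and numerical choices

The test suite trains on 2,000-window balanced datasets (three seeds) and
generates one full 10,000-window dataset; both sizes keep a single-CPU run
in minutes while leaving the 90/10 protocol and combination coverage intact.
Resampling identity and encode/decode round trips are asserted at 1e-9;
batching invariance of the network at 1e-5 (float32 accumulation order);
epoch-millisecond timestamps are honest to ~1e-7 s in double precision.
Duplicate timestamps keep the first sample; posture ties after annotator
label flips keep the highest-priority surviving posture (WA > ST > SI > LY).

## Known limitations

* The simulator's separability makes near-perfect held-out scores expected;
  they say nothing about accuracy against human-annotated video of real
  wearers.
* The network is small and CPU-oriented; no GPU path, no transfer learning.
* No distinction between self-generated and externally caused movement.
* Weighted κ, bootstrap confidence intervals and calibration analysis are
  not implemented.
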