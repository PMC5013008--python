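# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `hystsum`, and what the synthetic-data tests do and do
not demonstrate.

## Problem setting and assumptions

Diagnostic hysteroscopy video is continuous, unedited and has no shot
boundaries; color and texture vary little across a session. The pipeline
rests on two domain assumptions: (1) diagnostically important regions are
examined slowly, so important frames sit in low-motion segments with many
near-duplicates; (2) important content is locally *busy* — lesions and
injured tissue carry high texture entropy, contrast and curvature, whereas
glare- or blur-contaminated frames and featureless tissue do not. The four
saliency models operationalize these cues; no semantic understanding of
pathology is attempted.

## Operators and numerical conventions

All operators use mirror reflection at borders (edge pixel not duplicated,
`np.pad(mode="reflect")` / `scipy.ndimage mode="mirror"`): zero padding
would create spurious border saliency in every model.

**Motion.** The estimator behind the motion field is deliberately the
simplest deterministic choice: exhaustive block matching (default block
16 px, search radius ±8 px, integer displacements) minimizing the sum of
absolute luminance differences, under the convention
`cur[y, x] ≈ prev[y − dy, x − dx]`. Ties are broken by smallest
displacement magnitude, then smallest `dy`, then smallest `dx`, so constant
frames yield an exactly zero field. The first frame of a sequence has no
predecessor and is assigned a zero field. An optical-flow method would be
less transparent and not oracle-verifiable to the last bit; the frame-level
statistic (mean motion magnitude) is insensitive to the estimator's
sub-block detail.

**Texture.** Local entropy uses a 15×15 window over 256 gray levels, with
luminance quantized by `floor(g·256)` clipped to 255. The entropy is
normalized by `log2(256)` so the segmentation threshold `τ = 0.8` operates
on a `[0, 1]` scale; on the raw 8-bit scale (entropies up to 8 bits) a 0.8
threshold would be almost always exceeded and segment nothing useful. The
window default matters: a `w×w` window caps normalized entropy at
`log2(w²)/8`, which is below 0.8 for `w ≤ 9`; `w = 15` caps at 0.976,
keeping `τ = 0.8` meaningful. The implementation accumulates one
`−p·log2 p` term per occupied gray level in ascending order via integer
integral-image counts, which reproduces a per-pixel histogram loop
bit-for-bit — the unit tests assert exact equality with a brute-force
oracle. The mask is post-processed by closing with a disk (radius 5;
the structuring element is a free choice, a disk being isotropic like the
anatomy) and flood-fill hole filling. Two frame-level statistics exist —
mean of the masked luminance and the mask area fraction; the pipeline
scores texture by the **area fraction**, matching the premise that a frame
is salient when a *large proportion* of it is injurious.

**Contrast.** The 5×5 neighborhood excludes the center pixel (its term is
zero anyway; documented for oracle parity). Channel values are on `[0, 1]`
and the three channels are summed. The map is computed by explicit
neighbor-shift differences rather than the algebraically equivalent
box-filter expansion, so constant inputs give exact zeros instead of
`~1e-14` cancellation residue. The Gaussian pyramid uses σ = 1 smoothing
and factor-2 decimation; level maps are upsampled to base resolution by
bilinear interpolation before summation (the cross-scale alignment is a
free choice; bilinear is deterministic and order-1 accurate).

**Curvature.** Luminance is smoothed by a Gaussian of scale σ = 1.5 px
(kernel truncated at 3σ); the four second partials are central finite
differences of the smoothed image. `g_xy` and `g_yx` coincide analytically
but are computed independently, preserving the four-term root-sum-square
form. Rotation invariance holds to machine precision for 90° rotations of
smooth inputs (asserted < 5 % relative, observed ≤ 1e-6).

## Fusion and extraction

Per-frame scores are normalized by dividing by the sequence maximum, not
min–max: zero is meaningful (an all-zero map scores zero) and must stay
zero. An all-zero score vector normalizes to all zeros rather than
erroring — a static video is a legitimate input. Scoring happens per frame
first, then normalization across frames; the alternative order (normalize
maps, then score) differs only by a per-frame positive factor and the
score-then-normalize order is the one that makes the downstream threshold
rule scale-invariant.

The fusion weights are equal by default (weighted linear fusion with
unspecified weights degenerates to the mean); they are configurable per
model, and zeroing a subset implements model ablation. The normalized
motion score is converted to stillness (`1 − s`) before fusion
(`motion_as_stillness=True`): important segments are the slowly-examined
ones, so raw motion magnitude is evidence *against* importance at the
frame level. Setting the flag false recovers plain magnitude fusion.

Extraction: the threshold rule uses the arithmetic mean of the curve with
a strict `>` comparison (a constant curve yields no keyframes). The NKF
rule partitions the `n` frames into `min(NKF, n)` contiguous shots, the
first `n mod NKF` shots one frame longer, and takes each shot's earliest
argmax — an arithmetic partition chosen for determinism and
oracle-checkability.

## Evaluation

Matching is one-to-one within a ±tolerance window (default 0): truth
indices are processed in increasing order and each takes the earliest
still-unmatched extracted index inside its window. This interval greedy
provably attains the maximum matching cardinality (verified against an
exhaustive assignment oracle in the tests), which a nearest-neighbor
greedy does not. Accuracy is `100·TP/|truth|` and therefore equals recall
as a percentage — integer accuracy steps with 10 ground-truth keyframes
(30 %, 40 %, ...) follow directly. Empty ground truth yields accuracy and
recall 0 by convention.

## Synthetic data: what it emulates, and what it does not

The generator renders a large pink tissue canvas with band-limited
(σ = 3 smoothed) noise, viewed through a moving window with a circular
vignette. The camera alternates fast pans (12 px/frame) with slow dwells
(1 px/frame) centred on lesion patches carrying near-white noise of
amplitude 100 (8-bit scale) — high local entropy, contrast and curvature.
30 % of pan frames get saturated glare blobs plus blur; dwell frames are
never contaminated, which keeps the planted ground truth unambiguous for
recovery tests. Ground truth is the middle frame of each dwell. Defaults
are 240 frames at 128×160; tests and the acceptance script run 60–90-frame
videos at 80×96, sizes chosen so the whole suite completes quickly on one
CPU while every frame still contains multiple motion blocks and entropy
windows.

Passing these tests shows that the operators measure what they claim and
that the fused curve separates slow, textured dwells from fast, glary pans
under controlled statistics. It does **not** show clinical performance:
real DH footage has correlated lighting drift, fluid turbidity, deforming
tissue and lesions that are not noise patches, and expert keyframe choice
encodes pathology, not texture energy.

## Known limitations

- Block matching returns integer displacements only and saturates at the
  search radius; very fast pans are clipped, which still separates pan
  from dwell but under-reports pan speed.
- The texture stage is blind to lesions whose entropy stays below τ within
  the window size; window and τ trade sensitivity against glare false
  positives.
- Video-container input depends on the imageio plugins available at run
  time; directories of PNG/JPEG/TIFF frames are the fully supported path.
- Per-model normalization divides by the per-video maximum, so scores are
  comparable within a video but not across videos.
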