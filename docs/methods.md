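# Methods

## Model

The backbone is a reduced first-generation residual network: a 3x3
convolutional stem followed by 8 residual blocks (two 3x3 convolutions
with batch normalisation on the residual branch; identity skip, or 1x1
projection where channel count or resolution changes; activation after
the merge). The output of each block's final activation is its *tap
point*, used by the decoding and activation analyses; the
residual-branch output just before the merge is the target of spatial
scrambling. Global average pooling over the final block feeds the
classification heads.

**Global gain.** A single scalar δ multiplies the output of *every*
activation function — the stem activation and both activations of each
block share one `GlobalGainState`. δ = 1 is the neutral state; all
training happens there, and δ is varied only at evaluation, so
performance changes across δ isolate the gain mechanism from learning.

**Activation function.** Two variants. The rectifier is
`f(S) = δ·max(0, S)`. The saturating variant is
`f(S) = δ·A_max·tanh(max(0, S)/A_max)` with ceiling `A_max = 5`
(default): non-negative, monotone, within ~1.4 % of the rectifier on
S ∈ [0, 1], and bounded by `A_max` before gain scaling. This family
realises the qualitative contract of a cortical transfer function —
threshold, quasi-linear mid-range, firing-rate ceiling — with a single
interpretable parameter; the analyses do not depend on the algebraic
form beyond these properties, and the rectifier variant is available as
a control.

**Normalisation under gain (a deliberate design decision).** With
normalisation statistics frozen at their training values, a network this
deep has an extremely narrow usable gain range: a single δ a few percent
from 1 compounds through 17 activation sites, drives every layer out of
its trained operating range, and collapses all profiles to a delta
function at δ = 1 (we verified this directly; accuracy was exactly at
chance everywhere except δ = 1). We therefore treat normalisation as
homeostatic: entering a gain state means setting δ *and re-estimating
every normalisation layer's running mean and variance under that gain*
on a fixed calibration set (the generic pre-training images, 256 at desk
scale), deterministically (fixed order, two passes, batch statistics
pooled with batch-size weights). Biologically this says normalisation
tracks the prevailing drive level rather than staying pinned to the
neutral state; computationally it lets gain act through the informative
channels — the balance between δ-scaled skip branches and normalised
residual branches, threshold/saturation shifts, and the scaling of the
final features against the fixed readout — rather than through
catastrophic distribution shift. Frozen-statistics evaluation remains
available by entering a gain state without calibration images.
`weight_hash` covers learned parameters only, so entering a gain state
never changes checkpoint identity.

## Stimuli

All images are procedural, in [0, 1], float32.

**Real scenes.** Multi-scale oriented gratings (log-uniform spatial
frequency 0.04–0.35 cycles/px) under Gaussian envelopes, plus 3 random
polygonal occluders, min–max normalised and then given a per-image
contrast (pixel SD uniform in 0.12–0.30) and mean luminance (0.4–0.6) —
the heterogeneity of real photographs, which matters because blending k
images attenuates contrast roughly by 1/sqrt(k): large-k averages fall
far below any single scene's contrast while k = 1.25 blends overlap the
real distribution.

**Average images.** The weighted pixel mean of ceil(k) source scenes.
Integer k uses equal weights 1/k; fractional k = n + α uses weights
(1, …, 1, α)/k, so k = 1.25 is one full image plus a second at 25 %
alpha, and k = 1 reproduces its source exactly. Averages are *not*
re-normalised after blending (flag `renormalize` exposes the
alternative): the natural contrast loss is part of the stimulus.
Sources come from a pool disjoint from the real-class pool; train, val
and test splits use disjoint pools; every split is exactly 50/50
balanced; real-class images are shared across difficulty levels while
averages are rebuilt per level.

**Category stimuli** (pre-training and the answer-options task).
Category i of 8 is a conjunction of grating orientation i·π/8, an
occluder shape family and a mild multiplicative colour tint, composited
on the same scene-texture distribution as the discrimination task so the
learned features match the task domain. The tint makes categories
linearly identifiable from raw pixels by construction (a probe
calibration anchor), but colour-jitter augmentation during training
makes it an unreliable cue for the network, pushing the representation
toward texture and shape.

## Training protocol

The backbone (with a softmax category head) is trained once per study,
entirely at δ = 1, with momentum SGD (0.9), cosine learning-rate decay,
weight decay 1e-4, and augmentation: pixel noise (SD 0.1),
contrast/brightness jitter (±30 %/±0.1), per-channel colour jitter
(±30 %), and mixup (Beta(0.4, 0.4), on half the batches). Mixup is
load-bearing: convex image blends with soft labels force deep features
to encode mixture proportions, the cue the k = 1.25 discrimination
rests on — without it that signal, present in early blocks (probe
accuracy ≈ 0.72 at block 1), vanished from the pooled features
(≈ 0.49, chance). Divergence (non-finite loss) raises a training error.

Each experimental condition gets sigmoidal readout heads fine-tuned on
the pooled final-block features of the frozen backbone (hash-checked) at
δ = 1. One head per *model instance*; instances differ by seed through
their initialisation, data order, and an 80 % subsample of the
fine-tuning data, giving them the independent-run variability that a
shared frozen backbone otherwise suppresses. Features are standardised
during head training and the affine map folded back into raw feature
space, so a head is a fixed affine readout applicable at any gain state.
Answer-option heads are multi-unit sigmoid (one-vs-all) heads over a
category subset; subsets of size 2 and 4 are drawn independently per
iteration (20 by default) from the 8 categories, distinct within a draw.

## Analyses

**Gain sweep.** The δ grid is geometric (gain is multiplicative) on
[0.125, 8], 60 points by default, with the point nearest 1 snapped to
exactly 1.0. Per instance and δ: accuracy, hit and false-alarm rates,
d′ = z(hit) − z(FA) and criterion c = −½(z(hit) + z(FA)), extreme rates
corrected by 1/(2N) before the quantile transform; the categorical task
reports the unweighted mean one-vs-rest AUC. The peak gain of a profile
is, per instance, the median of the δ set attaining the best value
(maximum; minimum |c| for the criterion, since good performance means
bias near zero); across instances we report the median and a Student-t
95 % interval on the mean. Restricting the grid to δ ≤ 1 implements the
limited-arousal-range analysis.

**Decoding probes.** Logistic regression (scikit-learn defaults,
max_iter 1000) on flattened tap activations, with a seeded Gaussian
random projection to at most 4096 dimensions (1024 at desk scale) when
taps are larger; 5 iterations of disjoint random train/test draws
(1000/1000 by default) per (block, δ, difficulty) cell; single-class
draws are redrawn and counted. Difficulty levels decoded above 0.99
everywhere are excluded from peak aggregation (ceiling rule); per-block
peak gains are averaged across the remaining difficulties; the most
informative block per (difficulty, δ) reports the first and last tied
block index. Mean activation is the scalar mean over images, channels
and space per tap.

**Spatial scrambling.** `scramble_block` permutes the spatial positions
within a random subset of ceil(p·C) feature maps of the residual-branch
output, independently per map and per image, preserving each map's
exact value multiset; untouched maps are bit-identical. A seeded
`Scrambler` replays its stream, so one repetition applies the same
perturbation across all gain states (paired within repetition), while
repetitions differ. Importance curves measure accuracy vs p at δ = 1
(p = 0 anchored at the exact unperturbed baseline; 10 repetitions by
default); after isotonic non-increasing smoothing, the calibrated rate
p\* is the smallest p at which retention
r(p) = (perf(p) − floor)/(perf(0) − floor), floor = min(perf(1),
chance), falls to 0.2, linearly interpolated between grid points —
p\* = 1 with a warning if retention never reaches threshold, and a
degenerate-block error if the unperturbed performance is not above the
floor. Progressive disruption scrambles the last s blocks
(late→early) or first s blocks (early→late) at their p\* for
s = 1…B−1, sweeping δ per stage; per-stage peaks are computed per
repetition (instances averaged within repetition) with the same median
tie rule.

## Problem sizes

The default `StudyConfig` keeps the full-scale setup: 64x64 images,
widths 16–128, six difficulty levels (1.25, 2, 3, 6, 20, 40),
2000/600/600 images per split, 10 instances, 60-point grid. Tests,
analysis drivers and the acceptance script run `desk_profile()`: 32x32
images, levels {1.25, 20}, 600/160/400 per split, 5 instances, 21-point
grid, 3-iteration probes at 300/300 with 1024-dim projection, 5
scrambling repetitions on a 13-point grid with a 160-image test subset.
These are the package's single-workstation problem sizes; every knob is
a `StudyConfig` field.

## What the synthetic study does and does not show

The generator reproduces the statistical skeleton the tasks assume —
parametric blend difficulty with contrast and structure cues, disjoint
pools, balanced splits, domain-matched pre-training — but not the
richness of natural photographs or of an ImageNet-trained hierarchy:
features here are narrower, more correlated, and the hard task sits
much closer to chance (≈ 0.53–0.61 at δ = 1) than a large model's
(≈ 0.6–0.65). Consequently the *contracts* (exact neutral-gain
identity, homogeneity, SDT/AUC/calibration arithmetic, scrambling
invariants, probe null calibration) are sharp tests, while the
*directional* results — whether easier tasks peak at gain states at
least as high as harder ones, and whether disrupting late blocks shifts
the peak upward — are reproduced only in part at desk scale: profiles
show the inverted-U shape with graceful degradation on both sides of
δ = 1, but the easy condition's peak pins at δ = 1.0 rather than
shifting clearly above it, because the readout margin that would let
accuracy plateau across a band of gain states is narrower for a small
backbone than for a large heterogeneous one. The across-difficulty peak
ordering is therefore sensitive to seed at this scale; the tests state
the directional hypotheses exactly and report honestly when a seed does
not realise them.

## Numerical choices

Float32 throughout the network; convolutions are im2col + BLAS matmul;
backward passes are hand-written and verified against finite
differences. Peak ties use exact float equality (accuracies are
multiples of 1/n_test, so ties are meaningful); the criterion peak uses
|c|. BN eps 1e-5; probe features are not standardised (scikit-learn
defaults, matching a plain logistic probe); AUC ties count 1/2.
Degenerate inputs raise: gain ≤ 0, grids without 1.0, single-class
probe pools after 50 redraws, zero-trial SDT counts, importance curves
whose baseline is not above the chance floor.

A desk-scale corollary of the scrambling design: because scrambling
preserves each map's value distribution and the easy task's cue is
itself largely distributional, single-block importance curves for the
easy task often never fall to 20 % retention, so the calibrated rates
take the p\* = 1 fallback and progressive disruption operates at full
scrambling. The perturbation still discriminates — it removes all
spatial information from the targeted blocks — but per-block importance
is flatter than it would be for a spatial-structure-bound task.
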