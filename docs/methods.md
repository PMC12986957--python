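# Methods

## Problem setting

Mangrove change detection from bi-temporal aerial imagery is dominated by a
conflict between appearance and ecology: between two acquisitions the tide
moves, so water extent, waterline morphology, wet-mud albedo and sun glint
change dramatically while the vegetation itself is stable. A useful detector
must ignore this *pseudo-change* and respond only to structural change
(stands appearing or disappearing), which typically covers a small minority
of pixels. `tidalcd` implements a dual-stream difference-modeling network
with deep-guided multiscale fusion for this setting, together with a
synthetic tidal-scene generator that reproduces the statistical structure of
the problem so the whole pipeline can be exercised on a laptop CPU.

## Network

**Encoder.** A shared-weight (siamese) 18-layer residual encoder taps its
four stages, giving per-image feature pyramids at strides {4, 8, 16, 32}
with channels {64, 128, 256, 512}. 34-layer and (experimental) 50-layer
variants are selectable; the 50-layer stage widths are adapted to the
pyramid contract by learned 1×1 projections. Initialization is He-normal
from the run seed; the package performs all training from scratch and does
not ship or download pretrained weights.

**Dual-stream change fusion (DSCF).** At every level the bi-temporal pair
(F₁, F₂) is fused by two branches. The *connection branch* concatenates the
pair and applies a 3×3 block at 2C′ then a 1×1 block back to C′, preserving
context. The *difference branch* (difference-aided attention unit, DAU)
computes the signed difference F_d = F₁ − F₂ (an |·| variant is a config
flag), exchanges the odd-indexed channels between the two inputs
(deterministic alternating mask at ratio ½, so the channel multiset is
conserved), and derives spatial gates
W_j = σ(WtConv(DSConv(F_d ⊕ F_{jk}))) per stream, where DSConv is a
depthwise-separable 3×3→1×1 block mapping 2C′→C′ and WtConv is a
shape-preserving wavelet convolution (one level of orthonormal Haar
decomposition, trainable depthwise 3×3 per sub-band, inverse
reconstruction). A channel gate W_S = σ(Σₖ Ψₖ(pool(F_d))) sums k = 4
two-layer perceptron branches (hidden width 8) over the globally pooled
difference. The gated features W_S ⊗ W_j ⊗ F_j are concatenated and reduced
by a final depthwise-separable convolution. Branch outputs are fused by
concatenation followed by a single 3×3 dilated convolution (dilation 2);
an additive variant (X = F_cat + F_diff) is selectable by config.

**Deep feature guidance (DFG).** The two deepest fused levels produce a
single-channel guidance map at stride 16: X₄ is 1×1-compressed to 256 and
bilinearly upsampled, concatenated with X₃, mixed by a 3×3 block,
passed through single-head scaled dot-product self-attention over the
flattened positions (embedding width 223), projected to one channel and
squashed by a sigmoid. The deepest level is multiplied by the (resized)
guidance map before refinement; a `use_dfg=False` ablation replaces the map
by the constant ½.

**Guided cross-scale fusion (DFGF).** Decoding is progressive, deep to
shallow. At level i the refined deeper output is upsampled and expanded to
2C′ (F_h), the level feature is expanded to 2C′ (F_l), and their
concatenation is gated by σ(F_DFG) + 1 ∈ (1, 2) — the +1 preserves the
original signal if the guidance is uninformative — then reduced to 2C′
(F_GA). Broadcast channel means of F_h and F_l are concatenated with F_GA
(6C′); a shared bottleneck perceptron (reduction 32) applied to the
channel-wise max- and average-pooled vector, summed, yields the channel
attention, which is sigmoid-activated, projected 6C′→2C′, used to gate both
F_l and F_h, and the gated sum is projected back to C′. The 6C′→2C′
projection closes a dimensional gap the compact description leaves open;
it is one consistent reading and is flagged as such.

**Feature refinement (FR).** A lightweight grouped attention block applied
to all four levels: channels split into 4 groups, each passing a depthwise
3×3 convolution and a channel gate (global average pool → 1×1 → sigmoid),
re-concatenated and added residually.

**Change head.** Each refined level is 1×1-projected to a common width
(264), bilinearly upsampled to stride 4, summed, passed through a 3×3 block
and a 1×1 classifier to 2 channels, and upsampled ×4 to full-resolution
logits. Predictions are the per-pixel argmax; no threshold is involved.

All upsampling is bilinear with `align_corners` semantics off; convolutions
are followed by batch normalization and ReLU unless a sigmoid is specified.

### Width choices and complexity accounting

The architecture description leaves several widths open (excitation branch
width, channel-attention bottleneck, self-attention embedding, decoder
width, and the two published fusion variants). These were fixed once so that
the default model's complexity matches its published figures — 38.09 M
parameters and 12.84 G MACs for one bi-temporal forward at 256×256 (both
siamese streams, single-count multiply-accumulate convention: convolutions,
linear layers and attention matrix products count; normalization,
activations, pooling and resampling do not) — and are frozen in
`ModelConfig`: dilated-convolution fusion, excitation hidden width 8,
channel-attention reduction 32, attention width 223, decoder width 264.
With the same head, the 34-layer variant lands on 17.68 G MACs and 48.20 M
parameters; the published 48.21 M is internally inconsistent with the
published parameter delta by 0.012 M, so both absolutes cannot hold at
once. The counter measures a real forward pass, so the report reflects
exactly the executed operations.

## Loss

Changed pixels are a small minority, so the objective mixes a focal term,
which down-weights easy pixels by (1 − p̂)^γ with p̂ the predicted
probability of the true class (clamped to [ε, 1−ε], ε = 1e−7), and a soft
dice term on the change-class probability, 1 − (2Σep + ε)/(Σe + Σp + ε).
The focal term is averaged over pixels so the loss is resolution-invariant.
Two published parameterizations disagree: the methods description states
α = 0.2, γ = 2 with unit mixture weights, while the implementation details
state γ = 0, α disabled, weights 0.5/0.5. Both ship as named presets
(`paper-methods`, the default, and `paper-implementation`); the
contradiction is surfaced rather than silently resolved.

## Training protocol

SGD with momentum 0.9, weight decay 5e−5, initial learning rate 0.05
decayed ×0.1 every 50 epochs, 200 epochs, batch size 8 (4 at 512 px), all
randomness from one recorded seed; augmentation applies the same geometric
transform jointly to both images and the mask (right-angle rotation with
p = 0.15, vertical flip p = 0.3, horizontal flip p = 0.5 — right angles
avoid mask resampling). The best-validation-F1 parameter set is kept. The
multi-seed protocol re-runs with seeds (1234, 2345, 3456, 4567, 5678) and
reports mean ± sample standard deviation.

Evaluation accumulates TP/FP/FN/TN over a whole split (micro-averaging;
per-image averaging by flag) and derives Pre, Rec, F1 = 2·Pre·Rec/(Pre+Rec)
and IoU = TP/(TP+FP+FN), which satisfy F1 = 2·IoU/(1+IoU). Degenerate
conventions: an image with no positives anywhere scores 1; otherwise a
vanishing denominator with TP = 0 scores 0. Error maps color pixels white
(TP), black (TN), red (FP), green (FN).

## Numerical engine

The package runs on its own compact reverse-mode autodiff engine
(`tidalcd.nn`) over numpy float32: convolution via im2col and BLAS matmul
(with the transpose trick for input gradients), composite batch
normalization, dense separable matrices for bilinear resampling, an
orthonormal one-level Haar pair whose backward is its own inverse, and
tape-based backpropagation. Every primitive is verified against
finite-difference gradients and, for convolution, against an independent
scipy correlation oracle. Given a seed, runs are bit-reproducible on a
fixed BLAS configuration.

## Synthetic tidal scenes

Each tile derives from a band-limited random height field tilted toward a
shoreline. Pixels below the epoch's tide level render as water (depth-graded
blue-grey with sparse sun glint); recently exposed mud is darkened (wet
band), and patchy algal films — green-tinted, tide-following — appear on
the exposed flat. Mangrove stands are smooth random polygons (radius
modulated by low-order harmonics) with textured green fill, placed without
overlap on ground that stays dry at high tide; a `change_rate` fraction of
stands exists in exactly one epoch, and only those pixels are labeled.
Independent illumination noise (gain jitter plus per-pixel Gaussian noise)
is added per epoch.

Defaults (256-px tiles, 6 stands, tides 0.35/0.55, change rate 0.3, noise
0.03) give ≈5 % labeled pixels, and unlabeled differing pixels outnumber
labeled ones by well over 2:1. The palette is deliberately chosen so that
water-vs-mud contrast is at least as strong as canopy-vs-mud contrast:
a single |T1−T2| threshold then cannot separate tidal pseudo-change from
structural change, which is the failure mode the dual-stream design
addresses. What the generator does *not* model: sensor PSF and radiometric
calibration, georeferencing and registration error, species and seasonal
spectral variation, and partial-stand degradation (whole-stand
appearance/disappearance only; partial erosion is left as an extension).
Tests passing on these scenes therefore demonstrate correct mechanics and
the intended inductive bias, not field-ready accuracy on real imagery.

## Scaled-down verification runs

The published benchmark scores require hours of GPU training on datasets
that are not redistributable, so the test suite verifies the
architecture-intrinsic numbers exactly and the learning behavior at CPU
scale. The learning check trains the full model (stage widths scaled to
{16, 32, 64, 128}) and its no-guidance ablation on 96 synthetic 64-px pairs
(16 validation, 32 test; seed 1234) for 40 epochs with the learning-rate
step scaled proportionally (12), selecting the best-validation-F1
checkpoint, and requires the full model to clear F1 0.70 while strictly
beating both the fitted image-difference threshold and the ablation. Under
these conditions the margins are stable across 30/40/50-epoch runs. A
separate memorization smoke test overfits eight tide-stable 128-px pairs to
F1 ≥ 0.95 in 60 epochs.

## Known limitations

- No pretrained encoder weights: published-scale accuracy on real datasets
  additionally reflects ImageNet initialization, which the package does not
  reproduce.
- The numpy engine is single-device and orders of magnitude slower than a
  compiled framework; full-width training runs are impractical, though
  full-width forward passes (used by the complexity counter and shape
  checks) take only seconds.
- The Eq.-level reading of the 6C′→2C′ channel-attention projection, the
  channel-exchange mask, and the wavelet-convolution internals are
  documented interpretations of a compact architecture description; other
  consistent readings exist.
- Bit-exact reproducibility holds per BLAS configuration; different thread
  counts can reorder reductions.
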