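# Methods

This note records the modelling choices, defaults and limitations behind
`timnet`, in the spirit of a model-documentation page: what the code
computes, which knobs matter, and what the tests do and do not establish.

## Numerical core

All layers run on `timnet.grad`, a tape-based reverse-mode autodiff engine
over numpy float32 arrays. Convolution is im2col plus one GEMM; its
backward pass scatters the column gradient with a loop over kernel
offsets. Max-pooling routes gradients to the first maximal element of each
window. Bilinear resizing (decoder upsampling and side-output heads) is a
pair of precomputed row/column interpolation matrices (half-pixel-centre
convention, `align_corners` off), so its backward pass is the exact
transpose. Binary cross-entropy is computed on logits in the stable
`max(z,0) − z·t + log(1+e^(−|z|))` form. Every operation is verified
against central finite differences in the test suite.

## Architecture

Four encoder levels with channel widths `b, 2b, 4b, 8b`. The default base
width is **b = 16**: the package's reference configuration is deliberately
desk-scale, so that a from-scratch training run finishes in minutes on a
single CPU core while every architectural element is exercised; wider
models (e.g. `base_channels=32`) are one config field away and change no
code path. Each stage is two 3×3 convolutions with rectified-linear
activations; no normalisation layers are used in the convolutional trunk.

**Multiscale input (M-Net mode).** The input is max-pooled into a pyramid
at scales 1, 1/2, 1/4, 1/8. Stage *k* ≥ 2 consumes the channel
concatenation of (a) the pooled previous stage and (b) one 3×3
convolution of pyramid level *k*. `backbone_kind="unet"` disables the
pyramid branch and reproduces the plain U-Net encoder used as the ablation
baseline.

**Dual attention** sits behind the deepest encoder stage. The 1×1
convolution entering the block preserves the channel count, so the
residual addition is well-typed. The channel-attention MLP is bias-free by
default (the gating is a pure `W1·relu(W0·v)` composition; a bias flag
exists), with reduction ratio `r = 16` validated to divide the bottleneck
width. Channel pooling for the spatial branch is per-pixel mean and max
across channels; the 7×7 convolution uses padding 3.

**Transformer skip.** The grid is fixed at 4×4 = 16 patches; patch
vectors are the channel-major ravel of each block, projected by a
bias-free matrix of shape `(P·P·C) × D`. Defaults `n = 2` layers,
`D = 128`, `h = 4` heads; head width is `D/h`, the MLP hidden width `4D`
with GELU, layer-norm epsilon `1e−5`, pre-norm placement (normalisation
inside the residual branch). Position embeddings are learned parameters,
initialised from N(0, 0.02²) with the model seed. Because the patch
projection is not invertible, the return path is a learned inverse
projection `D → P·P·C` per token followed by spatial reassembly. The
refined map *replaces* the raw skip features by default (a concatenation
mode exists on the module). The transformer can be placed at any subset of
levels {2, 3, 4}; level 4 re-encodes the deepest map *before* the
dual-attention block, levels 2–3 re-encode the corresponding lateral
skips. The default placement is level 2 only, the strongest single
position in the ablation study.

**Decoder and side outputs.** The bottleneck passes one convolution block,
then three up-concat-conv stages mirror the encoder. Each of the four
decoder stages emits a side head: 1×1 convolution, bilinear upsampling to
full resolution, sigmoid. Side5 is the coarsest stage, Side8 the finest —
this ordering (coarse→fine) is a documented interpretation of the side
numbering. SideOut fuses *probabilities*, not logits, with convex weights;
the default is the tuned (0.10, 0.25, 0.25, 0.40), the equal scheme
(0.25×4) being one config away.

## Training

Adam (β = 0.9/0.999), learning rate 0.0015, batch size 2, both taken from
the published recipe; epoch count is configurable. The loss is the
α-weighted sum of per-side pixel-mean BCEs computed on logits; gradients
from all four heads flow into the shared trunk, which the test suite
checks directly. Sample order is shuffled per epoch from the training
seed; with a fixed seed two runs produce bit-identical loss curves on one
device. A non-finite loss aborts with a diagnostic rather than continuing.

Images are normalised to [0, 1] and, when grayscale, replicated to three
channels; no green-channel extraction, CLAHE or other photometric
preprocessing is applied — resizing is the only preparation step.
Input rasters are resized with bilinear interpolation, masks and FOV with
nearest-neighbour (binarity-preserving, threshold 127/255). The network
requires the input side to be divisible by 32 so the deepest map still
splits into the 4×4 patch grid.

## Metrics

Confusion counts pool over all evaluated pixels of a dataset (micro
pooling); restricting to the field of view is optional and off by default.
The binarisation threshold is 0.5. AUC is the rank-statistic area under
the ROC curve (tie-corrected, via scikit-learn); the test suite
cross-checks it against an independent Mann–Whitney pair-counting oracle.
Ratios with empty denominators (e.g. sensitivity on a vessel-free image)
are reported as `None`, never coerced to 0. Ablation improvements are
plain row differences of a results table, averaged over datasets; the
packaged CSV transcribes the published coarse-grained ablation results of
TiM-Net on DRIVE, CHASEDB1 and STARE. Note that differencing that table
gives a mean sensitivity gain of dual attention over the U-Net baseline of
0.0460 across the three datasets; the package always reports the value
recomputed from the table.

## Synthetic phantoms

The generator emulates only the geometry that the pipeline depends on: a
centred circular field of view of radius 0.48·size, a brighter disc with a
smooth radial falloff and low-frequency texture, and dark branching vessel
trees. Trees grow as random walks from the disc margin (heading jitter up
to ±25° per step, branch separation ≈ 35°, width multiplied by
`width_decay` at each bifurcation — fixed conventions, not fitted to
data), rasterised with a soft brush and thresholded at 0.5 coverage; the
brush radius is floored at 0.8 px so each tree stays 8-connected after
thresholding. Defaults (size 64, 3 trees, root width 2 px, decay 0.85,
contrast 0.5, noise σ 0.02) yield a vessel density of roughly 4–14% of the
FOV, in the range of real fundus photographs.

What the phantoms do **not** model: optic disc and macula, lesions,
colour, non-uniform illumination fields, inter-image variability of real
cameras, and annotation noise. Consequently, passing the learnability
check (a from-scratch network overfits one phantom to Dice ≥ 0.9) shows
the architecture, gradients and training loop are sound — it says nothing
about segmentation accuracy on real retinas, which requires training on
DRIVE/STARE/CHASEDB1 at full resolution.

## Problem sizes and tolerances

The reference experiments run at input 64×64 with base width 16
(~1.8 M parameters) — sizes chosen so the full suite and the reproduction
script each complete in minutes on a single core. Oracle-equivalence
tests use feature maps up to 8×8 and 100 random instances per primitive
at 1e−5 absolute tolerance; finite-difference gradient checks use 1e−6.
The overfit experiment trains 300 epochs; its loss-monotonicity check
averages over 10-epoch windows with a 2%-of-initial tolerance, since Adam
on a single sample is not strictly descending step to step.

## Known limitations

- Single-image batches are processed sequentially (gradient accumulation),
  so large batches gain no vectorisation.
- The per-layer channel widths of the original figure are not recoverable
  from text; the doubling scheme here is the standard convention.
- Checkpoints store raw float32 arrays keyed by attribute path; renaming
  modules invalidates old checkpoints (detected, with a clear error).
- No GPU path, no patch-tiling inference, no test-time augmentation.
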