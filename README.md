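# timnet

Retinal vessel segmentation with **TiM-Net** — an M-Net-style multiscale
encoder/decoder extended with a dual channel/spatial attention bottleneck,
a vision-transformer re-encoder inside the skip connections, and four
weighted deeply-supervised side outputs.

Vessel morphology in fundus photographs is a clinical window onto
cardiovascular and cerebrovascular disease, and pixel-accurate vessel maps
are the substrate for that reading. This package is for researchers and
students who want a fully inspectable, CPU-friendly implementation of the
TiM-Net architecture: every layer — convolution, attention, transformer,
and the training loop itself — runs on a small, self-contained numpy
reverse-mode autodiff core (`timnet.grad`), so the whole computation can
be stepped through, unit-tested and cross-checked against straight-line
oracles. A seeded phantom generator supplies fundus-like test images, so
nothing needs to be downloaded; the DRIVE / STARE / CHASEDB1 folder layout
is supported for real data.

## The model

Let `x` be the input image resized to a square raster. The encoder sees a
max-pooled image pyramid at scales 1, 1/2, 1/4, 1/8; stage *k* consumes the
pyramid level alongside the pooled previous stage (M-Net convention).

**Dual attention** refines the deepest feature map `G`. With
`F = conv1x1(G)`:

```
F_c = σ( W1 relu(W0 avgpool(F)) + W1 relu(W0 maxpool(F)) )      (C×1×1)
F_s = σ( f7×7([avgpool_c(·) ; maxpool_c(·)]) )                  (1×H×W)
F'  = F + (F ⊙ F_c) ⊙ F_s(F ⊙ F_c)
```

where `W0 ∈ ℝ^(C/r×C)`, `W1 ∈ ℝ^(C×C/r)` are shared between the pooled
branches and `r` is the reduction ratio.

**Transformer skip.** A skip feature map is cut into a 4×4 grid of 16
patches `p^i`, embedded as `z_0 = [p^1X; …; p^16X] + X_pos`, and passed
through `n` pre-norm layers

```
z' = MSA(LN(z)) + z,     z = MLP(LN(z')) + z'
```

with scaled-dot-product multi-head self-attention; a learned inverse
projection reassembles the tokens into a map of the original shape.

**Deep supervision.** Each decoder stage emits a full-resolution sigmoid
side output (Side5 coarsest … Side8 finest). Training minimises

```
L = Σ_i α_i L_i ,   Σ α_i = 1
```

with per-side binary cross-entropy and tuned weights
α = (0.10, 0.25, 0.25, 0.40); the deployable prediction is either the
Side7 map (`variant="side7"`) or the SideOut convex fusion
(`variant="sideout"`). Evaluation reports Acc = (TP+TN)/total,
Se = TP/(TP+FN), Sp = TN/(TN+FP) and ROC-AUC, with vessel as the positive
class.

## Worked example

Train the default network on one synthetic phantom and evaluate it against
the phantom's own mask:

```python
import numpy as np
import timnet as tn

ph = tn.generate_phantom(tn.PhantomParams(size=64, seed=7))
image = np.repeat(ph.image[None], 3, axis=0).astype(np.float32)

net = tn.NetworkConfig(seed=7)            # M-Net + dual attention + level-2 transformer
opt = tn.TrainConfig(epochs=120, seed=7)  # lr 0.0015, batch size 2, Adam
result = tn.train([(image, ph.mask)], net, opt)

prob, mask = tn.predict(image, result.model, variant="sideout")
report = tn.evaluate(prob, ph.mask, fov=ph.fov)
print(f"final loss {result.history[-1]['loss']:.4f}")
print(f"Dice {tn.dice(mask, ph.mask):.4f}")
print(f"Acc {report.acc:.4f}  Se {report.se:.4f}  Sp {report.sp:.4f}  AUC {report.auc:.4f}")
```

prints (a couple of minutes on one CPU core):

```
final loss 0.0431
Dice 0.9873
Acc 0.9977  Se 0.9964  Sp 0.9978  AUC 0.9999
```

The loss is the weighted sum of the four side cross-entropies after 120
epochs of overfitting a single image; Dice and Acc/Se/Sp/AUC measure how
completely the network has memorised the vessel tree — the learnability
check for the architecture, not a generalisation claim.

The same pipeline is available from the shell:

```
timnet simulate --out ds --n 8 --size 64 --seed 7
timnet train --data ds --checkpoint model.npz --epochs 40 --seed 7
timnet predict --checkpoint model.npz --image ds/images/phantom_000.png \
               --out-prob prob.png --out-mask mask.png
timnet evaluate --pred-dir preds --gt-dir ds/masks --fov-dir ds/fov
timnet ablate --metric Se --from Backbone1 --to Backbone1+DA \
              --datasets DRIVE,CHASEDB1,STARE
```

The `ablate` command differences rows of a results CSV
(`dataset,config,Acc,Se,Sp,AUC`); without `--table` it uses the packaged
transcription of the TiM-Net coarse-grained ablation study on DRIVE,
CHASEDB1 and STARE.

Real datasets use the same folder layout: `images/`, `masks/` and
optionally `fov/`, matched by file stem, any of PNG/TIFF/JPEG.

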