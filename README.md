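# plaquenet

Joint semantic segmentation and size regression of carotid plaques in
B-mode ultrasound, exercised end-to-end on a bundled synthetic phantom
generator.

## The problem

Carotid atherosclerotic plaque is routinely characterized on ultrasound by
its outline and by two caliper measurements, the **long and short
diameters** (mm). Automating both is hard for the same reasons manual
reading is: intense multiplicative speckle, low plaque/background
contrast, blurred edges, and acoustic shadowing below calcifications.
`plaquenet` implements a dual-branch network, **DualPlaqueNet**, that
couples the two tasks over one shared encoder:

* a U-Net-style encoder–decoder with skip connections produces per-pixel
  class scores (background / plaque);
* a regression branch reads the bottleneck features through global average
  pooling and two fully-connected layers and outputs the two diameters.

Every encoder stage ends in an **efficient channel attention (ECA)** block
whose channel weights come from a *stack* of 1-D convolutions over the
globally pooled channel descriptor (with a rectifier between layers),
rather than the single convolution of the original ECA design.

Training minimizes the weighted joint loss

```
L = α · L_seg + β · L_size
```

with `L_seg` the mean per-pixel softmax cross-entropy and `L_size` the
mean squared error of the two diameters; `α, β` are either fixed or
learned through homoscedastic-uncertainty balancing.

Evaluation uses the standard segmentation algebra over pooled confusion
counts — Accuracy, MIoU (background included), IoU excluding background,
Dice = 2TP/(2TP+FP+FN) — and MSE / MAE / R² per diameter. A
**segment-then-measure baseline** (same trunk, no attention, no regression
branch, diameters read off the predicted mask by maximum-Feret caliper
morphometry) provides the comparison arm for size prediction.

Because clinical data cannot ship with the package, a **phantom module**
generates B-mode-like images with exactly known masks and diameters:
elliptical plaques at a small intensity offset over the vessel background,
Gaussian edge blur, unit-mean Gamma speckle (`looks` L, variance 1/L), and
occasional hypoechoic shadow bands. The whole pipeline — generation, 7:1:2
split, ×8 augmentation (elastic / rotate / scale / flip), training with
best-on-validation checkpointing and early stopping, repeated evaluation
with mean ± std aggregation — runs from these phantoms.

The network itself (convolutions, batch norm, pooling, transposed
convolutions, the ECA stack, Adam, and all gradients) is implemented in
NumPy inside `plaquenet.nn` and verified against finite differences, so
the package has no deep-learning-framework dependency and runs on one CPU.

## Worked example

```python
from pathlib import Path
from plaquenet.protocols import build_smoke_dataset, smoke_train_config
from plaquenet.harness import train_once, evaluate

man = build_smoke_dataset(Path("scratch/demo"), seed=1)   # 160 phantoms, 7:1:2, x3 augment
cfg = smoke_train_config(seed=1, epochs=10)               # depth-3 trunk, Adam lr 1e-3
res = train_once(man, cfg)
rep = evaluate(res, man, cfg, split="test")
print(f"Dice {rep.seg.dice_pct:.1f}%  MIoU {rep.seg.miou_pct:.1f}%  "
      f"ACC {rep.seg.accuracy_pct:.1f}%")
print(f"long diameter:  R2 {rep.reg_long.r2:.2f}  MAE {rep.reg_long.mae:.2f} mm")
print(f"short diameter: R2 {rep.reg_short.r2:.2f}  MAE {rep.reg_short.mae:.2f} mm")
```

prints (seed 1, one CPU, ~90 s):

```
Dice 91.9%  MIoU 91.6%  ACC 98.3%
long diameter:  R2 0.81  MAE 0.32 mm
short diameter: R2 0.80  MAE 0.25 mm
```

i.e. the predicted plaque outline overlaps the true mask at Dice ≈ 92%,
and the regressed long diameter explains ≈ 81% of the true variance with a
mean error of ≈ 0.3 mm (2.7 pixels at the phantom's 0.12 mm/px spacing).

A CLI mirrors the library:

```bash
plaquenet generate --n 160 --out data/ --seed 1
plaquenet split --manifest data/manifest.csv --ratios 7 1 2 --seed 1
plaquenet augment --manifest data/manifest.csv --variants 7 --seed 1
plaquenet measure --mask data/masks/phantom_00000.png --spacing 0.12
```

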