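# unifocal

Loss functions for class-imbalanced semantic segmentation, implemented in
numpy, culminating in the symmetric and asymmetric **Unified Focal losses** —
a three-parameter family that generalises the cross entropy, Focal, Dice,
Tversky, Focal Tversky, Combo and Hybrid Focal losses.

Medical segmentation targets (polyps, vessels, tumours) routinely occupy a few
percent — sometimes 0.2% — of an image. Under that imbalance the choice of
training loss decides whether a model learns the rare class at all, and
whether its errors skew toward false positives or false negatives. The package
provides:

- **distribution losses** — cross entropy; Focal loss
  `α_t (1−p_t)^γ · (−log p_t)`; the modified Focal loss (single δ class
  weight); the asymmetric variant that exempts the rare class from focal
  suppression;
- **region losses** — soft Dice `2TP/(2TP+FP+FN)`; Tversky index
  `TP/(TP + α·FP + β·FN)`; Focal Tversky `(1−TI)^{1/γ}`; the modified and
  asymmetric Focal Tversky losses of the Unified family;
- **compound losses** — Combo (`α·L_mCE − (1−α)·DSC`), Hybrid Focal
  (`λ·L_F + (1−λ)·L_FT`) and the Unified Focal losses

  `L_sUF = λ·L_mF(δ, γ) + (1−λ)·L_mFT(δ, γ)`
  `L_aUF = λ·L_maF(δ, γ) + (1−λ)·L_maFT(δ, γ)`

  with recommended defaults λ = 0.5, δ = 0.6, γ = 0.5, leaving γ the single
  hyperparameter to tune;
- **hard metrics** (DSC, IoU, recall, precision, per image and per class),
  a **seeded synthetic generator** of imbalanced 2-D/3-D tasks with
  controllable foreground prevalence, a built-in **autodiff backend** (so all
  losses have exact gradients and a tiny convolutional segmenter can be
  trained end-to-end on CPU), and a **benchmark harness** with a thin CLI.

Every reduction arrow in the loss hierarchy (Focal→CE at γ=0, Focal
Tversky→Tversky at γ=1, Tversky→Dice at α=β=0.5, Unified Focal→Dice /
½·CE at the corner settings, …) is verified numerically by
`verify_reductions`.

## Worked example

```python
import numpy as np, unifocal as uf

# ground truth: 4 foreground pixels out of 16; prediction: 0.5 everywhere
p = np.full((1, 4, 4, 2), 0.5)
labels = np.zeros((1, 4, 4), dtype=int); labels[0, 0, :] = 1
y = uf.one_hot_encode(labels, 2)

uf.soft_dice(p, y).per_class[0, 1]              # 0.3333  (tp=2, fp=6, fn=2)
uf.tversky_index(p, y, 0.3, 0.7).per_class[0, 1]  # 0.3846
uf.modified_tversky_index(p, y, 0.6).per_class[0, 1]  # 0.3125
uf.unified_focal_asymmetric(p, y, lam=0.5, delta=0.6, gamma=0.5).value  # 0.7276
```

The first three numbers are the soft overlap scores of the foreground class
under increasingly asymmetric false-positive/false-negative weighting; the
last is the full compound loss (distribution + region component) for the
batch. Training gradients come from the same functions:

```python
value, grad = uf.value_and_grad(uf.unified_focal_asymmetric, p, y)
```

The `examples/` directory contains one short script per capability (losses on
a toy batch, hierarchy verification, synthetic tasks, metric reports, loss
landscapes, a mini training benchmark). The harness is also exposed as a CLI:

```bash
unifocal verify-hierarchy --trials 100 --seed 17
unifocal landscape --losses modified_focal,modified_focal_tversky --grid 200 --out curves.csv
unifocal make-data --fraction 0.01 --n 50 --shape 64x64 --seed 42 --out data/
unifocal bench --loss cross_entropy --loss unified_focal_asym --imbalance 0.01 --out runs/
```

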