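"""Evaluate the whole loss family on one small imbalanced batch.

Builds a 2-image, 16x16 binary batch with ~5% foreground and prints every
loss at its published operating point.  Distribution losses (cross entropy
family) average per-pixel log terms; region losses sum (1 - overlap score)
over the two classes, so their scale is roughly [0, 2]; the Combo loss can be
negative because it subtracts a similarity.
"""

import numpy as np

import unifocal as uf
from unifocal import LossSettings

task = uf.generate(n_images=2, shape=(16, 16), target_fraction=0.05, seed=3)
y = uf.one_hot_encode(task.masks, 2)

# a deliberately imperfect "prediction": the truth blurred toward uncertainty
p = 0.7 * y + 0.3 * np.full_like(y, 0.5)

rows = [
    ("cross entropy", uf.cross_entropy(p, y)),
    ("Focal (a=0.25, g=2)", uf.focal_loss(p, y, 0.25, 2.0)),
    ("Dice", uf.dice_loss(p, y)),
    ("Tversky (0.3, 0.7)", uf.tversky_loss(p, y, 0.3, 0.7)),
    ("Focal Tversky (g=4/3)", uf.focal_tversky_loss(p, y, 0.3, 0.7, 4 / 3)),
    ("Combo (a=0.5, b=0.5)", uf.combo_loss(p, y, 0.5, 0.5)),
    ("Hybrid Focal", uf.hybrid_focal_loss(p, y, LossSettings(alpha=0.25))),
    ("Unified Focal (sym)", uf.unified_focal_symmetric(p, y)),
    ("Unified Focal (asym)", uf.unified_focal_asymmetric(p, y)),
]
print(f"foreground fraction: {task.realized_fraction:.3f}")
for name, value in rows:
    print(f"{name:24s} {value.value: .4f}")
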