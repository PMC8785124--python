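"""Hard-metric evaluation of a deliberately imperfect prediction.

Erodes the true mask (misses boundary pixels -> false negatives) and adds a
spurious region (false positives), then prints per-class DSC, IoU, recall and
precision.  Note recall < precision: the erosion costs recall, the spurious
blob costs precision less because it is small.
"""

import numpy as np

import unifocal as uf

task = uf.generate(n_images=3, shape=(48, 48), target_fraction=0.10, seed=8)
preds = []
for mask in task.masks:
    pred = mask.copy()
    # erode: drop foreground pixels whose 4-neighbourhood is not all foreground
    fg = mask == 1
    interior = fg.copy()
    interior[1:, :] &= fg[:-1, :]
    interior[:-1, :] &= fg[1:, :]
    interior[:, 1:] &= fg[:, :-1]
    interior[:, :-1] &= fg[:, 1:]
    pred[fg & ~interior] = 0
    pred[:3, :3] = 1  # spurious corner blob
    preds.append(pred)

per_image = uf.evaluate_collection(preds, list(task.masks), 2)
summary = uf.summarize_collection(per_image)
print(summary.round(3).to_string(index=False))
print("\nforeground recall drops from the erosion; precision from the corner blob")
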