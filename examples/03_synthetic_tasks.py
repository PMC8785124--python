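"""Generate synthetic imbalanced segmentation tasks at dataset-like prevalences.

Each regime mimics the foreground fraction of a public benchmark family
(polyps ~9%, vessels ~9%, breast tumours ~5%, enhancing brain tumour ~0.2%);
the printed realized fraction should track the target.  The nested 3-class
mode places a rare "tumour" core inside each "organ" blob.
"""

import unifocal as uf
from unifocal.synthetic import TABLE_PREVALENCES

for name, fraction in TABLE_PREVALENCES.items():
    if name == "kidney_tumour":
        continue  # covered by the nested mode below
    task = uf.generate(n_images=4, shape=(64, 64), target_fraction=fraction,
                       seed=1)
    print(f"{name:16s} target {fraction:.3f}  realized {task.realized_fraction:.4f}")

nested = uf.generate(n_images=4, shape=(64, 64), target_fraction=0.108,
                     num_classes=3, seed=1)
organ = (nested.masks == 1).mean()
core = (nested.masks == 2).mean()
print(f"\nnested mode: organ fraction {organ:.4f}, tumour-core fraction {core:.4f}")
print("(the core is strictly inside the organ blobs, like kidney vs kidney tumour)")
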