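"""Train the tiny segmenter with different losses under severe imbalance.

Generates a 1%-foreground task, trains the tiny convolutional segmenter with
plain cross entropy and with the asymmetric Unified Focal loss (3 seeds each),
and prints foreground test metrics.  The expected pattern mirrors the
published comparisons: the Unified Focal loss holds a clear recall advantage
at this imbalance, often at similar or better DSC.

Takes a couple of minutes on one CPU.
"""

import warnings

import unifocal as uf
from unifocal import LossSettings
from unifocal.harness import results_to_frame, run_benchmark
from unifocal.model import ModelSpec

warnings.filterwarnings("ignore")

task = uf.generate(n_images=100, shape=(64, 64), target_fraction=0.01, seed=42)
splits = uf.split(task, seed=42)
results = run_benchmark(
    [("cross_entropy", None),
     ("unified_focal_asym", LossSettings(lam=0.5, delta=0.6, gamma=0.5))],
    splits, ModelSpec(epochs=12), seeds=[0, 1, 2])

frame = results_to_frame(results)
fg = frame[frame["class"] == 1]
print(fg[["loss", "seed", "dsc", "recall", "precision"]].round(3).to_string(index=False))
print("\nforeground recall: the asymmetric Unified Focal loss does not let the "
      "rare class\nbe suppressed, so its recall should exceed cross entropy's "
      "in most seeds")
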