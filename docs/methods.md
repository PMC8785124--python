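# Methods

This note documents the models, conventions and numerical choices behind the
package, the way a statistics or simulation library documents its internals.

## Data contracts

All losses operate on a probability map of shape `(batch, *spatial, C)` with
the class axis last and class 0 = background, paired with a one-hot label
array of identical shape. Binary problems are always represented as
two-channel softmax maps (C = 2), never as single-channel sigmoid maps: this
makes every loss definable once for general C and matches the softmax output
layer the losses are designed to sit behind. Probabilities must sum to one
over the class axis to within 1e−5 at the strict contract level; the guard
inside the losses uses a looser 1e−3 so that already-clipped maps remain
valid inputs.

Hard binarization is argmax over channels with ties broken toward the lower
class index. For C = 2 softmax maps this coincides with a 0.5 threshold on
the foreground channel, which is why the metrics only implement argmax.

## The loss family

Write `p_t` for the probability assigned to the true class at a position, and
per class c let `tp = Σ p·g`, `fp = Σ p·(1−g)`, `fn = Σ (1−p)·g` be the soft
confusion terms (g the one-hot truth). The implemented family:

| loss | per-position / per-class term |
|---|---|
| cross entropy | `−log p_t` |
| Focal | `α_t (1−p_t)^γ (−log p_t)` |
| modified Focal | `δ_t (1−p_t)^γ (−log p_t)`, δ on foreground, 1−δ on background |
| asymmetric Focal | rare class: `δ(−log p_t)`; others: `(1−δ)(1−p_t)^γ(−log p_t)` |
| soft Dice | `(2tp+ε)/(2tp+fp+fn+ε)` |
| Tversky index | `(tp+ε)/(tp+α·fp+β·fn+ε)` |
| Focal Tversky | `(1−TI)^{1/γ}` |
| modified Focal Tversky | `(1−mTI)^{1−γ}` with `mTI = TI(α=δ, β=1−δ)` |
| asymmetric Focal Tversky | rare: `(1−mTI)^{1−γ}`; others: `(1−mTI)` |
| Combo | `α·mCE − (1−α)·DSC_fg`, mCE weighting foreground by β |
| Hybrid Focal | `λ·Focal + (1−λ)·Focal Tversky`, each with its own parameters |
| Unified Focal (sym/asym) | `λ·(modified/asymmetric Focal) + (1−λ)·(modified/asymmetric Focal Tversky)` |

Aggregation: distribution losses average over positions within an item;
region losses are computed per item and summed over the class set (all C
classes by default, background included; a foreground-only mode is available
because binary practice varies). The batch aggregate is always the mean over
items, reported together with the per-item values.

### Exponent and δ conventions

Two conventions in the Unified family are genuinely ambiguous in the
literature, and the package fixes them as follows:

- **Focal-side exponent γ, Tversky-side exponent 1−γ.** This is the unique
  assignment under which γ = 0 simultaneously recovers the δ-weighted cross
  entropy and the Tversky(δ) loss — the reduction property the framework is
  built on — while a single γ ∈ [0, 1) suppresses easy background terms on
  the cross entropy side and enhances rare-class terms on the Tversky side.
  The alternative printed forms (exponent 1−γ on the Focal side, γ on the
  Tversky side) are available behind `literal=True` flags; they break the
  γ = 0 reductions and are not used elsewhere.
- **δ multiplies the false-positive term of the modified Tversky index**
  (`mTI = TI(α=δ, β=1−δ)`), matching the index formula this family is defined
  by and the worked values the implementation is tested against. Note the
  consequence for direction-of-effect: on a foreground class with fp > fn the
  region loss increases with δ, with fn > fp it decreases. On the
  cross entropy side δ > 0.5 up-weights rare-class positions, which is what
  drives the recall advantage observed in the benchmark. Users who want the
  opposite region-side weighting can call `tversky_loss(alpha=1−δ, beta=δ)`
  directly.
- The asymmetric Focal loss applies `log` of each position's own true-class
  probability in both terms (the rare and non-rare sums differ only in
  weighting and modulation).
- The Unified Focal loss recovers the cross entropy at λ = 1, γ = 0, δ = 0.5
  only up to the factor δ = 0.5; the scale factor is inherent to any
  consistent reading and is asserted as `0.5 × CE` in the hierarchy checks.

### Defaults

δ = 0.6, γ = 0.5, λ = 0.5 for the Unified losses; α = 0.25, γ = 2 for the
Focal loss; α = 0.3, β = 0.7 (γ = 4/3) for the (Focal) Tversky loss;
α = β = 0.5 for Combo — the operating points recommended in the literature
this family comes from. ε = 1e−6 is the package's own smoothing constant: it
clips probabilities before any logarithm and is added to numerator and
denominator of every ratio score, so empty classes score 1 instead of 0/0 and
no input can produce a non-finite loss. When a fractional exponent e < 1 is
applied to `1 − score`, the base is floored at 1e−12: at exact perfection the
derivative of `x^e` diverges, and the floor trades an O(1e−9) bias in an
already-zero loss for a finite gradient.

## Gradients

There is no deep-learning framework in the dependency set; instead the
package carries a small vectorized reverse-mode autodiff core
(`unifocal._backend`). Losses are written once against a dispatch layer and
therefore run identically on numpy arrays (returning a `LossValue`) and on
`Tensor` nodes (returning a differentiable scalar). `value_and_grad` exposes
exact gradients with respect to the probability map; the test suite checks
them against central finite differences (step 1e−5, relative tolerance 1e−4)
for every loss, and checks that saturated 0/1 inputs yield finite values and
gradients (the clip means such entries get zero gradient, which is the
documented cost of log-safety).

## Synthetic tasks

The generator emulates the prevalence regimes of public medical segmentation
datasets — roughly 9% foreground (polyps, vessels), 5% (breast tumours),
0.2% (enhancing brain tumour), and a nested 10.8%/0.2%-style organ/tumour
pair — without downloading data. Foreground objects are soft-edged,
axis-aligned random ellipses/ellipsoids (1–3 per image, volume-neutral random
eccentricity in [0.7, 1.4]); a per-image feedback loop rescales the common
size so the realized foreground fraction tracks the target (±25% per batch is
the contract; exact matching is over-constrained for random placement). The
image is `contrast · soft_mask + N(0, noise_sd)` min-max normalised to
[0, 1], defaults contrast 1.0 and noise 0.3 — a moderate signal-to-noise
ratio at which per-pixel classification is possible but boundary pixels are
genuinely ambiguous, so different losses reach different recall/precision
trade-offs. Everything is bit-reproducible per seed.

What the generator does *not* emulate: scanner-specific appearance (MRI
sequences, CT Hounsfield clipping), anatomy-shaped objects, correlated noise,
annotation error, or data augmentation. Passing benchmarks on these tasks
therefore demonstrates the *relative* behaviour of the losses under
controlled imbalance, not absolute performance on real scans.

## The tiny segmenter and benchmark

The benchmark model is a three-layer 3×3 convolutional softmax segmenter
(1 → 8 → 8 → C channels, ~3k parameters) with parameter-free instance
normalisation after the hidden layers, trained by plain SGD (lr 0.1, batch 8)
with reduce-on-plateau decay, early stopping on validation loss, and
selection of the best-validation weights. Instance normalisation is
essential, not cosmetic: without it the softmax saturates toward the majority
class within the first epoch at 1% foreground and every gradient path dies.
The model runs in float32; the loss contracts are tested in float64.

Desk-scale problem sizes were chosen once: 200 images at 64×64 for the
imbalanced benchmark (split 64/16/20% train/val/test), 12 training epochs,
10 model seeds for the cross entropy vs asymmetric Unified Focal recall
comparison, and 6 epochs × 9 γ values × both variants for the γ-stability
sweep. The easy-task sanity threshold (every loss reaches foreground DSC
≥ 0.90 on a high-contrast 10% foreground task) was fixed from pilot runs;
the plain Focal loss with α = 0.25 is reproducibly the weakest learner there,
consistent with its published behaviour, which is why the threshold is 0.90
rather than 0.95. Stochastic claims are always made over seed ensembles
(win rates), never single runs.

## Known limitations

- Only 2-D training is wired into the tiny model (the losses and generator
  are dimension-agnostic; 3-D training would need a conv3d op).
- The Combo loss extension to C > 2 (β weighting all foreground classes,
  DSC averaged over foreground) goes beyond its binary definition and is
  flagged as such.
- Metrics exclude zero-denominator classes from macro averages with a
  warning; a micro-averaged pooled mode is available but non-default.
- The landscape export presents labelled per-component curves (per-position
  terms vs `p_t`, per-class terms vs Tversky index) rather than claiming any
  specific figure's exact parameterisation.
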