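# Methods

## The activation catalogue

Every activation is an `ActivationSpec` (kind + fixed hyperparameters) plus,
for learnable kinds, per-channel parameter vectors (`ChannelParams`).
`eval_activation` and `grad_activation` implement the forward value, the
input gradient and the gradient with respect to every learnable parameter
analytically; the whole catalogue is verified against a central
finite-difference oracle (h = 1e−6 scaled by coordinate magnitude, sample
points kept ≥ 1e−3 from every non-differentiability, 50 seeded draws per
kind, relative tolerance 1e−4).

Conventions and resolutions of genuinely open choices:

* **Subgradients.** At every kink the derivative is taken from the right
  (the `x ≥ 0` branch of the ReLU family). The hat basis uses derivative
  −1 at its peak (`x ≥ a`) for the same reason.
* **APLU hinge form.** The hinge is `max(0, b_c − x)`: slopes `a_c` are
  active for `x < b_c`, matching the gradient formulas
  (d/da_c = b_c − x for x < b_c, d/db_c = a_c there) and the standard APLU
  construction. Hinge count n defaults to 5 and is configurable; hinge
  locations are initialized uniformly on (0, maxInput) from the run seed,
  since only "random" initialization is prescribed.
* **Splash.** `Splash(x) = APLU_{a⁺,b}(x) + APLU_{a⁻,b}(−x)` with hinge
  locations shared between the two branches and both slope vectors starting
  at zero, so Splash starts as |x|.
* **PDELU.** Deformation t = 0.9 (the convention of its source method);
  α initialized to 0 so the negative branch starts flat. The negative
  branch uses the truncated base `[1 + (1−t)x]₊`, making f(0) = 0 exact.
* **SRS.** α = 3, β = 2 at init (source-method defaults); both are clamped
  to ≥ 1e−6 after every update to keep them positive.
* **Soft Learnable.** The negative branch is parenthesized as
  `α·ln((1 + e^{βx})/2)`: the /2 inside the logarithm is the only reading
  that makes the function continuous at 0. `soft_learnable` fixes β = 1 and
  learns α; `soft_learnable2` learns both. Both α and β start at 1 — a
  neutral choice (slope αβ/2 = 1/2 at 0⁻) in the absence of a prescribed
  value.
* **SReLU.** Two init presets: `operational` (a_l = 0.5, a_r = 0.2,
  t_l = −2, t_r = 1.5; the default) and `zero` (a_l = 0, t_l = 0,
  t_r = maxInput, with a_r = 1 so the function equals ReLU at init). Both
  appear in the protocol this package models; the operational values are
  the ones actually used in its experiments.
* **SELU.** Included for completeness with the standard constants
  λ ≈ 1.0507, α ≈ 1.6733.
* **Mish / Swish.** `mish` fixes α = 1, `mish_learnable` learns it
  (init 1); `swish` fixes β (default 1, e.g. 50 to approximate ReLU),
  `swish_learnable` learns β from 1.
* **2D MeLU.** Output channel i consumes input channels i and i+1 with
  cyclic pairing (channel N pairs with channel 1), so output width equals
  input width. The hat argument is the Euclidean distance to the grid
  center (a_u, a_v), with half-width λ_{max(u,v)}; the coefficient grid is
  (k−1)² per channel. The gradient at the center (r = 0) is set to 0.
* **Flexible MeLU.** Hat centers are learnable, initialized at the ladder
  values; d/da_j = c_j · sign(x − a_j) on the hat support.
* **maxInput** is a pure scale: ladders satisfy
  ladder(m) = m · ladder(1) elementwise. 256 reproduces the canonical
  integer ladder, 1 the unit one; 255 is what the benchmarking experiments
  use, and all three are just arguments.

## Ladders

`build_melu_ladder(maxInput, k)` generates hats breadth-first by level:
level ℓ has half-width 2·maxInput/2^{ℓ−1} and peaks at its odd multiples.
The k = 4 ladder is a prefix of the k = 8 ladder. The GaLU ladder is
derived by halving the half-widths and shifting centers left by the new
half-width (λ′ = λ/2, a′ = a − λ/2), which is the mapping implied by the
printed GaLU parameter table; a GaLU hat then spans the same interval as
the MeLU hat it came from, with an up-triangle followed by a zero-mean
down-triangle.

## Network surgery and training

Networks are abstract `LayerGraph`s; `sample_replacement_plan` assigns pool
activations to sites either independently per site (`per_layer`, the
default) or one draw for the whole network (`per_network`). Both readings
of "randomly replacing the activations" exist in the literature this
package models; the flag selects between them. Plans serialize to YAML for
exact replay.

Training runs on `TinyNetModel`, a two-conv-block numpy CNN (3×3 conv →
activation site → 2×2 max-pool, twice, then a linear head). The backward
pass routes through the catalogue's analytic gradients — there is no
autograd involved, which is the point: a wrong hand-derived gradient shows
up immediately as failed descent or a failed finite-difference test.
The optimizer is SGD with momentum 0.9 (the standard fine-tuning default
for the ecosystem the protocol comes from; the protocol itself names only
learning rate, batch size and epochs). Default protocol constants are
batch 30, base LR 1e−4, final-layer multiplier 20, APLU penalty 0.001, and
20 epochs — 30 when the plan mixes more than one activation kind.
Augmentation applies Bernoulli(1/2) flips on both axes and two independent
axis rescales with factors uniform on [1, 2], resampled back to the
original raster by bilinear interpolation (the protocol is silent on how
rescaled images re-enter a fixed-size network; bilinear back-resampling is
this package's choice).

Desk-scale runs in the test suite train TinyNet from scratch (not from
pretrained weights), so they use a larger base LR (0.01), a 2× head
multiplier and 6–8 epochs on 140 training images — sizes chosen so a full
five-member stochastic ensemble trains in seconds on one CPU while still
exercising every code path.

## Ensembles, selection, evaluation

Sum-rule fusion averages member softmax matrices (the mean keeps rows
stochastic; the argmax is unchanged from summing). SFFS adds, at each
step, the candidate with the highest fused-accuracy gain, then conditionally
removes the member whose exclusion most improves the score, until no strict
improvement or the size cap; ties break toward the smaller ensemble, then
lexicographic order, making selection deterministic. The objective is mean
fused accuracy over one or more validation contexts (pass per-context
matrix lists for leave-one-dataset-out selection). SFFS is greedy, not
optimal: the suite compares it against the exhaustive-subset oracle on
pools of ≤ 8 and asserts only that it never falls below the best single
candidate.

Cross-validation is stratified (per-class fold sizes differ by ≤ 1) —
with per-class counts as low as 20, unstratified folds would routinely
lose whole classes from training splits. The Wilcoxon signed-rank test
drops zero differences (standard convention), uses midranks for tied
absolute differences, enumerates all 2^n sign patterns exactly for n ≤ 15,
and switches to the normal approximation with continuity and tie
correction beyond. Average ranks use midranks, so per-dataset ranks always
sum to m(m+1)/2 for m methods.

## Synthetic data

`ToySpec` generates grayscale image classes from one of three signals:
Gaussian blob position on a ring (default), sinusoid texture frequency, or
intensity-gradient direction, plus i.i.d. pixel noise of standard deviation
σ (in units of the unit signal amplitude) clipped to [0, 1]. At σ = 0 a
nearest-centroid rule on raw pixels is perfect; difficulty grows with σ.
Defaults (4 classes, 50 samples per class, 32×32, σ = 0.5) are set so the
TinyNet stack separates the classes comfortably within a few epochs on one
CPU — deliberately easy, because the ensemble-level tests are directional
(fused vs. member accuracy), not absolute.

What the toy generator does *not* emulate: the class imbalance, stain/
illumination variability, inter-dataset heterogeneity and label noise of
real microscopy or histology collections, nor anything requiring
pretrained-backbone transfer. Passing tests therefore establish the
correctness of the machinery (gradients, surgery, fusion, selection,
statistics) and the directional behavior of ensembles under controlled
conditions — not performance claims about real medical data.

## Known limitations

* `TinyNetModel` supports exactly the two-conv-block topology; adapters
  for real pretrained backbones are out of scope (no weight downloads).
* The stochastic-ensemble recipes default to 15 members in the registry
  helpers but tests use 5-member ensembles for speed.
* The exact Wilcoxon path is O(2^n) and intentionally capped at n = 15.
* 2D MeLU trains noticeably slower than the 1D kinds (its coefficient grid
  is (k−1)² per channel) and is excluded from the default stochastic pools,
  matching the protocol it models.
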