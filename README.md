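# afens — activation-function catalogues and replacement ensembles

`afens` is a numpy toolkit for studying how the choice of CNN activation
function — and ensembles built by *varying* that choice — affects
image-classification performance, a question that matters most for small to
midsize biomedical datasets (hundreds to a few thousand microscopy or
histology images), where single fine-tuned networks are noisy and ensembles
of cheaply diversified networks help.

It provides:

* **A catalogue of 25 activation functions** with exact forward values,
  input gradients and per-parameter gradients: the classics (ReLU, Leaky
  ReLU, PReLU, ELU, SELU, Swish, Mish, SReLU, APLU, PDELU, SRS, Soft
  Learnable, Splash) and the Mexican-hat ladder family — MeLU, GaLU and
  their 2D, symmetric, mixed and flexible variants.
* **Network surgery**: abstract layer graphs whose activation sites can be
  re-assigned activations, deterministically or stochastically from named
  pools, with seeded, replayable plans.
* **A desk-scale training stack**: a small numpy CNN whose backward pass
  uses the catalogue's analytic gradients, plus the benchmarking protocol
  (flip/rescale augmentation, 20× final-layer learning rate, the APLU
  slope penalty and its relative learning rate).
* **Ensemble machinery**: sum-rule fusion of softmax outputs, stochastic
  activation-replacement ensembles, named recipes (ENS, ENS_G, eENS, ALL,
  15ReLU, Stoc_1–4, …) and SFFS member selection.
* **Evaluation**: stratified k-fold protocols, accuracy, exact Wilcoxon
  signed-rank tests, and average-rank summaries.
* **Synthetic data**: seeded toy image datasets and probability-matrix
  fixtures, so everything above runs end-to-end on one CPU in seconds.

## The core model

MeLU (Mexican ReLU) augments PReLU with a fixed ladder of triangular
"Mexican hat" bumps φ_{a,λ}(x) = max(λ − |x − a|, 0):

    MeLU(x) = PReLU_{c0}(x) + Σ_{j=1}^{k−1} c_j · φ_{a_j, λ_j}(x)

The per-channel coefficients c_0, c_1, …, c_{k−1} are learned; the centers
a_j and half-widths λ_j are fixed by recursive dyadic subdivision of
[0, 4·maxInput]: the first hat peaks at 2·maxInput and vanishes at 0 and
4·maxInput, the next level halves the half-width and peaks at maxInput and
3·maxInput, and so on. Because all c_j start at zero, MeLU (and the whole
ladder/hinge family) *equals ReLU at initialization*, so it can replace the
activations of a ReLU-pretrained network without changing its function.
GaLU uses zero-mean up/down hat pairs on a derived ladder (half-widths
halved, centers shifted left by the new half-width).

Stochastic ensembles exploit this: each member network gets a random
assignment of activations from a pool, members are trained independently,
and their softmax outputs are averaged (sum rule).

## Worked example

```python
import numpy as np
from afens import build_melu_ladder, derive_galu_ladder
from afens.ensembles import sum_rule_fuse, sffs_select
from afens.evaluation import accuracy, wilcoxon_signed_rank
from afens.synthetic import make_probability_fixtures

lad = build_melu_ladder(256, 8)
print(lad.centers.tolist())      # [512.0, 256.0, 768.0, 128.0, 384.0, 640.0, 896.0]
print(lad.half_widths.tolist())  # [512.0, 256.0, 256.0, 128.0, 128.0, 128.0, 128.0]

# five synthetic classifiers with prescribed accuracies, fused by sum rule
mats, labels = make_probability_fixtures(5, 1000, 4,
                                         [0.75, 0.7, 0.7, 0.65, 0.6], seed=7)
print([accuracy(m, labels) for m in mats])   # [75.0, 70.0, 70.0, 65.0, 60.0]
print(accuracy(sum_rule_fuse(mats), labels)) # 89.1

# paired comparison of two methods across six datasets
x = np.array([91.2, 88.4, 95.0, 84.1, 90.3, 87.7])
y = x - np.array([1.1, 0.4, 2.0, 0.7, 1.6, 0.2])
print(wilcoxon_signed_rank(x, y, "greater")) # 0.015625
```

The fused accuracy (89.1%) exceeds every member (60–75%): with independent
errors, averaging softmax rows recovers the signal the members share.  The
exact one-sided Wilcoxon p-value 0.015625 = 1/64 says six uniformly
positive paired differences are what you'd see once in 64 sign patterns by
chance.

A full stochastic-ensemble experiment on a generated four-class image set:

```python
from afens import tiny_net_graph
from afens.ensembles import build_stochastic_ensemble
from afens.surgery import pool_stoc1
from afens.training import TrainConfig

graph = tiny_net_graph(n_classes=4)
cfg = TrainConfig(batch_size=30, base_lr=0.01,
                  final_layer_lr_multiplier=2.0, epochs=6, seed=1)
models, members, fused = build_stochastic_ensemble(
    graph, pool_stoc1(), n_members=5, dataset=split, config=cfg, seed=42)
```

There is also a thin CLI: `afens ladder`, `afens make-toy`, `afens fuse
--recipe ENS_G --max-input 255 --probs-dir ... --out ...`.

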