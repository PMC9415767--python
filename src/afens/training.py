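"""Fine-tuning protocol and a small numpy CNN for desk-scale experiments.

The training stack is deliberately self-contained: convolution, pooling and
the cross-entropy head are implemented directly on numpy arrays so that the
activation catalogue's hand-derived gradients (:func:`afens.activations
.grad_activation`) are exercised as the actual backward pass, not re-derived
by an autograd engine.

Protocol pieces mirror the benchmarking recipe the package models:

* augmentation = independent horizontal/vertical reflections plus two
  independent axis rescales with factors drawn uniformly from [1, 2],
  resampled back to the original raster (:func:`augment_image`);
* a per-layer learning-rate schedule where the final classifier layer trains
  at ``base_lr * final_layer_lr_multiplier`` (20x by default) and the
  APLU/Splash slope parameters at the relative rate ``base_lr / max_input``
  (:func:`build_lr_schedule`);
* an L2 penalty ``coeff * sum(a_c^2)`` on APLU/Splash slopes
  (:func:`aplu_regularization`), 0.001 by default;
* SGD with momentum 0.9; 20 epochs by default, 30 when the replacement plan
  mixes more than one activation kind (stochastic members converge slower).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image
from skimage.transform import resize

from .activations import (ActivationSpec, ChannelParams, clamp_params,
                          eval_activation, grad_activation)
from .surgery import LayerGraph, ReplacementPlan, apply_plan

__all__ = [
    "TrainConfig",
    "ImageDataset",
    "SplitDataset",
    "TinyNetModel",
    "augment_image",
    "rescale_factors",
    "build_lr_schedule",
    "aplu_regularization",
    "train_model",
    "predict_proba",
    "load_image_dataset",
]

_APLU_FAMILY_SLOPES = {"a", "a_pos", "a_neg"}


@dataclass
class TrainConfig:
    """Training protocol parameters.

    ``epochs=None`` resolves to 20, or 30 when the replacement plan contains
    more than one distinct activation kind.
    """

    batch_size: int = 30
    base_lr: float = 1e-4
    epochs: int | None = None
    final_layer_lr_multiplier: float = 20.0
    aplu_reg_coeff: float = 1e-3
    momentum: float = 0.9
    seed: int = 0
    augment: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs is not None and self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.base_lr <= 0 or self.final_layer_lr_multiplier <= 0:
            raise ValueError("learning rates and multipliers must be positive")
        if self.aplu_reg_coeff < 0:
            raise ValueError("aplu_reg_coeff must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ImageDataset:
    """Images as (N, C, H, W) floats in [0, 1] with integer labels."""

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 4:
            raise ValueError("X must be (N, C, H, W)")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")

    @property
    def n_classes(self) -> int:
        return len(self.class_names) if self.class_names else int(self.y.max()) + 1


@dataclass
class SplitDataset:
    train: ImageDataset
    test: ImageDataset


def load_image_dataset(root) -> ImageDataset:
    """Read a ``<root>/<class_name>/<sample>.png`` tree as grayscale images."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    images, labels = [], []
    for ci, cdir in enumerate(class_dirs):
        for f in sorted(cdir.glob("*.png")):
            images.append(np.asarray(Image.open(f).convert("L"), dtype=float) / 255.0)
            labels.append(ci)
    X = np.stack(images)[:, None, :, :]
    return ImageDataset(X, np.array(labels), tuple(d.name for d in class_dirs))


# ---------------------------------------------------------------------------
# augmentation


def rescale_factors(rng: np.random.Generator) -> tuple[float, float]:
    """Two independent axis rescale factors, each uniform on [1, 2]."""
    f = rng.uniform(1.0, 2.0, size=2)
    return float(f[0]), float(f[1])


def augment_image(image, seed) -> np.ndarray:
    """Random reflections on both axes plus independent axis rescales.

    Each axis is flipped with probability 1/2; then the two spatial axes are
    rescaled by independent factors uniform on [1, 2] and the result is
    resampled back to the input raster with bilinear interpolation.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rng.random() < 0.5:
        img = img[::-1, ...]
    if rng.random() < 0.5:
        img = img[:, ::-1, ...]
    fy, fx = rescale_factors(rng)
    h, w = img.shape[:2]
    big = resize(img, (max(1, round(h * fy)), max(1, round(w * fx))) + img.shape[2:],
                 order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    out = resize(big, img.shape, order=1, mode="edge", anti_aliasing=False,
                 preserve_range=True)
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# learning-rate schedule and regularization


def build_lr_schedule(config: TrainConfig, graph: LayerGraph,
                      plan: ReplacementPlan | None = None) -> dict[str, float]:
    """Per parameter-group learning rates.

    Weight layers get ``base_lr``; the final classifier layer gets
    ``base_lr * final_layer_lr_multiplier``; APLU/Splash slope parameters get
    the relative rate ``base_lr / max_input``; all other activation
    parameters get ``base_lr``.
    """
    lrs: dict[str, float] = {}
    for layer in graph.layers:
        if layer.role in ("conv", "fc", "classifier"):
            mult = config.final_layer_lr_multiplier if layer.is_final else 1.0
            lrs[f"layer:{layer.layer_id}"] = config.base_lr * mult
        elif layer.role == "activation":
            spec = (plan.site_assignments[layer.layer_id] if plan is not None
                    else layer.activation)
            if spec is None:
                continue
            from .activations import ACTIVATION_KINDS
            for pkey in ACTIVATION_KINDS[spec.kind][0]:
                lr = config.base_lr
                if spec.kind in ("aplu", "splash") and pkey in _APLU_FAMILY_SLOPES:
                    lr = config.base_lr / spec.max_input
                lrs[f"site:{layer.layer_id}:{pkey}"] = lr
    return lrs


def aplu_regularization(params: ChannelParams, coeff: float) -> float:
    """L2 penalty ``coeff * sum(a_c^2)`` over APLU/Splash slope parameters."""
    keys = set(params.params)
    if "a" in keys and "b" in keys:
        slopes = [params["a"]]
    elif "a_pos" in keys and "a_neg" in keys:
        slopes = [params["a_pos"], params["a_neg"]]
    else:
        raise ValueError("params are not from an APLU/Splash-family site")
    return float(coeff) * float(sum(np.sum(s ** 2) for s in slopes))


# ---------------------------------------------------------------------------
# TinyNet: conv-act-pool x2 + linear head, manual backprop


def _conv2d(x, W):
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))
    return np.einsum("nchwij,ocij->nohw", win, W, optimize=True), win


def _conv2d_backward(dy, win, W):
    dW = np.einsum("nohw,nchwij->ocij", dy, win, optimize=True)
    dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dwin = sliding_window_view(dyp, (3, 3), axis=(2, 3))
    dx = np.einsum("nohwij,ocij->nchw", dwin, W[:, :, ::-1, ::-1], optimize=True)
    return dx, dW


def _maxpool(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = np.argmax(flat, axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool_backward(dy, idx, shape):
    n, c, h, w = shape
    dflat = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    return (dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TinyNetModel:
    """Two conv blocks (3x3 conv -> activation site -> 2x2 maxpool) and a
    linear classifier head, trained with SGD + momentum.

    The activation sites carry :class:`ChannelParams` from the replacement
    plan; their forward/backward go through the catalogue's analytic
    formulas.
    """

    def __init__(self, graph: LayerGraph, input_shape: tuple[int, int, int],
                 n_classes: int, seed: int = 0):
        cin, h, w = input_shape
        sites = [l for l in graph.layers if l.role == "activation"]
        convs = [l for l in graph.layers if l.role == "conv"]
        if len(sites) != 2 or len(convs) != 2:
            raise ValueError("TinyNetModel expects a two-conv-block graph")
        for l in sites:
            if l.activation is None or l.params is None:
                raise ValueError("activation sites must be instantiated "
                                 "(run apply_plan first)")
        c1, c2 = convs[0].channels, convs[1].channels
        rng = np.random.default_rng(seed)
        he = lambda fan_in, *shape: rng.normal(0, np.sqrt(2.0 / fan_in), shape)  # noqa: E731
        self.graph = graph
        self.n_classes = n_classes
        self.input_shape = input_shape
        feat = c2 * (h // 4) * (w // 4)
        self.weights = {
            f"layer:{convs[0].layer_id}:W": he(cin * 9, c1, cin, 3, 3),
            f"layer:{convs[0].layer_id}:b": np.zeros(c1),
            f"layer:{convs[1].layer_id}:W": he(c1 * 9, c2, c1, 3, 3),
            f"layer:{convs[1].layer_id}:b": np.zeros(c2),
            f"layer:{graph.final_layer.layer_id}:W": he(feat, n_classes, feat),
            f"layer:{graph.final_layer.layer_id}:b": np.zeros(n_classes),
        }
        self.sites: dict[str, tuple[ActivationSpec, ChannelParams]] = {
            l.layer_id: (l.activation, l.params.copy()) for l in sites}
        self._conv_ids = [l.layer_id for l in convs]
        self._site_ids = [l.layer_id for l in sites]
        self._fc_id = graph.final_layer.layer_id

    # -- forward -----------------------------------------------------------

    def _act_forward(self, site_id, x):
        spec, params = self.sites[site_id]
        n, c, h, w = x.shape
        xt = x.transpose(1, 0, 2, 3).reshape(c, -1)
        yt = eval_activation(spec, params, xt)
        return yt.reshape(c, n, h, w).transpose(1, 0, 2, 3)

    def _act_backward(self, site_id, x, dy):
        spec, params = self.sites[site_id]
        n, c, h, w = x.shape
        xt = x.transpose(1, 0, 2, 3).reshape(c, -1)
        gt = dy.transpose(1, 0, 2, 3).reshape(c, -1)
        bundle = grad_activation(spec, params, xt, upstream=gt)
        dx = bundle.d_input.reshape(c, n, h, w).transpose(1, 0, 2, 3)
        return dx, bundle.d_params

    def forward(self, X, cache: dict | None = None):
        c1, c2 = self._conv_ids
        s1, s2 = self._site_ids
        w = self.weights
        z1, win1 = _conv2d(X, w[f"layer:{c1}:W"])
        z1 += w[f"layer:{c1}:b"][None, :, None, None]
        a1 = self._act_forward(s1, z1)
        p1, idx1 = _maxpool(a1)
        z2, win2 = _conv2d(p1, w[f"layer:{c2}:W"])
        z2 += w[f"layer:{c2}:b"][None, :, None, None]
        a2 = self._act_forward(s2, z2)
        p2, idx2 = _maxpool(a2)
        flat = p2.reshape(len(X), -1)
        logits = flat @ w[f"layer:{self._fc_id}:W"].T + w[f"layer:{self._fc_id}:b"]
        if cache is not None:
            cache.update(win1=win1, z1=z1, a1shape=a1.shape, idx1=idx1, p1=p1,
                         win2=win2, z2=z2, a2shape=a2.shape, idx2=idx2,
                         flat=flat)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.forward(X))

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(self, X, y, reg_coeff: float = 0.0):
        cache: dict = {}
        logits = self.forward(X, cache)
        probs = _softmax(logits)
        n = len(X)
        ce = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))
        reg = 0.0
        for sid in self._site_ids:
            spec, params = self.sites[sid]
            if spec.kind in ("aplu", "splash"):
                reg += aplu_regularization(params, reg_coeff)
        loss = ce + reg

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        w = self.weights
        c1, c2 = self._conv_ids
        s1, s2 = self._site_ids
        grads: dict[str, np.ndarray] = {}
        site_grads: dict[str, dict[str, np.ndarray]] = {}

        grads[f"layer:{self._fc_id}:W"] = dlogits.T @ cache["flat"]
        grads[f"layer:{self._fc_id}:b"] = dlogits.sum(axis=0)
        dflat = dlogits @ w[f"layer:{self._fc_id}:W"]
        _, c2s, h2, w2 = cache["a2shape"]
        dp2 = dflat.reshape(len(X), c2s, h2 // 2, w2 // 2)
        da2 = _maxpool_backward(dp2, cache["idx2"], cache["a2shape"])
        dz2, sg2 = self._act_backward(s2, cache["z2"], da2)
        site_grads[s2] = sg2
        dp1, dW2 = _conv2d_backward(dz2, cache["win2"], w[f"layer:{c2}:W"])
        grads[f"layer:{c2}:W"] = dW2
        grads[f"layer:{c2}:b"] = dz2.sum(axis=(0, 2, 3))
        da1 = _maxpool_backward(dp1, cache["idx1"], cache["a1shape"])
        dz1, sg1 = self._act_backward(s1, cache["z1"], da1)
        site_grads[s1] = sg1
        _, dW1 = _conv2d_backward(dz1, cache["win1"], w[f"layer:{c1}:W"])
        grads[f"layer:{c1}:W"] = dW1
        grads[f"layer:{c1}:b"] = dz1.sum(axis=(0, 2, 3))

        # L2 penalty gradient on APLU/Splash slopes
        if reg_coeff > 0:
            for sid in self._site_ids:
                spec, params = self.sites[sid]
                if spec.kind in ("aplu", "splash"):
                    for key in _APLU_FAMILY_SLOPES & set(params.params):
                        site_grads[sid][key] = (site_grads[sid][key]
                                                + 2.0 * reg_coeff * params[key])
        return loss, grads, site_grads, probs


def predict_proba(model: TinyNetModel, X) -> np.ndarray:
    """Softmax class probabilities, row-stochastic."""
    return model.predict_proba(np.asarray(X, dtype=float))


def _resolve_epochs(config: TrainConfig, plan: ReplacementPlan | None) -> int:
    if config.epochs is not None:
        return config.epochs
    if plan is not None and plan.n_distinct_kinds > 1:
        return 30
    return 20


def train_model(graph: LayerGraph, plan: ReplacementPlan | None,
                dataset: ImageDataset, config: TrainConfig,
                weight_seed: int | None = None):
    """Train a TinyNet on an image dataset.

    Minimizes cross-entropy plus the APLU/Splash L2 penalty with SGD +
    momentum under :func:`build_lr_schedule` rates.  Returns the trained
    model and a per-epoch trace DataFrame (epoch, loss, accuracy).  Fully
    deterministic for a fixed config seed.
    """
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    planned = apply_plan(graph, plan, seed=config.seed) if plan is not None else graph
    for l in planned.layers:
        if l.role == "activation" and l.params is None:
            raise ValueError("graph activation sites are not instantiated and "
                             "no plan was given")
    n_classes = dataset.n_classes
    model = TinyNetModel(planned, dataset.X.shape[1:], n_classes,
                         seed=config.seed if weight_seed is None else weight_seed)
    lrs = build_lr_schedule(config, graph, plan)
    epochs = _resolve_epochs(config, plan)
    rng = np.random.default_rng(config.seed)

    velocity: dict[str, np.ndarray] = {}

    def lr_for(key: str) -> float:
        if key.startswith("layer:"):
            return lrs["layer:" + key.split(":")[1]]
        return lrs.get(key, config.base_lr)

    rows = []
    n = len(dataset.X)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            Xb = dataset.X[batch]
            if config.augment:
                Xb = np.stack([
                    np.moveaxis(augment_image(np.moveaxis(img, 0, -1), rng), -1, 0)
                    for img in Xb])
            yb = dataset.y[batch]
            loss, grads, site_grads, probs = model.loss_and_grads(
                Xb, yb, reg_coeff=config.aplu_reg_coeff)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            preds = probs.argmax(axis=1)
            epoch_correct += int(np.sum(preds == yb))
            epoch_loss += loss * len(batch)
            for key, g in grads.items():
                v = velocity.get(key, 0.0)
                v = config.momentum * v - lr_for(key) * g
                velocity[key] = v
                model.weights[key] += v
            for sid, sg in site_grads.items():
                spec, params = model.sites[sid]
                for pkey, g in sg.items():
                    key = f"site:{sid}:{pkey}"
                    v = velocity.get(key, 0.0)
                    v = config.momentum * v - lr_for(key) * g
                    velocity[key] = v
                    params.params[pkey] += v
                clamp_params(spec, params)
        rows.append({"epoch": epoch, "loss": epoch_loss / n,
                     "accuracy": 100.0 * epoch_correct / n})
    return model, pd.DataFrame(rows)
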