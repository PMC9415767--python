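"""Seeded desk-scale image-classification fixtures.

Stands in for multi-class microscopy/histology benchmarks at toy size:
labeled grayscale images whose class signal is controllable (blob position,
texture frequency or intensity-gradient direction) and whose difficulty is a
single noise knob sigma.  At ``sigma = 0`` classes are perfectly separable
from raw pixels; increasing sigma degrades any classifier monotonically.

Also generates per-model class-probability matrices with prescribed argmax
accuracies, used to exercise fusion and SFFS selection without any training.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .ensembles import ProbabilityMatrix

__all__ = [
    "ToySpec",
    "generate_toy_arrays",
    "make_toy_dataset",
    "make_probability_fixtures",
]

_SIGNALS = ("blob", "texture", "gradient")


@dataclass(frozen=True)
class ToySpec:
    """Generative description of one toy dataset."""

    n_classes: int = 4
    samples_per_class: int = 50
    image_size: int = 32
    signal: str = "blob"
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.signal not in _SIGNALS:
            raise ValueError(f"signal must be one of {_SIGNALS}")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")


def _class_template(spec: ToySpec, cls: int) -> np.ndarray:
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s] / (s - 1)
    angle = 2 * np.pi * cls / spec.n_classes
    if spec.signal == "blob":
        # Gaussian bump at a class-specific position on a ring
        cy = 0.5 + 0.28 * np.sin(angle)
        cx = 0.5 + 0.28 * np.cos(angle)
        width = 0.12
        return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width ** 2))
    if spec.signal == "texture":
        freq = 2.0 + 2.0 * cls
        return 0.5 + 0.5 * np.sin(2 * np.pi * freq * xx)
    # intensity gradient along a class-specific direction
    t = np.cos(angle) * xx + np.sin(angle) * yy
    t = (t - t.min()) / (t.max() - t.min())
    return t


def generate_toy_arrays(spec: ToySpec):
    """Images (N, 1, S, S) in [0, 1] and labels, deterministic in the spec."""
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for cls in range(spec.n_classes):
        template = _class_template(spec, cls)
        for _ in range(spec.samples_per_class):
            img = template + spec.sigma * rng.normal(size=template.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
    X = np.stack(images)[:, None, :, :]
    return X, np.array(labels)


def make_toy_dataset(spec: ToySpec, root) -> pd.DataFrame:
    """Write the dataset as ``<root>/<class_name>/<sample>.png`` plus a
    ``labels.csv`` manifest; byte-identical for identical spec + seed."""
    root = Path(root)
    X, y = generate_toy_arrays(spec)
    rows = []
    idx_in_class = {c: 0 for c in range(spec.n_classes)}
    for img, cls in zip(X[:, 0], y):
        cname = f"class_{cls:02d}"
        cdir = root / cname
        cdir.mkdir(parents=True, exist_ok=True)
        i = idx_in_class[cls]
        idx_in_class[cls] += 1
        fname = f"{i:04d}.png"
        Image.fromarray(np.round(img * 255).astype(np.uint8)).save(cdir / fname)
        rows.append({"path": f"{cname}/{fname}", "label": int(cls),
                     "class_name": cname})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "labels.csv", index=False)
    return manifest


def make_probability_fixtures(n_models: int, n_samples: int, n_classes: int,
                              accuracy_targets, seed: int = 0):
    """Probability matrices with prescribed argmax accuracies.

    For each model, exactly ``round(target * n_samples)`` rows (a seeded
    random subset) have their argmax at the true label; the rest argmax at a
    random wrong class.  Realized accuracy therefore matches the target to
    within half a sample.  Returns ``(matrices, labels)``.
    """
    targets = np.atleast_1d(np.asarray(accuracy_targets, dtype=float))
    if len(targets) != n_models:
        raise ValueError("need one accuracy target per model")
    if np.any(targets < 1.0 / n_classes - 1e-12) or np.any(targets > 1.0 + 1e-12):
        raise ValueError("targets must lie in [1/n_classes, 1]")
    rng = np.random.default_rng(seed)
    labels = rng.integers(n_classes, size=n_samples)
    matrices = []
    for m, target in enumerate(targets):
        n_correct = int(round(target * n_samples))
        correct = np.zeros(n_samples, dtype=bool)
        correct[rng.choice(n_samples, size=n_correct, replace=False)] = True
        argmax_class = labels.copy()
        wrong_idx = np.flatnonzero(~correct)
        for i in wrong_idx:
            choices = np.delete(np.arange(n_classes), labels[i])
            argmax_class[i] = rng.choice(choices)
        base = rng.dirichlet(np.ones(n_classes), size=n_samples)
        rows = 0.45 * base
        rows[np.arange(n_samples), argmax_class] += 0.55
        matrices.append(ProbabilityMatrix(rows, model_id=f"model_{m}"))
    return matrices, labels
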