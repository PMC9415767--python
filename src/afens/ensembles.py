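"""Sum-rule fusion, stochastic ensembles, named recipes and SFFS selection.

Ensemble decisions are combined by the sum rule: the softmax probability
rows of all member networks are averaged and the fused row's argmax is the
ensemble decision.  The mean (rather than the raw sum) is used so fused
matrices remain row-stochastic; the argmax is unchanged.

Member selection uses Sequential Forward Floating Selection (SFFS): at each
step the candidate whose addition most increases fused accuracy joins the
ensemble, then a backtracking step drops the member whose removal most
improves the score, if any does.  Ties break toward the smaller ensemble and
then toward lexicographic member order, which makes the procedure
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .surgery import LayerGraph, sample_replacement_plan

__all__ = [
    "ProbabilityMatrix",
    "EnsembleRecipe",
    "sum_rule_fuse",
    "build_stochastic_ensemble",
    "sffs_select",
    "recipe_members",
    "recipe_ensemble",
    "member_key",
    "DEFAULT_ALL_MEMBERS",
]

_ROW_TOL = 1e-9


@dataclass
class ProbabilityMatrix:
    """n_samples x n_classes class-probability rows from one model."""

    values: np.ndarray
    model_id: str = ""
    context_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (n_samples, n_classes)")
        if np.any(v < 0):
            raise ValueError("probabilities must be nonnegative")
        if np.max(np.abs(v.sum(axis=1) - 1.0)) > _ROW_TOL:
            raise ValueError("every row must sum to 1 within 1e-9")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values,
                          columns=[f"class_{j}" for j in range(self.n_classes)])
        df.insert(0, "sample_id", np.arange(self.n_samples))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_id: str = "") -> "ProbabilityMatrix":
        df = pd.read_csv(path).sort_values("sample_id")
        cols = [c for c in df.columns if c.startswith("class_")]
        return cls(df[cols].to_numpy(), model_id=model_id or Path(path).stem)


@dataclass(frozen=True)
class EnsembleRecipe:
    name: str
    members: tuple[str, ...]
    fusion: str = "sum"


def sum_rule_fuse(members: Sequence[ProbabilityMatrix]) -> ProbabilityMatrix:
    """Elementwise mean of member probability matrices (sum-rule fusion)."""
    if not members:
        raise ValueError("empty member list")
    shape = members[0].values.shape
    for m in members[1:]:
        if m.values.shape != shape:
            raise ValueError("members disagree on sample or class count")
    fused = np.mean([m.values for m in members], axis=0)
    return ProbabilityMatrix(fused, model_id="+".join(m.model_id for m in members))


def _fused_accuracy(matrices: Sequence[ProbabilityMatrix], labels) -> float:
    from .evaluation import accuracy
    return accuracy(sum_rule_fuse(list(matrices)), labels)


def build_stochastic_ensemble(graph: LayerGraph, pool, n_members: int,
                              dataset, config, seed: int = 0,
                              granularity: str = "per_layer"):
    """Train ``n_members`` networks with independently sampled replacement
    plans and fuse their test-set outputs by sum rule.

    ``dataset`` is a :class:`afens.training.SplitDataset`.  Member plan and
    training seeds derive from the master seed, so the whole ensemble is
    reproducible.  Returns ``(models, member_matrices, fused_matrix)``.
    """
    from dataclasses import replace as dc_replace

    from .training import predict_proba, train_model

    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    member_seeds = rng.integers(2 ** 31, size=n_members)
    models, matrices = [], []
    for i, mseed in enumerate(member_seeds):
        plan = sample_replacement_plan(graph, pool, granularity, seed=int(mseed))
        cfg = dc_replace(config, seed=int(mseed))
        model, _ = train_model(graph, plan, dataset.train, cfg)
        probs = predict_proba(model, dataset.test.X)
        models.append(model)
        matrices.append(ProbabilityMatrix(probs, model_id=f"stoc#{i}"))
    return models, matrices, sum_rule_fuse(matrices)


# ---------------------------------------------------------------------------
# SFFS


def _normalize_candidates(candidates, labels):
    """Accept per-model matrices (one context) or per-model lists of matrices
    (one per validation context, e.g. leave-one-dataset-out)."""
    if not candidates:
        raise ValueError("empty candidate list")
    first = candidates[0]
    if isinstance(first, ProbabilityMatrix):
        per_model = [[c] for c in candidates]
        label_sets = [np.asarray(labels)]
    else:
        per_model = [list(c) for c in candidates]
        label_sets = [np.asarray(l) for l in labels]
    n_ctx = len(per_model[0])
    if any(len(m) != n_ctx for m in per_model) or len(label_sets) != n_ctx:
        raise ValueError("candidates and labels disagree on context count")
    for ctx in range(n_ctx):
        n = per_model[0][ctx].n_samples
        if len(label_sets[ctx]) != n:
            raise ValueError("labels do not align with matrices")
    return per_model, label_sets


def sffs_select(candidates, labels, max_size: int | None = None) -> list[int]:
    """Pick ensemble members by sequential forward floating selection.

    The objective is mean fused accuracy over the validation contexts.
    Returns the selected candidate indices in selection order.  The result's
    objective is never below the best single candidate's.
    """
    per_model, label_sets = _normalize_candidates(candidates, labels)
    n_models = len(per_model)
    max_size = n_models if max_size is None else min(max_size, n_models)
    n_ctx = len(label_sets)

    def score(subset: tuple[int, ...]) -> float:
        vals = [_fused_accuracy([per_model[i][ctx] for i in subset],
                                label_sets[ctx]) for ctx in range(n_ctx)]
        return float(np.mean(vals))

    selected: list[int] = []
    current = -np.inf
    while len(selected) < max_size:
        # forward step: best addition (ties -> lowest index)
        best_gain, best_idx = None, None
        for i in range(n_models):
            if i in selected:
                continue
            s = score(tuple(selected + [i]))
            if best_gain is None or s > best_gain:
                best_gain, best_idx = s, i
        if best_idx is None:
            break
        if selected and best_gain <= current:
            break  # no strict improvement from any addition
        selected.append(best_idx)
        current = best_gain
        # backtracking: drop the member whose removal most improves the score
        while len(selected) > 2:
            best_drop_score, best_drop = None, None
            for j in selected:
                s = score(tuple(k for k in selected if k != j))
                if best_drop_score is None or s > best_drop_score:
                    best_drop_score, best_drop = s, j
            if best_drop_score is not None and best_drop_score > current:
                selected.remove(best_drop)
                current = best_drop_score
            else:
                break
    return selected


# ---------------------------------------------------------------------------
# named recipes

DEFAULT_ALL_MEMBERS = (
    "relu", "leaky_relu", "elu", "selu", "prelu", "srelu", "aplu",
    "melu_k8", "melu_k4", "small_galu", "galu", "pdelu", "swish",
    "swish_learnable", "mish", "mish_learnable", "tanelu", "srs",
    "soft_learnable", "soft_learnable2", "splash", "melu_2d",
    "melu_plus_galu", "symmetric_melu", "symmetric_galu", "flexible_melu",
)

_ENS_MEMBERS = {
    1: ("melu_k8", "leaky_relu", "elu", "melu_k4", "prelu", "srelu", "aplu",
        "relu"),
    255: ("melu_k8", "melu_k4", "srelu", "aplu", "relu"),
}


def member_key(member: str, max_input: float) -> str:
    """Registry key for one trained member at one input scale."""
    return f"{member}@mi{max_input:g}"


def recipe_members(name: str, max_input: float = 1.0,
                   all_members: Sequence[str] = DEFAULT_ALL_MEMBERS,
                   n_replicas: int = 15) -> list[str]:
    """Registry keys required by a named ensemble recipe."""
    mi = int(max_input)
    if mi not in (1, 255) and name not in ("15ReLU",):
        raise ValueError("recipes are defined for max_input 1 or 255")
    if name == "ENS":
        return [member_key(m, mi) for m in _ENS_MEMBERS[mi]]
    if name == "ENS_G":
        return [member_key(m, mi)
                for m in _ENS_MEMBERS[mi] + ("small_galu", "galu")]
    if name == "eENS":
        return recipe_members("ENS", 1) + recipe_members("ENS", 255)
    if name == "eENS_G":
        return recipe_members("ENS_G", 1) + recipe_members("ENS_G", 255)
    if name == "ALL":
        return [member_key(m, mi) for m in all_members]
    if name == "eALL":
        return (recipe_members("ALL", 1, all_members)
                + recipe_members("ALL", 255, all_members))
    if name == "15ReLU":
        return [member_key(f"relu#{j}", mi) for j in range(n_replicas)]
    if name.startswith("Stoc_"):
        return [member_key(f"{name.lower()}#{j}", mi) for j in range(n_replicas)]
    raise ValueError(f"unknown recipe {name!r}")


def recipe_ensemble(name: str, registry: Mapping[str, ProbabilityMatrix],
                    max_input: float = 1.0, labels=None,
                    all_members: Sequence[str] = DEFAULT_ALL_MEMBERS,
                    n_replicas: int = 15, max_size: int | None = None
                    ) -> ProbabilityMatrix:
    """Fuse the members of a named recipe from a registry of per-model
    probability matrices.

    ``Selection`` runs :func:`sffs_select` over every registry entry and
    fuses the selected subset (``labels`` required); all other recipes fuse
    a fixed member list by sum rule.
    """
    if name == "Selection":
        if labels is None:
            raise ValueError("Selection requires validation labels")
        keys = sorted(registry)
        cands = [registry[k] for k in keys]
        chosen = sffs_select(cands, labels, max_size=max_size)
        return sum_rule_fuse([cands[i] for i in chosen])
    keys = recipe_members(name, max_input, all_members, n_replicas)
    missing = [k for k in keys if k not in registry]
    if missing:
        raise KeyError(f"registry missing members: {missing}")
    return sum_rule_fuse([registry[k] for k in keys])
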