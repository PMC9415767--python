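"""Layer graphs, activation sites, and stochastic activation replacement.

A network is abstracted as an ordered :class:`LayerGraph` whose activation
sites can be re-assigned any activation from the catalogue.  The stochastic
ensemble method draws, per member network, a random assignment of activations
from a named pool (:func:`sample_replacement_plan`); because every pool kind
equals ReLU at initialization (hat coefficients and piecewise slopes start at
zero), replacement leaves a ReLU-pretrained network's function unchanged until
training moves the new parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .activations import ActivationSpec, ChannelParams, get_spec, init_params

__all__ = [
    "Layer",
    "LayerGraph",
    "SiteDescriptor",
    "ReplacementPlan",
    "tiny_net_graph",
    "enumerate_activation_sites",
    "sample_replacement_plan",
    "apply_plan",
    "plan_to_yaml",
    "plan_from_yaml",
    "pool_stoc1",
    "pool_stoc2",
    "pool_stoc3",
    "pool_stoc4",
    "NAMED_POOLS",
]


@dataclass(frozen=True)
class Layer:
    layer_id: str
    role: str  # conv | fc | activation | pool | classifier
    channels: int = 0
    is_final: bool = False
    activation: ActivationSpec | None = None
    params: ChannelParams | None = None


@dataclass(frozen=True)
class LayerGraph:
    """Ordered layers with at least one activation site and one classifier."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        sites = [l for l in self.layers if l.role == "activation"]
        if not sites:
            raise ValueError("graph has no activation sites")
        if any(l.channels <= 0 for l in sites):
            raise ValueError("activation sites must have positive channel counts")
        finals = [l for l in self.layers if l.is_final]
        if len(finals) != 1:
            raise ValueError("graph must have exactly one final classifier layer")

    def layer(self, layer_id: str) -> Layer:
        for l in self.layers:
            if l.layer_id == layer_id:
                return l
        raise KeyError(layer_id)

    @property
    def final_layer(self) -> Layer:
        return next(l for l in self.layers if l.is_final)


@dataclass(frozen=True)
class SiteDescriptor:
    site_id: str
    channels: int
    position: int  # index in layer order


@dataclass(frozen=True)
class ReplacementPlan:
    """Assignment of an ActivationSpec to every activation site of a graph."""

    site_assignments: dict[str, ActivationSpec]
    granularity: str  # per_layer | per_network
    pool: tuple[ActivationSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.granularity not in ("per_layer", "per_network"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        if self.granularity == "per_network":
            specs = set(self.site_assignments.values())
            if len(specs) > 1:
                raise ValueError("per_network plan must assign one spec everywhere")

    @property
    def n_distinct_kinds(self) -> int:
        return len({s.kind for s in self.site_assignments.values()})


def tiny_net_graph(in_channels: int = 1, conv_channels: tuple[int, int] = (8, 16),
                   n_classes: int = 4) -> LayerGraph:
    """Canonical small test network: two conv blocks plus a linear head."""
    c1, c2 = conv_channels
    return LayerGraph((
        Layer("conv1", "conv", channels=c1),
        Layer("act1", "activation", channels=c1, activation=get_spec("relu")),
        Layer("pool1", "pool"),
        Layer("conv2", "conv", channels=c2),
        Layer("act2", "activation", channels=c2, activation=get_spec("relu")),
        Layer("pool2", "pool"),
        Layer("fc", "classifier", channels=n_classes, is_final=True),
    ))


def enumerate_activation_sites(graph: LayerGraph) -> list[SiteDescriptor]:
    """All activation sites in stable layer order."""
    return [SiteDescriptor(l.layer_id, l.channels, i)
            for i, l in enumerate(graph.layers) if l.role == "activation"]


def sample_replacement_plan(graph: LayerGraph, pool, granularity: str = "per_layer",
                            seed: int = 0) -> ReplacementPlan:
    """Draw a random activation assignment for every site.

    ``per_layer`` draws each site independently and uniformly from the pool;
    ``per_network`` draws one activation and applies it to all sites.
    Identical seeds produce identical plans.
    """
    pool = tuple(pool)
    if not pool:
        raise ValueError("pool must be non-empty")
    sites = enumerate_activation_sites(graph)
    rng = np.random.default_rng(seed)
    if granularity == "per_network":
        choice = pool[rng.integers(len(pool))]
        assignments = {s.site_id: choice for s in sites}
    elif granularity == "per_layer":
        idx = rng.integers(len(pool), size=len(sites))
        assignments = {s.site_id: pool[i] for s, i in zip(sites, idx)}
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    return ReplacementPlan(assignments, granularity, pool, seed)


def apply_plan(graph: LayerGraph, plan: ReplacementPlan, seed: int = 0) -> LayerGraph:
    """Instantiate the plan: each site gets its assigned spec with freshly
    initialized per-channel parameters (seeded, hence bit-reproducible)."""
    sites = enumerate_activation_sites(graph)
    missing = {s.site_id for s in sites} - set(plan.site_assignments)
    if missing:
        raise ValueError(f"plan does not cover sites: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    new_layers = []
    for layer in graph.layers:
        if layer.role == "activation":
            spec = plan.site_assignments[layer.layer_id]
            params = init_params(spec, layer.channels,
                                 seed=int(rng.integers(2 ** 31)))
            new_layers.append(replace(layer, activation=spec, params=params))
        else:
            new_layers.append(layer)
    return LayerGraph(tuple(new_layers))


# ---------------------------------------------------------------------------
# plan serialization (exact experiment replay)


def _spec_to_dict(spec: ActivationSpec) -> dict:
    return {"kind": spec.kind, "k": spec.k, "max_input": float(spec.max_input),
            "constants": dict(spec.constants)}


def _spec_from_dict(d: dict) -> ActivationSpec:
    return ActivationSpec(kind=d["kind"], k=d.get("k", 0),
                          max_input=d.get("max_input", 1.0),
                          constants=d.get("constants", {}))


def plan_to_yaml(plan: ReplacementPlan) -> str:
    return yaml.safe_dump({
        "granularity": plan.granularity,
        "seed": plan.seed,
        "pool": [_spec_to_dict(s) for s in plan.pool],
        "sites": {sid: _spec_to_dict(s) for sid, s in plan.site_assignments.items()},
    }, sort_keys=True)


def plan_from_yaml(text: str) -> ReplacementPlan:
    d = yaml.safe_load(text)
    return ReplacementPlan(
        {sid: _spec_from_dict(s) for sid, s in d["sites"].items()},
        d["granularity"],
        tuple(_spec_from_dict(s) for s in d["pool"]),
        d["seed"],
    )


# ---------------------------------------------------------------------------
# named pools


def pool_stoc1(max_input: float = 255.0) -> tuple[ActivationSpec, ...]:
    """Nine-function pool: MeLU(k=8), Leaky ReLU, ELU, MeLU(k=4), PReLU,
    SReLU, APLU, GaLU, Small GaLU."""
    return (
        get_spec("melu", max_input, k=8),
        get_spec("leaky_relu", max_input),
        get_spec("elu", max_input),
        get_spec("melu", max_input, k=4),
        get_spec("prelu", max_input),
        get_spec("srelu", max_input),
        get_spec("aplu", max_input),
        get_spec("galu", max_input),
        get_spec("small_galu", max_input),
    )


def pool_stoc2(max_input: float = 255.0) -> tuple[ActivationSpec, ...]:
    """pool_stoc1 plus ReLU, Soft Learnable, PDELU, learnable Mish, SRS,
    learnable Swish and Swish."""
    return pool_stoc1(max_input) + (
        get_spec("relu", max_input),
        get_spec("soft_learnable", max_input),
        get_spec("pdelu", max_input),
        get_spec("mish_learnable", max_input),
        get_spec("srs", max_input),
        get_spec("swish_learnable", max_input),
        get_spec("swish", max_input),
    )


def pool_stoc3(max_input: float = 255.0) -> tuple[ActivationSpec, ...]:
    """pool_stoc2 without the hat-ladder kinds (MeLU, GaLU, Small GaLU)."""
    drop = {"melu", "galu", "small_galu"}
    return tuple(s for s in pool_stoc2(max_input) if s.kind not in drop)


def pool_stoc4(max_input: float = 255.0) -> tuple[ActivationSpec, ...]:
    """Configurable recipe pool; defaults to pool_stoc2."""
    return pool_stoc2(max_input)


NAMED_POOLS = {
    "stoc1": pool_stoc1,
    "stoc2": pool_stoc2,
    "stoc3": pool_stoc3,
    "stoc4": pool_stoc4,
}
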