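"""Catalogue of fixed and learnable CNN activation functions.

Every activation is defined by an :class:`ActivationSpec` (its kind plus fixed
hyperparameters) and, for learnable kinds, a :class:`ChannelParams` holding one
parameter vector per channel.  :func:`eval_activation` computes the forward
value and :func:`grad_activation` the analytic input gradient and the gradient
with respect to every learnable parameter — the quantities a backprop engine
needs, exposed here explicitly so they can be verified against finite
differences.

The MeLU/GaLU family is built on a fixed "ladder" of Mexican-hat basis
functions: triangular bumps ``phi(x; a, lam) = max(lam - |x - a|, 0)`` whose
centers ``a_j`` and half-widths ``lam_j`` come from a recursive dyadic
subdivision of ``[0, 4 * max_input]`` (:func:`build_melu_ladder`).  The GaLU
variant replaces each bump by a zero-mean up/down pair
(:func:`derive_galu_ladder`, ``variant="gaussian"`` of :func:`hat_eval`).

Conventions
-----------
* At non-differentiable points the derivative is taken from the right
  (the ``x >= 0`` branch of the ReLU family).
* ``grad_activation`` returns a vector-Jacobian product: ``d_input`` is the
  gradient of ``sum(upstream * y)`` with respect to ``x`` (``upstream`` defaults
  to ones) and ``d_params`` the gradient with respect to each parameter.  For
  elementwise kinds with ``upstream=None`` this reduces to the pointwise
  derivative ``dy_i/dx_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ActivationSpec",
    "ParameterLadder",
    "ChannelParams",
    "GradBundle",
    "ACTIVATION_KINDS",
    "get_spec",
    "build_melu_ladder",
    "derive_galu_ladder",
    "hat_eval",
    "init_params",
    "eval_activation",
    "grad_activation",
    "clamp_params",
    "ladder_to_csv",
    "ladder_from_csv",
]

_LADDER_KS = (2, 4, 8)
_SRS_EPS = 1e-6

# kind -> (learnable parameter keys, default k, default fixed constants)
ACTIVATION_KINDS: dict[str, tuple[tuple[str, ...], int, dict[str, float]]] = {
    "relu": ((), 0, {}),
    "leaky_relu": ((), 0, {"a": 0.01}),
    "prelu": (("c0",), 0, {}),
    "elu": ((), 0, {"a": 1.0}),
    "selu": ((), 0, {"lambda": 1.0507009873554805, "alpha": 1.6732632423543772}),
    "pdelu": (("alpha",), 0, {"t": 0.9}),
    "swish": ((), 0, {"beta": 1.0}),
    "swish_learnable": (("beta",), 0, {}),
    "mish": ((), 0, {"alpha": 1.0}),
    "mish_learnable": (("alpha",), 0, {}),
    "tanelu": (("a",), 0, {}),
    "srelu": (("t_l", "t_r", "a_l", "a_r"), 0, {"init_preset": "operational"}),
    "aplu": (("a", "b"), 0, {"n": 5}),
    "melu": (("c0", "c"), 8, {}),
    "small_galu": (("c0", "c"), 2, {}),
    "galu": (("c0", "c"), 4, {}),
    "srs": (("alpha", "beta"), 0, {}),
    "soft_learnable": (("alpha",), 0, {"beta": 1.0}),
    "soft_learnable2": (("alpha", "beta"), 0, {}),
    "splash": (("a_pos", "a_neg", "b"), 0, {"n": 5}),
    "melu_2d": (("c0", "c2d"), 8, {}),
    "melu_plus_galu": (("c0", "c", "a"), 8, {}),
    "symmetric_melu": (("c0", "c"), 8, {}),
    "symmetric_galu": (("c0", "c"), 4, {}),
    "flexible_melu": (("c0", "c", "centers"), 8, {}),
}

_LADDER_KINDS = frozenset(
    {"melu", "small_galu", "galu", "melu_2d", "melu_plus_galu",
     "symmetric_melu", "symmetric_galu", "flexible_melu"}
)


@dataclass(frozen=True)
class ActivationSpec:
    """Immutable description of one activation kind plus fixed hyperparameters.

    Parameters
    ----------
    kind
        One of the names in :data:`ACTIVATION_KINDS`.
    k
        Hat count parameter of the MeLU/GaLU family (number of learnable
        parameters per channel, ``k - 1`` of them hat coefficients).  Must be
        2, 4 or 8 for ladder-based kinds; ignored otherwise.
    max_input
        Assumed input scale of the activation (1, 255 or 256 in practice).
        Linearly scales the hat ladder and APLU's relative learning rate.
    constants
        Fixed, non-learnable scalars referenced by the kind's formula
        (leaky slope, ELU ``a``, PDELU ``t``, fixed Swish/Mish parameter,
        APLU hinge count ``n``, SReLU init preset).
    """

    kind: str
    k: int = 0
    max_input: float = 1.0
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ACTIVATION_KINDS:
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if self.max_input <= 0:
            raise ValueError("max_input must be positive")
        if self.kind in _LADDER_KINDS and self.k not in _LADDER_KS:
            raise ValueError(f"{self.kind} requires k in {_LADDER_KS}, got {self.k}")
        object.__setattr__(self, "constants", dict(self.constants))

    def __hash__(self) -> int:
        return hash((self.kind, self.k, self.max_input,
                     tuple(sorted(self.constants.items()))))

    def const(self, name: str) -> float:
        merged = {**ACTIVATION_KINDS[self.kind][2], **self.constants}
        return merged[name]

    @property
    def param_keys(self) -> tuple[str, ...]:
        return ACTIVATION_KINDS[self.kind][0]


def get_spec(name: str, max_input: float = 1.0, k: int | None = None,
             **constants: float) -> ActivationSpec:
    """Build the default :class:`ActivationSpec` for a registry name."""
    if name not in ACTIVATION_KINDS:
        raise ValueError(f"unknown activation kind {name!r}")
    default_k = ACTIVATION_KINDS[name][1]
    return ActivationSpec(kind=name, k=default_k if k is None else k,
                          max_input=max_input, constants=constants)


@dataclass(frozen=True)
class ParameterLadder:
    """Fixed Mexican-hat centers ``a_j`` and half-widths ``lam_j``."""

    centers: np.ndarray
    half_widths: np.ndarray
    max_input: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "half_widths", np.asarray(self.half_widths, dtype=float))
        if self.centers.shape != self.half_widths.shape:
            raise ValueError("centers and half_widths must have equal length")
        if self.centers.size == 0:
            raise ValueError("empty ladder")
        if np.any(self.half_widths <= 0):
            raise ValueError("all half-widths must be positive")

    def __len__(self) -> int:
        return self.centers.size


@dataclass
class ChannelParams:
    """Per-channel learnable parameter vectors, keyed by parameter name.

    Every array's leading axis has length ``n_channels``; hinge-based kinds
    (APLU, Splash) carry an extra hinge axis and 2D MeLU a ``(k-1, k-1)``
    coefficient grid per channel.
    """

    params: dict[str, np.ndarray]
    n_channels: int

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for key, arr in self.params.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != self.n_channels:
                raise ValueError(
                    f"parameter {key!r} has leading dim {arr.shape[0]}, "
                    f"expected n_channels={self.n_channels}")
            self.params[key] = arr

    def __getitem__(self, key: str) -> np.ndarray:
        return self.params[key]

    def copy(self) -> "ChannelParams":
        return ChannelParams({k: v.copy() for k, v in self.params.items()},
                             self.n_channels)


@dataclass
class GradBundle:
    """Input gradient plus per-parameter gradients of one activation site."""

    d_input: np.ndarray
    d_params: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# ladders


def build_melu_ladder(max_input: float, k: int) -> ParameterLadder:
    """Fixed MeLU hat parameters by recursive dyadic subdivision.

    Level 1 is a single hat peaking at ``2*max_input`` and vanishing at 0 and
    ``4*max_input``; each next level halves the half-width, its hats peaking at
    the odd multiples of that half-width.  The first ``k - 1`` (center,
    half-width) pairs are returned breadth-first by level, so the ``k=4``
    ladder is a prefix of the ``k=8`` one.
    """
    if k not in _LADDER_KS:
        raise ValueError(f"k must be one of {_LADDER_KS}, got {k}")
    if max_input <= 0:
        raise ValueError("max_input must be positive")
    centers: list[float] = []
    half_widths: list[float] = []
    level = 1
    while len(centers) < k - 1:
        hw = 2.0 * max_input / 2 ** (level - 1)
        for j in range(2 ** (level - 1)):
            centers.append((2 * j + 1) * hw)
            half_widths.append(hw)
        level += 1
    return ParameterLadder(np.array(centers[: k - 1]),
                           np.array(half_widths[: k - 1]), max_input)


def derive_galu_ladder(melu_ladder: ParameterLadder) -> ParameterLadder:
    """GaLU ladder from a MeLU ladder: half-widths halved, centers shifted
    left by the new half-width (so each up/down pair spans the old support)."""
    new_hw = melu_ladder.half_widths / 2.0
    new_centers = melu_ladder.centers - new_hw
    return ParameterLadder(new_centers, new_hw, melu_ladder.max_input)


def hat_eval(x, a: float, lam: float, variant: str = "mexican"):
    """Evaluate one hat basis function.

    ``mexican``: triangular bump ``max(lam - |x - a|, 0)`` with support
    ``[a - lam, a + lam]``.  ``gaussian``: the bump followed by a mirror-image
    trough at ``a + 2*lam``, i.e. ``+ min(|x - a - 2*lam| - lam, 0)``; the two
    triangles have equal area so the function integrates to zero.
    """
    if lam <= 0:
        raise ValueError("half-width lam must be positive")
    x = np.asarray(x, dtype=float)
    up = np.maximum(lam - np.abs(x - a), 0.0)
    if variant == "mexican":
        return up if up.shape else float(up)
    if variant == "gaussian":
        out = up + np.minimum(np.abs(x - a - 2.0 * lam) - lam, 0.0)
        return out if out.shape else float(out)
    raise ValueError(f"unknown hat variant {variant!r}")


def ladder_to_csv(ladder: ParameterLadder, path) -> None:
    """Write a ladder as CSV with columns ``j, a_j, lambda_j`` (j is 1-based)."""
    pd.DataFrame({
        "j": np.arange(1, len(ladder) + 1),
        "a_j": ladder.centers,
        "lambda_j": ladder.half_widths,
    }).to_csv(path, index=False)


def ladder_from_csv(path, max_input: float) -> ParameterLadder:
    df = pd.read_csv(path).sort_values("j")
    return ParameterLadder(df["a_j"].to_numpy(), df["lambda_j"].to_numpy(), max_input)


def _melu_ladder_for(spec: ActivationSpec) -> ParameterLadder:
    return build_melu_ladder(spec.max_input, spec.k)


def _galu_ladder_for(spec: ActivationSpec) -> ParameterLadder:
    return derive_galu_ladder(build_melu_ladder(spec.max_input, spec.k))


# ---------------------------------------------------------------------------
# initialization


def init_params(spec: ActivationSpec, n_channels: int, seed: int) -> ChannelParams:
    """Initial learnable parameters for one activation site.

    Hat coefficients, PReLU/mixing slopes and APLU/Splash slopes start at
    zero, so every ladder-based kind (and APLU, TanELU) initially equals ReLU
    and can replace the ReLU sites of a pretrained network without changing
    its function.  APLU/Splash hinge locations are drawn uniformly on
    ``(0, max_input)`` from ``seed``.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    kind = spec.kind
    if kind not in ACTIVATION_KINDS:
        raise ValueError(f"unknown activation kind {kind!r}")
    rng = np.random.default_rng(seed)
    C = n_channels
    p: dict[str, np.ndarray] = {}
    zeros = lambda *shape: np.zeros(shape, dtype=float)  # noqa: E731

    if kind == "prelu":
        p["c0"] = zeros(C)
    elif kind == "pdelu":
        p["alpha"] = zeros(C)
    elif kind == "swish_learnable":
        p["beta"] = np.ones(C)
    elif kind == "mish_learnable":
        p["alpha"] = np.ones(C)
    elif kind == "tanelu":
        p["a"] = zeros(C)
    elif kind == "srelu":
        preset = spec.const("init_preset")
        if preset == "operational":
            p["a_l"] = np.full(C, 0.5)
            p["a_r"] = np.full(C, 0.2)
            p["t_l"] = np.full(C, -2.0)
            p["t_r"] = np.full(C, 1.5)
        elif preset == "zero":
            # identity above t_r keeps the function equal to ReLU at init
            p["a_l"] = zeros(C)
            p["a_r"] = np.ones(C)
            p["t_l"] = zeros(C)
            p["t_r"] = np.full(C, float(spec.max_input))
        else:
            raise ValueError(f"unknown SReLU init preset {preset!r}")
    elif kind == "aplu":
        n = int(spec.const("n"))
        p["a"] = zeros(C, n)
        p["b"] = rng.uniform(0.0, spec.max_input, size=(C, n))
    elif kind == "splash":
        n = int(spec.const("n"))
        p["a_pos"] = zeros(C, n)
        p["a_neg"] = zeros(C, n)
        p["b"] = rng.uniform(0.0, spec.max_input, size=(C, n))
    elif kind in ("melu", "small_galu", "galu", "symmetric_melu", "symmetric_galu"):
        p["c0"] = zeros(C)
        p["c"] = zeros(C, spec.k - 1)
    elif kind == "melu_plus_galu":
        p["c0"] = zeros(C)
        p["c"] = zeros(C, spec.k - 1)
        p["a"] = zeros(C)
    elif kind == "flexible_melu":
        p["c0"] = zeros(C)
        p["c"] = zeros(C, spec.k - 1)
        ladder = _melu_ladder_for(spec)
        p["centers"] = np.tile(ladder.centers, (C, 1))
    elif kind == "melu_2d":
        p["c0"] = zeros(C)
        p["c2d"] = zeros(C, spec.k - 1, spec.k - 1)
    elif kind == "srs":
        p["alpha"] = np.full(C, 3.0)
        p["beta"] = np.full(C, 2.0)
    elif kind == "soft_learnable":
        p["alpha"] = np.ones(C)
    elif kind == "soft_learnable2":
        p["alpha"] = np.ones(C)
        p["beta"] = np.ones(C)
    # fixed kinds (relu, leaky_relu, elu, selu, swish, mish) carry no params
    return ChannelParams(p, C)


def clamp_params(spec: ActivationSpec, params: ChannelParams) -> None:
    """Enforce parameter constraints in place (SRS alpha, beta >= 1e-6)."""
    if spec.kind in ("srs", "soft_learnable", "soft_learnable2"):
        for key in ("alpha", "beta"):
            if key in params.params:
                np.maximum(params.params[key], _SRS_EPS, out=params.params[key])


# ---------------------------------------------------------------------------
# forward / backward kernels
#
# Each kernel works on x2 of shape (C, M) with per-channel parameter columns
# and returns (y, dy_dx, dparams) where dparams maps a parameter key to the
# pointwise derivative of y with respect to that parameter: shape (C, M) for
# scalar-per-channel parameters and (C, n, M) for vector-per-channel ones.
# 2D MeLU is the one non-elementwise kind and is handled separately.


def _relu_pair(x):
    pos = x >= 0
    return np.where(pos, x, 0.0), pos.astype(float)


def _prelu_pair(x, c0):
    neg = x < 0
    y = np.where(neg, c0 * x, x)
    dyx = np.where(neg, c0, 1.0)
    dc0 = np.where(neg, x, 0.0)
    return y, dyx, dc0


def _hats_eval(x, centers, hws, coeffs, gaussian):
    """Sum of coefficient-weighted hats. centers/hws: (J,) or (C, J);
    coeffs: (C, J); x: (C, M). Returns y (C, M), dy_dx (C, M),
    dy_dc (C, J, M) and, for learnable centers, dy_dcenter (C, J, M)."""
    xe = x[:, None, :]                      # (C, 1, M)
    a = np.atleast_2d(centers)[..., None]   # (C|1, J, 1)
    lam = np.atleast_2d(hws)[..., None]
    d = xe - a
    inside = np.abs(d) < lam
    phi = np.maximum(lam - np.abs(d), 0.0)
    # right-derivative at the peak: -1 for x >= a
    dphi = np.where(inside, np.where(d >= 0, -1.0, 1.0), 0.0)
    if gaussian:
        d2 = xe - (a + 2.0 * lam)
        inside2 = np.abs(d2) < lam
        phi = phi + np.minimum(np.abs(d2) - lam, 0.0)
        dphi = dphi + np.where(inside2, np.where(d2 >= 0, 1.0, -1.0), 0.0)
    ce = coeffs[..., None]                  # (C, J, 1)
    y = np.sum(ce * phi, axis=1)
    dy_dx = np.sum(ce * dphi, axis=1)
    # d phi / d a = -d phi / d x on the support
    return y, dy_dx, phi, -dphi * ce


def _softplus(z):
    return np.logaddexp(0.0, z)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _elementwise_kernel(spec: ActivationSpec, P: dict[str, np.ndarray], x2):
    """Forward + pointwise derivatives for every elementwise kind."""
    kind = spec.kind
    C, M = x2.shape
    col = lambda key: P[key][:, None]  # noqa: E731
    dparams: dict[str, np.ndarray] = {}

    if kind == "relu":
        y, dyx = _relu_pair(x2)
    elif kind == "leaky_relu":
        a = spec.const("a")
        neg = x2 < 0
        y = np.where(neg, a * x2, x2)
        dyx = np.where(neg, a, 1.0)
    elif kind == "prelu":
        y, dyx, dc0 = _prelu_pair(x2, col("c0"))
        dparams["c0"] = dc0
    elif kind == "elu":
        a = spec.const("a")
        neg = x2 < 0
        ex = np.exp(np.minimum(x2, 0.0))
        y = np.where(neg, a * (ex - 1.0), x2)
        dyx = np.where(neg, a * ex, 1.0)
    elif kind == "selu":
        lam, a = spec.const("lambda"), spec.const("alpha")
        neg = x2 < 0
        ex = np.exp(np.minimum(x2, 0.0))
        y = lam * np.where(neg, a * (ex - 1.0), x2)
        dyx = lam * np.where(neg, a * ex, 1.0)
    elif kind == "pdelu":
        t = spec.const("t")
        alpha = col("alpha")
        q = 1.0 / (1.0 - t)
        base = np.maximum(1.0 + (1.0 - t) * x2, 0.0)
        pos = x2 > 0
        neg_val = base ** q - 1.0
        y = np.where(pos, x2, alpha * neg_val)
        dyx = np.where(pos, 1.0, alpha * base ** (q - 1.0))
        dparams["alpha"] = np.where(pos, 0.0, neg_val)
    elif kind in ("swish", "swish_learnable"):
        beta = col("beta") if kind == "swish_learnable" else spec.const("beta")
        s = _sigmoid(beta * x2)
        y = x2 * s
        dyx = s + beta * x2 * s * (1.0 - s)
        if kind == "swish_learnable":
            dparams["beta"] = x2 * x2 * s * (1.0 - s)
    elif kind in ("mish", "mish_learnable"):
        alpha = col("alpha") if kind == "mish_learnable" else spec.const("alpha")
        sp = _softplus(alpha * x2)
        th = np.tanh(sp)
        sig = _sigmoid(alpha * x2)
        y = x2 * th
        dyx = th + x2 * (1.0 - th ** 2) * sig * alpha
        if kind == "mish_learnable":
            dparams["alpha"] = x2 * (1.0 - th ** 2) * sig * x2
    elif kind == "tanelu":
        a = col("a")
        r, dr = _relu_pair(x2)
        th = np.tanh(x2)
        y = r + a * th
        dyx = dr + a * (1.0 - th ** 2)
        dparams["a"] = th
    elif kind == "srelu":
        a_l, a_r = col("a_l"), col("a_r")
        t_l, t_r = col("t_l"), col("t_r")
        lo = x2 <= t_l
        hi = x2 >= t_r
        y = np.where(lo, t_l + a_l * (x2 - t_l), np.where(hi, t_r + a_r * (x2 - t_r), x2))
        dyx = np.where(lo, a_l, np.where(hi, a_r, 1.0))
        z = np.zeros_like(x2)
        dparams["a_l"] = np.where(lo, x2 - t_l, z)
        dparams["t_l"] = np.where(lo, 1.0 - a_l, z)
        dparams["a_r"] = np.where(hi, x2 - t_r, z)
        dparams["t_r"] = np.where(hi, 1.0 - a_r, z)
    elif kind == "aplu":
        a, b = P["a"][:, :, None], P["b"][:, :, None]    # (C, n, 1)
        xe = x2[:, None, :]
        hinge = np.maximum(b - xe, 0.0)                  # (C, n, M)
        active = (xe < b).astype(float)
        r, dr = _relu_pair(x2)
        y = r + np.sum(a * hinge, axis=1)
        dyx = dr - np.sum(a * active, axis=1)
        dparams["a"] = hinge
        dparams["b"] = a * active
    elif kind == "splash":
        ap, an = P["a_pos"][:, :, None], P["a_neg"][:, :, None]
        b = P["b"][:, :, None]
        xe = x2[:, None, :]
        hp = np.maximum(b - xe, 0.0)
        actp = (xe < b).astype(float)
        hn = np.maximum(b + xe, 0.0)
        actn = (-xe < b).astype(float)
        rp, drp = _relu_pair(x2)
        rn, drn = _relu_pair(-x2)
        y = rp + rn + np.sum(ap * hp + an * hn, axis=1)
        dyx = drp - drn + np.sum(-ap * actp + an * actn, axis=1)
        dparams["a_pos"] = hp
        dparams["a_neg"] = hn
        dparams["b"] = ap * actp + an * actn
    elif kind in ("melu", "small_galu", "galu"):
        gaussian = kind != "melu"
        ladder = _galu_ladder_for(spec) if gaussian else _melu_ladder_for(spec)
        yp, dyxp, dc0 = _prelu_pair(x2, col("c0"))
        yh, dyxh, phi, _ = _hats_eval(x2, ladder.centers, ladder.half_widths,
                                      P["c"], gaussian)
        y = yp + yh
        dyx = dyxp + dyxh
        dparams["c0"] = dc0
        dparams["c"] = phi
    elif kind == "flexible_melu":
        ladder = _melu_ladder_for(spec)
        yp, dyxp, dc0 = _prelu_pair(x2, col("c0"))
        yh, dyxh, phi, dcen = _hats_eval(x2, P["centers"], ladder.half_widths,
                                         P["c"], gaussian=False)
        y = yp + yh
        dyx = dyxp + dyxh
        dparams["c0"] = dc0
        dparams["c"] = phi
        dparams["centers"] = dcen
    elif kind in ("symmetric_melu", "symmetric_galu"):
        gaussian = kind == "symmetric_galu"
        ladder = _galu_ladder_for(spec) if gaussian else _melu_ladder_for(spec)
        c0 = col("c0")
        y_list, dyx_acc, dc0_acc, dc_acc = [], 0.0, 0.0, 0.0
        for sign in (1.0, -1.0):
            xs = sign * x2
            yp, dyxp, dc0 = _prelu_pair(xs, c0)
            yh, dyxh, phi, _ = _hats_eval(xs, ladder.centers,
                                          ladder.half_widths, P["c"], gaussian)
            y_list.append(yp + yh)
            dyx_acc = dyx_acc + sign * (dyxp + dyxh)
            dc0_acc = dc0_acc + dc0
            dc_acc = dc_acc + phi
        y = y_list[0] + y_list[1]
        dyx = dyx_acc
        dparams["c0"] = dc0_acc
        dparams["c"] = dc_acc
    elif kind == "melu_plus_galu":
        mel = _melu_ladder_for(spec)
        gal = derive_galu_ladder(mel)
        a = col("a")
        yp, dyxp, dc0 = _prelu_pair(x2, col("c0"))
        ym, dyxm, phim, _ = _hats_eval(x2, mel.centers, mel.half_widths,
                                       P["c"], gaussian=False)
        yg, dyxg, phig, _ = _hats_eval(x2, gal.centers, gal.half_widths,
                                       P["c"], gaussian=True)
        y = yp + (1.0 - a) * ym + a * yg
        dyx = dyxp + (1.0 - a) * dyxm + a * dyxg
        dparams["c0"] = dc0
        dparams["c"] = (1.0 - a[:, None, :]) * phim + a[:, None, :] * phig
        dparams["a"] = yg - ym
    elif kind == "srs":
        alpha, beta = col("alpha"), col("beta")
        e = np.exp(-x2 / beta)
        D = x2 / alpha + e
        y = x2 / D
        dyx = (D - x2 * (1.0 / alpha - e / beta)) / D ** 2
        dparams["alpha"] = x2 ** 2 / (alpha ** 2 * D ** 2)
        dparams["beta"] = -(x2 ** 2) * e / (beta ** 2 * D ** 2)
    elif kind in ("soft_learnable", "soft_learnable2"):
        alpha = col("alpha")
        beta = col("beta") if kind == "soft_learnable2" else spec.const("beta")
        pos = x2 > 0
        xn = np.minimum(x2, 0.0)
        ebx = np.exp(beta * xn)
        lg = np.log1p(ebx) - np.log(2.0)
        sig = ebx / (1.0 + ebx)
        y = np.where(pos, x2, alpha * lg)
        dyx = np.where(pos, 1.0, alpha * beta * sig)
        dparams["alpha"] = np.where(pos, 0.0, lg)
        if kind == "soft_learnable2":
            dparams["beta"] = np.where(pos, 0.0, alpha * xn * sig)
    else:  # pragma: no cover
        raise ValueError(f"unknown activation kind {kind!r}")
    return y, dyx, dparams


def _melu2d_forward(spec, P, x2, need_grad):
    """2D MeLU: output channel i depends on input channels i and i+1 (cyclic).

    y_i = PReLU(x_i) + PReLU(x_{i+1}) + sum_{u,v} c_{u,v} *
          max(lam_{max(u,v)} - ||(x_i, x_{i+1}) - (a_u, a_v)||_2, 0)
    """
    C, M = x2.shape
    ladder = _melu_ladder_for(spec)
    a = ladder.centers
    lam_grid = np.maximum.outer(np.arange(a.size), np.arange(a.size))
    lam = ladder.half_widths[lam_grid]                  # (J, J)
    c0 = P["c0"][:, None]
    c2d = P["c2d"]                                      # (C, J, J)
    nxt = np.roll(np.arange(C), -1)
    x_b = x2[nxt]                                       # paired channel values

    yp_a, dyx_a, dc0_a = _prelu_pair(x2, c0)
    yp_b, dyx_b, dc0_b = _prelu_pair(x_b, P["c0"][nxt][:, None])  # c0 of paired channel
    # distance of (x_i, x_{i+1}) to every grid center
    da = x2[:, None, None, :] - a[None, :, None, None]   # (C, J, 1, M)
    db = x_b[:, None, None, :] - a[None, None, :, None]  # (C, 1, J, M)
    r = np.sqrt(da ** 2 + db ** 2)                       # (C, J, J, M)
    phi = np.maximum(lam[None, :, :, None] - r, 0.0)
    y = yp_a + yp_b + np.einsum("cuv,cuvm->cm", c2d, phi)
    if not need_grad:
        return y, None
    inside = (r < lam[None, :, :, None]) & (r > 0)
    w = np.where(inside, -1.0 / np.where(r == 0, 1.0, r), 0.0) * c2d[..., None]
    dy_dxa = dyx_a + np.sum(w * da, axis=(1, 2))         # d y_i / d x_i
    dy_dxb = dyx_b + np.sum(w * db, axis=(1, 2))         # d y_i / d x_{i+1}
    grads = {"phi": phi, "dy_dxa": dy_dxa, "dy_dxb": dy_dxb,
             "dc0_a": dc0_a, "dc0_b": dc0_b, "nxt": nxt}
    return y, grads


def _as_2d(x):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[:, None], True
    if x.ndim == 2:
        return x, False
    raise ValueError("x must be (n_channels,) or (n_channels, m)")


def _check_params(spec: ActivationSpec, params: ChannelParams, C: int) -> None:
    if params.n_channels != C:
        raise ValueError(f"params have {params.n_channels} channels, x has {C}")
    expected = set(spec.param_keys)
    got = set(params.params)
    if expected != got:
        raise ValueError(
            f"parameter keys {sorted(got)} do not match kind {spec.kind!r} "
            f"(expected {sorted(expected)})")


def eval_activation(spec: ActivationSpec, params: ChannelParams, x) -> np.ndarray:
    """Forward value of the activation, channel-wise parameterized.

    ``x`` has shape ``(n_channels,)`` or ``(n_channels, m)``.  All kinds are
    elementwise except ``melu_2d``, whose output channel ``i`` mixes input
    channels ``i`` and ``i+1`` (cyclically).
    """
    x2, squeeze = _as_2d(x)
    _check_params(spec, params, x2.shape[0])
    if spec.kind == "melu_2d":
        y, _ = _melu2d_forward(spec, params.params, x2, need_grad=False)
    else:
        y, _, _ = _elementwise_kernel(spec, params.params, x2)
    return y[:, 0] if squeeze else y


def grad_activation(spec: ActivationSpec, params: ChannelParams, x,
                    upstream=None) -> GradBundle:
    """Analytic gradients of the activation as a vector-Jacobian product.

    With ``upstream = g`` (defaults to ones), ``d_input`` is the gradient of
    ``sum(g * y)`` with respect to ``x`` and ``d_params[key]`` with respect to
    the corresponding learnable parameter.  For elementwise kinds and unit
    upstream, ``d_input`` equals the pointwise derivative ``dy_i/dx_i``.
    """
    x2, squeeze = _as_2d(x)
    C, M = x2.shape
    _check_params(spec, params, C)
    if upstream is None:
        g = np.ones_like(x2)
    else:
        g, _ = _as_2d(upstream)
        if g.shape != x2.shape:
            raise ValueError("upstream shape must match x")

    d_params: dict[str, np.ndarray] = {}
    if spec.kind == "melu_2d":
        _, gr = _melu2d_forward(spec, params.params, x2, need_grad=True)
        nxt = gr["nxt"]
        d_input = g * gr["dy_dxa"]
        contrib_b = g * gr["dy_dxb"]
        np.add.at(d_input, nxt, contrib_b)
        dc0 = np.sum(g * gr["dc0_a"], axis=1)
        np.add.at(dc0, nxt, np.sum(g * gr["dc0_b"], axis=1))
        d_params["c0"] = dc0
        d_params["c2d"] = np.einsum("cm,cuvm->cuv", g, gr["phi"])
    else:
        _, dyx, dps = _elementwise_kernel(spec, params.params, x2)
        d_input = g * dyx
        for key, arr in dps.items():
            if arr.ndim == 2:       # scalar-per-channel parameter
                d_params[key] = np.sum(g * arr, axis=1)
            else:                   # (C, n, M) vector-per-channel parameter
                d_params[key] = np.einsum("cm,cnm->cn", g, arr)
    return GradBundle(d_input[:, 0] if squeeze else d_input, d_params)
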