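"""Finite-difference oracle for activation gradients.

Independent of the analytic backward path: perturbs inputs and parameters of
``eval_activation`` directly and compares central differences against
``grad_activation``.  Sample points are drawn away from every
non-differentiability (kinks at 0, hinge points, ladder knots, SReLU
thresholds, 2D-MeLU support circles).
"""

from __future__ import annotations

import numpy as np

from afens.activations import (ActivationSpec, ChannelParams,
                               build_melu_ladder, derive_galu_ladder,
                               eval_activation, grad_activation, init_params)

MIN_KINK_DIST = 1e-3


def random_params(spec: ActivationSpec, n_channels: int,
                  rng: np.random.Generator) -> ChannelParams:
    """Plausible random learnable parameters for one kind."""
    p = init_params(spec, n_channels, seed=int(rng.integers(2 ** 31)))
    for key, v in p.params.items():
        if spec.kind == "srs" and key in ("alpha", "beta"):
            p.params[key] = rng.uniform(1.5, 4.0, v.shape)
        elif spec.kind in ("soft_learnable", "soft_learnable2") and key in ("alpha", "beta"):
            p.params[key] = rng.uniform(0.5, 2.0, v.shape)
        elif key == "b":
            p.params[key] = rng.uniform(0.1, spec.max_input, v.shape)
        elif key == "t_l":
            p.params[key] = rng.uniform(-2.5, -0.5, v.shape)
        elif key == "t_r":
            p.params[key] = rng.uniform(0.5, 2.5, v.shape)
        elif key in ("a_l", "a_r"):
            p.params[key] = rng.normal(0.3, 0.2, v.shape)
        elif key == "centers":
            p.params[key] = v + rng.normal(0.0, 0.05, v.shape)
        else:
            p.params[key] = v + rng.normal(0.0, 0.4, v.shape)
    return p


def _hat_knots(centers, hws, gaussian):
    centers = np.asarray(centers, dtype=float)
    hws = np.asarray(hws, dtype=float)
    knots = [centers - hws, centers, centers + hws]
    if gaussian:
        knots += [centers + 2 * hws, centers + 3 * hws]
    return np.concatenate(knots)


def channel_kinks(spec: ActivationSpec, params: ChannelParams, c: int) -> np.ndarray:
    """All non-differentiable input locations for channel c."""
    P = params.params
    kind = spec.kind
    ks = [np.array([0.0])]
    if kind == "pdelu":
        ks.append(np.array([-1.0 / (1.0 - spec.const("t"))]))
    elif kind == "srelu":
        ks.append(np.array([P["t_l"][c], P["t_r"][c]]))
    elif kind == "aplu":
        ks.append(P["b"][c])
    elif kind == "splash":
        ks.append(np.concatenate([P["b"][c], -P["b"][c]]))
    elif kind in ("melu",):
        lad = build_melu_ladder(spec.max_input, spec.k)
        ks.append(_hat_knots(lad.centers, lad.half_widths, False))
    elif kind in ("small_galu", "galu"):
        lad = derive_galu_ladder(build_melu_ladder(spec.max_input, spec.k))
        ks.append(_hat_knots(lad.centers, lad.half_widths, True))
    elif kind == "flexible_melu":
        lad = build_melu_ladder(spec.max_input, spec.k)
        ks.append(_hat_knots(P["centers"][c], lad.half_widths, False))
    elif kind == "melu_plus_galu":
        mel = build_melu_ladder(spec.max_input, spec.k)
        gal = derive_galu_ladder(mel)
        ks.append(_hat_knots(mel.centers, mel.half_widths, False))
        ks.append(_hat_knots(gal.centers, gal.half_widths, True))
    elif kind in ("symmetric_melu", "symmetric_galu"):
        gaussian = kind == "symmetric_galu"
        lad = build_melu_ladder(spec.max_input, spec.k)
        if gaussian:
            lad = derive_galu_ladder(lad)
        kn = _hat_knots(lad.centers, lad.half_widths, gaussian)
        ks.append(np.concatenate([kn, -kn]))
    return np.concatenate(ks)


def _melu2d_valid(spec, x, min_dist):
    lad = build_melu_ladder(spec.max_input, spec.k)
    a = lad.centers
    lam = lad.half_widths[np.maximum.outer(np.arange(a.size), np.arange(a.size))]
    C, M = x.shape
    nxt = np.roll(np.arange(C), -1)
    da = x[:, None, None, :] - a[None, :, None, None]
    db = x[nxt][:, None, None, :] - a[None, None, :, None]
    r = np.sqrt(da ** 2 + db ** 2)
    ok = np.all(np.abs(r - lam[None, :, :, None]) >= min_dist) and np.all(r >= min_dist)
    return ok and np.all(np.abs(x) >= min_dist)


def draw_x(spec: ActivationSpec, params: ChannelParams, n_channels: int,
           m: int, rng: np.random.Generator,
           min_dist: float = MIN_KINK_DIST) -> np.ndarray:
    lo, hi = -3.9 * spec.max_input, 3.9 * spec.max_input
    if spec.kind == "melu_2d":
        for _ in range(2000):
            x = rng.uniform(lo, hi, (n_channels, m))
            if _melu2d_valid(spec, x, min_dist):
                return x
        raise RuntimeError("could not sample away from 2D MeLU kinks")
    x = rng.uniform(lo, hi, (n_channels, m))
    for c in range(n_channels):
        kinks = channel_kinks(spec, params, c)
        for j in range(m):
            for _ in range(1000):
                if np.min(np.abs(x[c, j] - kinks)) >= min_dist:
                    break
                x[c, j] = rng.uniform(lo, hi)
    return x


def max_fd_error(spec: ActivationSpec, params: ChannelParams, x,
                 upstream=None, rng=None) -> float:
    """Max relative error between analytic gradients and central differences.

    The scalar probed is S = sum(upstream * eval_activation(...)); step size
    h = 1e-6 * max(1, |coordinate|).
    """
    x = np.asarray(x, dtype=float)
    if upstream is None:
        upstream = (np.ones_like(x) if rng is None
                    else rng.uniform(0.5, 1.5, x.shape))
    bundle = grad_activation(spec, params, x, upstream=upstream)

    def scalar(xv, pv):
        p2 = ChannelParams({k: v.copy() for k, v in pv.items()}, params.n_channels)
        return float(np.sum(upstream * eval_activation(spec, p2, xv)))

    def rel_err(an, fd):
        return np.abs(fd - an) / np.maximum(1.0, np.abs(fd))

    worst = 0.0
    fd_in = np.zeros_like(x)
    for idx in np.ndindex(*x.shape):
        h = 1e-6 * max(1.0, abs(x[idx]))
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        fd_in[idx] = (scalar(xp, params.params) - scalar(xm, params.params)) / (2 * h)
    worst = max(worst, float(np.max(rel_err(bundle.d_input, fd_in))))
    for key, v in params.params.items():
        fd_p = np.zeros_like(v)
        for idx in np.ndindex(*v.shape):
            h = 1e-6 * max(1.0, abs(v[idx]))
            pp = {k: a.copy() for k, a in params.params.items()}
            pm = {k: a.copy() for k, a in params.params.items()}
            pp[key][idx] += h
            pm[key][idx] -= h
            fd_p[idx] = (scalar(x, pp) - scalar(x, pm)) / (2 * h)
        worst = max(worst, float(np.max(rel_err(bundle.d_params[key], fd_p))))
    return worst


def run_gradient_suite(kind: str, n_draws: int = 50, seed: int = 0,
                       n_channels: int = 2, m: int = 1) -> float:
    """Worst relative FD error over seeded random (x, params) draws."""
    from afens.activations import get_spec
    spec = get_spec(kind, max_input=1.0)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        params = random_params(spec, n_channels, rng)
        x = draw_x(spec, params, n_channels, m, rng)
        worst = max(worst, max_fd_error(spec, params, x, rng=rng))
    return worst
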