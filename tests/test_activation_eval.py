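"""Forward semantics of the activation catalogue."""

import numpy as np
import pytest
from scipy.integrate import quad

from afens.activations import (ACTIVATION_KINDS, ChannelParams,
                               build_melu_ladder, eval_activation, get_spec,
                               hat_eval, init_params)

from gradcheck import random_params

GRID = np.linspace(-8, 8, 10_000)


def _eval1(spec, params, xs):
    """Evaluate a 1-channel spec on a vector of points."""
    return eval_activation(spec, params, np.asarray(xs, dtype=float)[None, :])[0]


# ---------------------------------------------------------------------------
# hat basis


def test_hat_pointwise_values():
    assert hat_eval(2.0, a=2.0, lam=2.0) == 2.0          # peak equals lam
    assert hat_eval(5.0, a=2.0, lam=2.0) == 0.0          # outside support
    assert hat_eval(2.0, a=0.0, lam=1.0, variant="gaussian") == -1.0  # trough
    assert hat_eval(1.0, a=0.0, lam=1.0, variant="gaussian") == 0.0   # crossing


def test_hat_rejects_nonpositive_width():
    with pytest.raises(ValueError):
        hat_eval(0.0, a=0.0, lam=0.0)


@pytest.mark.parametrize("a,lam", [(0.0, 1.0), (2.0, 0.5), (-1.0, 2.0)])
def test_hat_supports(a, lam):
    x = np.linspace(a - 5 * lam, a + 5 * lam, 4001)
    mex = hat_eval(x, a, lam)
    assert np.all(mex[np.abs(x - a) > lam] == 0.0)
    gau = hat_eval(x, a, lam, variant="gaussian")
    outside = (x < a - lam) | (x > a + 3 * lam)
    assert np.all(gau[outside] == 0.0)


def test_gaussian_hat_integrates_to_zero():
    for a, lam in [(0.0, 1.0), (1.0, 0.5), (-2.0, 2.0)]:
        val, err = quad(lambda t: hat_eval(t, a, lam, variant="gaussian"),
                        a - lam, a + 3 * lam, limit=200)
        assert abs(val) < 1e-8


# ---------------------------------------------------------------------------
# pointwise plug-in examples


def test_relu_and_leaky_values():
    relu = get_spec("relu")
    p = init_params(relu, 1, 0)
    assert _eval1(relu, p, [-3.0, 4.0]).tolist() == [0.0, 4.0]
    leaky = get_spec("leaky_relu")
    assert _eval1(leaky, init_params(leaky, 1, 0), [-2.0])[0] == pytest.approx(-0.02)


def test_elu_value():
    elu = get_spec("elu")
    val = _eval1(elu, init_params(elu, 1, 0), [-1.0])[0]
    assert val == pytest.approx(np.exp(-1) - 1, abs=1e-12)


def test_prelu_value():
    spec = get_spec("prelu")
    p = ChannelParams({"c0": np.array([0.25])}, 1)
    assert _eval1(spec, p, [-2.0])[0] == pytest.approx(-0.5)


def test_melu_matches_direct_hat_summation():
    """MeLU forward equals PReLU + explicit coefficient-weighted hat sum."""
    spec = get_spec("melu", max_input=256.0, k=8)
    rng = np.random.default_rng(4)
    c0 = rng.normal(0, 0.2, 1)
    c = rng.normal(0, 0.5, (1, 7))
    p = ChannelParams({"c0": c0, "c": c}, 1)
    xs = np.linspace(-300, 1100, 100)
    got = _eval1(spec, p, xs)
    lad = build_melu_ladder(256.0, 8)
    expected = np.where(xs < 0, c0[0] * xs, xs)
    for j in range(7):
        expected = expected + c[0, j] * hat_eval(xs, lad.centers[j],
                                                 lad.half_widths[j])
    np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)


def test_melu_2d_zero_params_sums_paired_relus():
    spec = get_spec("melu_2d", k=8)
    p = init_params(spec, 3, 0)
    x = np.array([[-1.0, 2.0], [3.0, -4.0], [0.5, 1.5]])
    y = eval_activation(spec, p, x)
    relu = np.maximum(x, 0)
    expected = relu + relu[np.roll(np.arange(3), -1)]
    np.testing.assert_array_equal(y, expected)


# ---------------------------------------------------------------------------
# init semantics


RELU_AT_INIT = ["melu", "small_galu", "galu", "aplu", "tanelu",
                "melu_plus_galu", "flexible_melu"]


@pytest.mark.parametrize("kind", RELU_AT_INIT)
def test_relu_equivalence_at_init(kind):
    spec = get_spec(kind, max_input=1.0)
    p = init_params(spec, 1, seed=9)
    y = _eval1(spec, p, GRID)
    np.testing.assert_array_equal(y, np.maximum(GRID, 0.0))


@pytest.mark.parametrize("kind", ["symmetric_melu", "symmetric_galu"])
def test_symmetric_kinds_are_abs_at_init(kind):
    spec = get_spec(kind)
    p = init_params(spec, 1, seed=9)
    np.testing.assert_array_equal(_eval1(spec, p, GRID), np.abs(GRID))


def test_aplu_hinges_seeded_deterministic():
    spec = get_spec("aplu", max_input=255.0)
    p1 = init_params(spec, 2, seed=13)
    p2 = init_params(spec, 2, seed=13)
    np.testing.assert_array_equal(p1["b"], p2["b"])
    assert np.all((p1["b"] > 0) & (p1["b"] < 255))


def test_init_rejects_bad_channel_count():
    with pytest.raises(ValueError):
        init_params(get_spec("melu"), 0, seed=0)


# ---------------------------------------------------------------------------
# structural properties


@pytest.mark.parametrize("kind", ["symmetric_melu", "symmetric_galu"])
def test_evenness(kind):
    spec = get_spec(kind)
    rng = np.random.default_rng(11)
    for _ in range(5):
        p = random_params(spec, 2, rng)
        x = rng.uniform(-4, 4, (2, 64))
        y_pos = eval_activation(spec, p, x)
        y_neg = eval_activation(spec, p, -x)
        np.testing.assert_allclose(y_pos, y_neg, atol=1e-12, rtol=0)


def test_swish_approaches_relu_at_large_beta():
    spec = get_spec("swish", beta=50.0)
    p = init_params(spec, 1, 0)
    xs = np.concatenate([np.linspace(-8, -1, 200), np.linspace(1, 8, 200)])
    diff = np.abs(_eval1(spec, p, xs) - np.maximum(xs, 0.0))
    assert np.max(diff) < 1e-6


@pytest.mark.parametrize("kind", ["pdelu", "srs", "soft_learnable",
                                  "soft_learnable2", "elu", "selu"])
def test_zero_maps_to_zero_exactly(kind):
    spec = get_spec(kind)
    p = init_params(spec, 1, 0)
    assert _eval1(spec, p, [0.0])[0] == 0.0


def test_mismatched_params_rejected():
    spec = get_spec("melu")
    wrong = init_params(get_spec("prelu"), 1, 0)
    with pytest.raises(ValueError):
        eval_activation(spec, wrong, np.zeros((1, 4)))
    good = init_params(spec, 2, 0)
    with pytest.raises(ValueError):
        eval_activation(spec, good, np.zeros((3, 4)))


def test_every_registry_kind_evaluates():
    rng = np.random.default_rng(21)
    x = rng.uniform(-2, 2, (2, 16))
    for kind in ACTIVATION_KINDS:
        spec = get_spec(kind)
        p = init_params(spec, 2, seed=1)
        y = eval_activation(spec, p, x)
        assert y.shape == x.shape and np.all(np.isfinite(y))
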