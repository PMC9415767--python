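"""Augmentation, learning-rate schedule, regularization, and training loop."""

import numpy as np
import pytest

from afens.activations import ChannelParams, get_spec, init_params
from afens.surgery import sample_replacement_plan, tiny_net_graph
from afens.training import (TinyNetModel, TrainConfig, aplu_regularization,
                            augment_image, build_lr_schedule, load_image_dataset,
                            predict_proba, rescale_factors, train_model)


# ---------------------------------------------------------------------------
# augmentation


def test_augment_constant_image_is_identity():
    img = np.full((24, 24), 0.37)
    out = augment_image(img, seed=5)
    assert out.shape == img.shape
    np.testing.assert_allclose(out, img, atol=1e-6)


def test_augment_seeded_determinism():
    rng = np.random.default_rng(3)
    img = rng.uniform(0, 1, (32, 32))
    np.testing.assert_array_equal(augment_image(img, 11), augment_image(img, 11))


def test_augment_rejects_empty():
    with pytest.raises(ValueError):
        augment_image(np.empty((0, 0)), 0)


def test_rescale_factor_distribution():
    rng = np.random.default_rng(0)
    fs = np.array([rescale_factors(rng) for _ in range(10_000)]).ravel()
    assert fs.min() >= 1.0 and fs.max() <= 2.0
    sigma = np.sqrt(1 / 12 / fs.size)
    assert abs(fs.mean() - 1.5) < 3 * sigma


# ---------------------------------------------------------------------------
# schedule and regularizer


def test_final_layer_rate_20x():
    g = tiny_net_graph()
    cfg = TrainConfig(base_lr=1e-4, final_layer_lr_multiplier=20.0)
    lrs = build_lr_schedule(cfg, g)
    assert lrs["layer:fc"] == pytest.approx(2e-3)
    assert lrs["layer:conv1"] == pytest.approx(1e-4)


def test_aplu_slope_relative_rate():
    g = tiny_net_graph()
    plan = sample_replacement_plan(g, [get_spec("aplu", max_input=255.0)], seed=0)
    cfg = TrainConfig(base_lr=1e-4)
    lrs = build_lr_schedule(cfg, g, plan)
    assert lrs["site:act1:a"] == pytest.approx(1e-4 / 255.0)
    assert lrs["site:act1:b"] == pytest.approx(1e-4)


def test_unit_multiplier_gives_uniform_rates():
    g = tiny_net_graph()
    cfg = TrainConfig(base_lr=5e-4, final_layer_lr_multiplier=1.0)
    lrs = build_lr_schedule(cfg, g)
    layer_rates = [v for k, v in lrs.items() if k.startswith("layer:")]
    assert all(v == pytest.approx(5e-4) for v in layer_rates)


def test_aplu_regularization_values():
    p = ChannelParams({"a": np.array([[0.1], [-0.2]]),
                       "b": np.array([[0.5], [0.7]])}, 2)
    assert aplu_regularization(p, 0.001) == pytest.approx(5e-5)
    assert aplu_regularization(p, 0.0) == 0.0
    zero = ChannelParams({"a": np.zeros((2, 3)), "b": np.ones((2, 3))}, 2)
    assert aplu_regularization(zero, 0.001) == 0.0
    splash = init_params(get_spec("splash"), 2, 0)
    splash.params["a_pos"] += 0.1
    assert aplu_regularization(splash, 1.0) == pytest.approx(2 * 5 * 0.01)


def test_aplu_regularization_rejects_other_kinds():
    with pytest.raises(ValueError):
        aplu_regularization(init_params(get_spec("melu"), 2, 0), 0.001)


# ---------------------------------------------------------------------------
# training loop


def test_training_descends_and_is_deterministic(toy_split, graph, fast_config):
    plan = sample_replacement_plan(graph, [get_spec("relu")], seed=0)
    model, trace = train_model(graph, plan, toy_split.train, fast_config)
    assert trace["loss"].iloc[-1] < trace["loss"].iloc[0]
    assert np.all(np.isfinite(trace["loss"]))
    _, trace2 = train_model(graph, plan, toy_split.train, fast_config)
    np.testing.assert_array_equal(trace["loss"].to_numpy(),
                                  trace2["loss"].to_numpy())


def test_melu_plan_matches_relu_loss_before_updates(toy_split, graph, fast_config):
    """Same weight init => identical first forward pass, since MeLU == ReLU
    at init."""
    from afens.surgery import apply_plan
    X, y = toy_split.train.X[:32], toy_split.train.y[:32]
    for kind in ("melu", "relu"):
        plan = sample_replacement_plan(graph, [get_spec(kind, 255.0, k=8)
                                               if kind == "melu"
                                               else get_spec("relu")], seed=0)
        model = TinyNetModel(apply_plan(graph, plan, seed=2), X.shape[1:], 4,
                             seed=123)
        loss, *_ = model.loss_and_grads(X, y)
        if kind == "melu":
            melu_loss = loss
    assert melu_loss == loss


def test_single_class_dataset_rejected(graph, fast_config):
    from afens.training import ImageDataset
    X = np.zeros((10, 1, 32, 32))
    y = np.zeros(10, dtype=int)
    plan = sample_replacement_plan(graph, [get_spec("relu")], seed=0)
    with pytest.raises(ValueError):
        train_model(graph, plan, ImageDataset(X, y), fast_config)


def test_learnable_site_params_move_during_training(toy_split, graph):
    """Training actually updates activation parameters, not just weights."""
    cfg = TrainConfig(batch_size=30, base_lr=0.01,
                      final_layer_lr_multiplier=2.0, epochs=3, seed=1)
    plan = sample_replacement_plan(graph, [get_spec("prelu")], seed=0)
    model, _ = train_model(graph, plan, toy_split.train, cfg)
    moved = [np.abs(model.sites[s][1]["c0"]).max() for s in model.sites]
    assert max(moved) > 0


def test_png_dataset_roundtrip(tmp_path):
    from afens.synthetic import ToySpec, make_toy_dataset
    spec = ToySpec(n_classes=2, samples_per_class=3, image_size=16,
                   sigma=0.0, seed=1)
    make_toy_dataset(spec, tmp_path)
    ds = load_image_dataset(tmp_path)
    assert ds.X.shape == (6, 1, 16, 16)
    assert list(np.bincount(ds.y)) == [3, 3]
    assert ds.class_names == ("class_00", "class_01")
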