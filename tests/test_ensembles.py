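"""Sum-rule fusion, SFFS selection, and named recipes."""

import itertools

import numpy as np
import pytest

from afens.ensembles import (ProbabilityMatrix, member_key, recipe_ensemble,
                             recipe_members, sffs_select, sum_rule_fuse)
from afens.evaluation import accuracy
from afens.synthetic import make_probability_fixtures


def _pm(rows, model_id=""):
    return ProbabilityMatrix(np.asarray(rows, dtype=float), model_id=model_id)


# ---------------------------------------------------------------------------
# fusion


def test_fusion_idempotent_on_identical_members():
    m = _pm([[0.7, 0.3], [0.2, 0.8]])
    fused = sum_rule_fuse([m, m])
    np.testing.assert_allclose(fused.values, m.values)
    fused15 = sum_rule_fuse([m] * 15)
    np.testing.assert_allclose(fused15.values, m.values)


def test_fusion_averages_rows():
    fused = sum_rule_fuse([_pm([[1.0, 0.0]]), _pm([[0.0, 1.0]])])
    np.testing.assert_allclose(fused.values, [[0.5, 0.5]])


def test_fusion_permutation_invariant_and_row_stochastic():
    rng = np.random.default_rng(0)
    members = [ProbabilityMatrix(rng.dirichlet(np.ones(5), size=40),
                                 model_id=str(i)) for i in range(6)]
    fused = sum_rule_fuse(members)
    shuffled = sum_rule_fuse(members[::-1])
    np.testing.assert_allclose(fused.values, shuffled.values, atol=1e-15)
    assert np.max(np.abs(fused.values.sum(axis=1) - 1)) < 1e-9


def test_fusion_rejects_bad_input():
    with pytest.raises(ValueError):
        sum_rule_fuse([])
    with pytest.raises(ValueError):
        sum_rule_fuse([_pm([[1.0, 0.0]]), _pm([[1, 0, 0]])])


def test_probability_matrix_validates_rows():
    with pytest.raises(ValueError):
        ProbabilityMatrix(np.array([[0.5, 0.4]]))
    with pytest.raises(ValueError):
        ProbabilityMatrix(np.array([[1.2, -0.2]]))


def test_probability_matrix_csv_roundtrip(tmp_path):
    m = _pm([[0.25, 0.75], [0.6, 0.4]], model_id="m0")
    path = tmp_path / "m0.csv"
    m.to_csv(path)
    back = ProbabilityMatrix.from_csv(path)
    np.testing.assert_allclose(back.values, m.values)


# ---------------------------------------------------------------------------
# SFFS


def test_sffs_returns_dominant_single_candidate():
    mats, labels = make_probability_fixtures(3, 400, 4, [1.0, 0.3, 0.3], seed=1)
    chosen = sffs_select(mats, labels)
    fused_acc = accuracy(sum_rule_fuse([mats[i] for i in chosen]), labels)
    assert 0 in chosen and fused_acc == 100.0


def test_sffs_excludes_harmful_random_model():
    mats, labels = make_probability_fixtures(2, 500, 4, [1.0, 0.25], seed=2)
    chosen = sffs_select(mats, labels)
    assert chosen == [0]


def test_sffs_never_below_best_single_and_oracle_comparison():
    """On <= 8 candidates, SFFS's fused accuracy is at least the best single
    model's; the exhaustive best subset bounds it from above."""
    rng_targets = [0.85, 0.7, 0.6, 0.55, 0.5, 0.45, 0.4, 0.35]
    mats, labels = make_probability_fixtures(8, 400, 4, rng_targets, seed=3)
    chosen = sffs_select(mats, labels)
    sffs_acc = accuracy(sum_rule_fuse([mats[i] for i in chosen]), labels)
    singles = [accuracy(m, labels) for m in mats]
    assert sffs_acc >= max(singles)
    best_subset_acc = max(
        accuracy(sum_rule_fuse([mats[i] for i in sub]), labels)
        for r in range(1, 9) for sub in itertools.combinations(range(8), r))
    assert sffs_acc <= best_subset_acc + 1e-12


def test_sffs_multi_context_objective():
    """Leave-one-context-out style: objective is the mean over contexts."""
    mats_a, labels_a = make_probability_fixtures(3, 300, 3, [0.9, 0.6, 0.4],
                                                 seed=4)
    mats_b, labels_b = make_probability_fixtures(3, 300, 3, [0.85, 0.65, 0.35],
                                                 seed=5)
    per_model = [[mats_a[i], mats_b[i]] for i in range(3)]
    chosen = sffs_select(per_model, [labels_a, labels_b])
    assert 0 in chosen
    mean_acc = np.mean([
        accuracy(sum_rule_fuse([per_model[i][ctx] for i in chosen]), lab)
        for ctx, lab in enumerate([labels_a, labels_b])])
    best_single = max(np.mean([accuracy(per_model[i][0], labels_a),
                               accuracy(per_model[i][1], labels_b)])
                      for i in range(3))
    assert mean_acc >= best_single


def test_sffs_rejects_degenerate_input():
    with pytest.raises(ValueError):
        sffs_select([], [])
    mats, labels = make_probability_fixtures(2, 100, 3, [0.5, 0.5], seed=0)
    with pytest.raises(ValueError):
        sffs_select(mats, labels[:50])


# ---------------------------------------------------------------------------
# recipes


def test_ens_member_lists():
    assert recipe_members("ENS", 1) == [
        member_key(m, 1) for m in ("melu_k8", "leaky_relu", "elu", "melu_k4",
                                   "prelu", "srelu", "aplu", "relu")]
    assert recipe_members("ENS", 255) == [
        member_key(m, 255) for m in ("melu_k8", "melu_k4", "srelu", "aplu",
                                     "relu")]


def test_ens_g_adds_galu_kinds():
    ens = set(recipe_members("ENS", 1))
    ens_g = set(recipe_members("ENS_G", 1))
    assert ens_g - ens == {member_key("small_galu", 1), member_key("galu", 1)}


def test_eens_spans_both_scales():
    keys = recipe_members("eENS", 1)
    assert member_key("melu_k8", 1) in keys and member_key("melu_k8", 255) in keys
    assert len(keys) == 8 + 5


def test_recipe_fusion_and_missing_member():
    rng = np.random.default_rng(7)
    registry = {k: ProbabilityMatrix(rng.dirichlet(np.ones(3), size=20), k)
                for k in recipe_members("ENS", 1)}
    fused = recipe_ensemble("ENS", registry, max_input=1)
    assert fused.values.shape == (20, 3)
    registry.pop(member_key("relu", 1))
    with pytest.raises(KeyError):
        recipe_ensemble("ENS", registry, max_input=1)


def test_15relu_recipe_of_identical_models_matches_single():
    m = _pm(np.tile([0.6, 0.4], (10, 1)))
    registry = {member_key(f"relu#{j}", 1): m for j in range(15)}
    fused = recipe_ensemble("15ReLU", registry, max_input=1)
    np.testing.assert_allclose(fused.values, m.values)


def test_selection_recipe_runs_sffs():
    mats, labels = make_probability_fixtures(4, 300, 3, [0.9, 0.5, 0.5, 0.4],
                                             seed=8)
    registry = {f"m{i}": m for i, m in enumerate(mats)}
    fused = recipe_ensemble("Selection", registry, labels=labels)
    assert accuracy(fused, labels) >= max(accuracy(m, labels) for m in mats)
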