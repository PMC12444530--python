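"""Linear, robust and tree-ensemble regression models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from enthalpograph.errors import NotFittedError, RankDeficiencyError
from enthalpograph.models import (
    ForestConfig,
    ForestModel,
    HuberConfig,
    eq13_predict,
    fixed_index_model,
    forest_fit,
    huber_fit,
    impurity_importance,
    model_from_json,
    model_to_json,
    ols_fit,
    ridge_fit,
    tree_fit,
)

# ---------------------------------------------------------------------------
# fixed-coefficient predictor
# ---------------------------------------------------------------------------


def test_fixed_equation_intercept_and_coefficients():
    assert eq13_predict(0, 0, 0) == pytest.approx(-417.6882)
    assert eq13_predict(1, 0, 0) - eq13_predict(0, 0, 0) == pytest.approx(90.0)
    assert eq13_predict(0, 1, 0) - eq13_predict(0, 0, 0) == pytest.approx(-1.0789)
    assert eq13_predict(0, 0, 1) - eq13_predict(0, 0, 0) == pytest.approx(0.2822)


def test_fixed_equation_benzene():
    # benzene indices: EE 28.7159, W 174 (direct enumeration), Gutman 570
    assert eq13_predict(28.7159, 174, 570) == pytest.approx(2139.8682, abs=1e-3)


def test_fixed_model_predicts_from_table():
    m = fixed_index_model()
    tbl = pd.DataFrame({"estrada": [0.0], "wiener": [0.0], "gutman": [0.0]})
    assert m.predict(tbl)[0] == pytest.approx(-417.6882)


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------


def test_ols_two_points():
    m = ols_fit(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]))
    assert m.coefficients["x0"] == pytest.approx(1.0)
    assert m.intercept == pytest.approx(0.0, abs=1e-12)


def test_ridge_zero_alpha_equals_ols():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 3))
    y = X @ [2.0, -1.0, 0.5] + 3.0 + rng.normal(scale=0.1, size=30)
    ols = ols_fit(X, y)
    ridge = ridge_fit(X, y, alpha=0.0)
    for k in ols.coefficients:
        assert ridge.coefficients[k] == pytest.approx(ols.coefficients[k], abs=1e-10)
    assert ridge.intercept == pytest.approx(ols.intercept, abs=1e-10)


def test_ols_noiseless_recovery_of_fixed_coefficients():
    x = np.linspace(5, 300, 40)[:, None]
    y = 90.0 * x[:, 0] - 417.6882
    m = ols_fit(x, y)
    assert m.coefficients["x0"] == pytest.approx(90.0, abs=1e-8)
    assert m.intercept == pytest.approx(-417.6882, abs=1e-6)


def test_ols_rank_deficiency():
    X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
    with pytest.raises(RankDeficiencyError):
        ols_fit(X, np.arange(10.0))


def test_ridge_shrinks_with_alpha():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 2))
    y = X @ [5.0, -3.0] + rng.normal(size=50)
    small = ridge_fit(X, y, alpha=0.01)
    big = ridge_fit(X, y, alpha=1e6)
    assert np.abs(list(big.coefficients.values())).sum() < np.abs(
        list(small.coefficients.values())
    ).sum()
    assert big.intercept == pytest.approx(y.mean(), abs=0.1)


# ---------------------------------------------------------------------------
# Huber
# ---------------------------------------------------------------------------


def test_huber_matches_ols_on_clean_data():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(60, 2))
    y = X @ [2.0, -1.5] + 0.7
    huber = huber_fit(X, y, HuberConfig(epsilon=1e4, alpha=0.0, tol=1e-10))
    ols = ols_fit(X, y)
    for k in ols.coefficients:
        assert huber.coefficients[k] == pytest.approx(ols.coefficients[k], abs=1e-6)
    assert huber.intercept == pytest.approx(ols.intercept, abs=1e-6)


def test_huber_resists_gross_outlier():
    rng = np.random.default_rng(3)
    x = np.linspace(0, 10, 40)[:, None]
    y = 2.0 * x[:, 0] + rng.normal(scale=0.1, size=40)
    y[5] += 500.0  # gross outlier
    huber = huber_fit(x, y, HuberConfig(epsilon=1.35, alpha=0.0))
    ols = ols_fit(x, y)
    assert abs(huber.coefficients["x0"] - 2.0) < abs(ols.coefficients["x0"] - 2.0)


def test_huber_config_validation():
    with pytest.raises(ValueError):
        HuberConfig(epsilon=0.5)
    with pytest.raises(ValueError):
        HuberConfig(alpha=-1.0)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def brute_force_best_split(X, y, min_leaf=1):
    """Exhaustive (feature, threshold) search over midpoint candidates."""
    n, p = X.shape
    best = None
    for j in range(p):
        vals = np.unique(X[:, j])
        for a, b in zip(vals, vals[1:]):
            s = (a + b) / 2
            mask = X[:, j] <= s
            nl = mask.sum()
            if nl < min_leaf or n - nl < min_leaf:
                continue
            yl, yr = y[mask], y[~mask]
            score = (
                nl / n * np.mean((yl - yl.mean()) ** 2)
                + (n - nl) / n * np.mean((yr - yr.mean()) ** 2)
            )
            if best is None or score < best[0] - 1e-12:
                best = (score, j, s)
    return best


def test_tree_constant_target_is_single_leaf():
    t = tree_fit(np.arange(6.0)[:, None], np.full(6, 3.5))
    assert t.is_leaf and t.value == 3.5


def test_tree_step_function_split():
    x = np.arange(1.0, 11.0)[:, None]
    y = (x[:, 0] > 5).astype(float)
    t = tree_fit(x, y, max_depth=1)
    assert t.threshold == pytest.approx(5.5)
    assert {t.left.value, t.right.value} == {0.0, 1.0}


def test_tree_split_matches_exhaustive_oracle():
    rng = np.random.default_rng(9)
    for _ in range(50):
        n = int(rng.integers(4, 9))
        X = rng.normal(size=(n, 2)).round(2)
        y = rng.normal(size=n)
        t = tree_fit(X, y, max_depth=1)
        ref = brute_force_best_split(X, y)
        if ref is None:
            assert t.is_leaf
            continue
        _, j, s = ref
        assert (t.feature, t.threshold) == (j, pytest.approx(s))


def test_tree_matches_sklearn_predictions():
    from sklearn.tree import DecisionTreeRegressor

    rng = np.random.default_rng(4)
    X = rng.normal(size=(80, 3))
    y = X[:, 0] * 3 + np.sin(X[:, 1]) + rng.normal(scale=0.1, size=80)
    ours = tree_fit(X, y, max_depth=3, min_samples_leaf=2)
    ref = DecisionTreeRegressor(max_depth=3, min_samples_leaf=2, random_state=0)
    ref.fit(X, y)
    grid = rng.normal(size=(40, 3))
    assert ours.predict(grid) == pytest.approx(ref.predict(grid), abs=1e-8)


def test_tree_empty_input():
    with pytest.raises(ValueError):
        tree_fit(np.empty((0, 1)), np.empty(0))


# ---------------------------------------------------------------------------
# forests
# ---------------------------------------------------------------------------


def _toy_data(seed=0, n=120):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = 5 * X[:, 0] + 1 * X[:, 1] + rng.normal(scale=0.5, size=n)
    return X, y


def test_single_tree_forest_collapses_to_tree():
    X, y = _toy_data()
    cfg = ForestConfig(kind="rf", n_estimators=1, bootstrap=False, seed=0)
    forest = forest_fit(X, y, cfg)
    tree = tree_fit(X, y)
    grid = X[:20]
    assert forest.predict(grid) == pytest.approx(tree.predict(grid), abs=1e-12)


def test_forest_constant_target():
    X = np.arange(20.0)[:, None]
    m = forest_fit(X, np.full(20, 7.0), ForestConfig(n_estimators=5, seed=1))
    assert m.predict(X) == pytest.approx(np.full(20, 7.0))


def test_forest_predictions_within_target_range():
    X, y = _toy_data(seed=5)
    for kind in ("rf", "et"):
        m = forest_fit(X, y, ForestConfig(kind=kind, n_estimators=10, seed=2))
        preds = m.predict(np.random.default_rng(0).normal(size=(30, 3)) * 5)
        assert preds.min() >= y.min() - 1e-9
        assert preds.max() <= y.max() + 1e-9


def test_forest_determinism():
    X, y = _toy_data(seed=6)
    a = forest_fit(X, y, ForestConfig(n_estimators=8, seed=42)).predict(X)
    b = forest_fit(X, y, ForestConfig(n_estimators=8, seed=42)).predict(X)
    assert (a == b).all()


def test_forest_reduces_test_mse_vs_single_tree():
    X, y = _toy_data(seed=7, n=200)
    Xtr, ytr, Xte, yte = X[:150], y[:150], X[150:], y[150:]
    tree = tree_fit(Xtr, ytr)
    forest = forest_fit(Xtr, ytr, ForestConfig(n_estimators=100, seed=3))
    mse = lambda p: np.mean((yte - p) ** 2)
    assert mse(forest.predict(Xte)) <= mse(tree.predict(Xte))


def test_extra_trees_differ_from_rf_on_same_seed():
    X, y = _toy_data(seed=8)
    rf = forest_fit(X, y, ForestConfig(kind="rf", n_estimators=3, seed=4))
    et = forest_fit(X, y, ForestConfig(kind="et", n_estimators=3, seed=4))
    assert not np.allclose(rf.predict(X), et.predict(X))


def test_importance_single_informative_feature():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(100, 3))
    y = 4.0 * X[:, 1]
    m = forest_fit(X, y, ForestConfig(n_estimators=10, seed=5))
    imp = impurity_importance(m)
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)
    assert imp[1] > 0.95


def test_importance_orders_dominant_feature():
    X, y = _toy_data(seed=11)
    m = forest_fit(X, y, ForestConfig(n_estimators=20, seed=6))
    imp = impurity_importance(m)
    assert imp[0] > imp[1] > imp[2]


def test_importance_requires_fit():
    m = ForestModel(trees=[], config=ForestConfig(), feature_names=["a"])
    with pytest.raises(NotFittedError):
        impurity_importance(m)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_linear_model_json_roundtrip():
    m = ridge_fit(np.arange(10.0)[:, None], np.arange(10.0) * 2, alpha=0.5)
    m2 = model_from_json(model_to_json(m))
    X = np.array([[3.0], [7.0]])
    assert m2.predict(X) == pytest.approx(m.predict(X))


def test_forest_json_roundtrip():
    X, y = _toy_data(seed=12, n=60)
    m = forest_fit(X, y, ForestConfig(n_estimators=3, seed=7))
    m2 = model_from_json(model_to_json(m))
    assert m2.predict(X[:10]) == pytest.approx(m.predict(X[:10]))
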