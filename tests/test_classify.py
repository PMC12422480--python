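"""Weighted random forest, OOB confusion, chance test, importance."""

import math

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from callrep.classify import (
    ChanceTestResult,
    RFConfig,
    WeightedRandomForest,
    chance_test,
    inverse_frequency_weights,
    oob_confusion,
    variable_importance,
)
from callrep.confusion import ConfusionMatrix


def _blobs(n_a=30, n_b=30, sep=4.0, p=6, seed=0):
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0, 1, (n_a, p))
    Xb = rng.normal(0, 1, (n_b, p))
    Xb[:, 0] += sep
    X = np.vstack([Xa, Xb])
    y = np.array(["a"] * n_a + ["b"] * n_b)
    return X, y


def test_inverse_frequency_weight_formula():
    y = np.array(["rare"] * 10 + ["common"] * 100)
    w = inverse_frequency_weights(y)
    assert w.mean() == pytest.approx(1.0)
    ratio = w[y == "rare"][0] / w[y == "common"][0]
    assert ratio == pytest.approx(10.0)


def test_mtry_default_is_sqrt_p():
    X, y = _blobs(20, 20, p=31)
    m = WeightedRandomForest(RFConfig(n_trees=20, seed=0)).fit(X, y)
    assert m.mtry_ == 5


def test_oob_predictions_reproducible():
    X, y = _blobs()
    cfg = RFConfig(n_trees=60, seed=5)
    p1 = WeightedRandomForest(cfg).fit(X, y).oob_predictions_
    p2 = WeightedRandomForest(cfg).fit(X, y).oob_predictions_
    assert np.array_equal(p1, p2)


def test_separable_classes_high_oob_accuracy():
    accs = []
    for seed in range(5):
        X, y = _blobs(50, 50, sep=6.0, seed=seed)
        m = WeightedRandomForest(RFConfig(n_trees=200, seed=seed)).fit(X, y)
        accs.append(m.oob_accuracy)
    assert min(accs) >= 0.95


def test_agrees_with_sklearn_forest_on_separable_data():
    X, y = _blobs(40, 40, sep=6.0, seed=3)
    ours = WeightedRandomForest(RFConfig(n_trees=200, seed=3)).fit(X, y)
    ref = RandomForestClassifier(n_estimators=200, oob_score=True, random_state=3).fit(X, y)
    assert ours.oob_accuracy >= 0.95 and ref.oob_score_ >= 0.95


def test_permuted_labels_score_at_chance():
    X, y = _blobs(40, 40, sep=6.0, seed=1)
    n, k = len(y), 2
    half_width = 2.81 * math.sqrt((1 / k) * (1 - 1 / k) / n)  # central 99.5%
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        yp = rng.permutation(y)
        m = WeightedRandomForest(RFConfig(n_trees=100, seed=seed)).fit(X, yp)
        if abs(m.oob_accuracy - 1 / k) <= half_width:
            hits += 1
    assert hits >= 9


def test_weighting_improves_rare_class_recall():
    wins = 0
    for seed in range(10):
        # imbalanced 10:100, partially overlapping classes
        X, y = _blobs(10, 100, sep=1.5, seed=seed)
        mw = WeightedRandomForest(RFConfig(n_trees=200, seed=seed)).fit(X, y)
        mu = WeightedRandomForest(
            RFConfig(n_trees=200, class_weighting="none", seed=seed)
        ).fit(X, y)
        rare = y == "a"
        rec_w = np.mean(mw.oob_predictions_[rare] == "a")
        rec_u = np.mean(mu.oob_predictions_[rare] == "a")
        wins += rec_w >= rec_u
    assert wins >= 8  # paired comparison, weighting should not hurt


def test_missing_values_rejected():
    X, y = _blobs(10, 10)
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        WeightedRandomForest(RFConfig(n_trees=5)).fit(X, y)


def test_confusion_conservation():
    X, y = _blobs(25, 35, sep=2.0, seed=2)
    m = WeightedRandomForest(RFConfig(n_trees=100, seed=2)).fit(X, y)
    cm = oob_confusion(m.oob_predictions_, y)
    assert cm.total == len(y)
    assert cm.trace + (cm.counts.sum() - cm.trace) == len(y)
    assert list(cm.row_sums) == [25, 35]


def test_confusion_label_mismatch_raises():
    with pytest.raises(ValueError):
        oob_confusion(np.array(["a", "z"]), np.array(["a", "b"]))


# ------------------------------------------------- chance test


def _binom_twotailed_oracle(s, n, p0):
    """Exhaustive minimum-likelihood enumeration over all outcomes."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    obs = pmf[s]
    return sum(q for q in pmf if q <= obs * (1 + 1e-10))


def _cm_with_trace(s, n, k):
    c = np.zeros((k, k), dtype=int)
    c[0, 0] = s
    c[0, 1] = n - s
    return ConfusionMatrix(tuple(f"t{i}" for i in range(k)), c)


@pytest.mark.parametrize(
    "s,n,k",
    [(10, 10, 2), (0, 10, 2), (5, 12, 3), (8, 12, 4), (2, 9, 5), (4, 11, 2)],
)
def test_chance_test_matches_enumeration_oracle(s, n, k):
    res = chance_test(_cm_with_trace(s, n, k))
    assert res.p_value == pytest.approx(_binom_twotailed_oracle(s, n, 1 / k), rel=1e-9)
    assert res.chance_level == 1 / k


def test_chance_test_all_successes_small_n():
    res = chance_test(_cm_with_trace(10, 10, 2))
    assert res.p_value == pytest.approx(2 * 0.5**10, rel=1e-9)


def test_chance_test_at_expectation_is_nonsignificant():
    n, k = 60, 3
    res = chance_test(_cm_with_trace(round(n / k), n, k))
    assert res.p_value > 0.5


# ------------------------------------------------- importance


def test_variable_importance_contract():
    X, y = _blobs(30, 30, sep=6.0, seed=4)
    X = np.hstack([X, np.ones((60, 1))])  # constant feature appended
    m = WeightedRandomForest(RFConfig(n_trees=100, seed=4)).fit(
        X, y, feature_names=[f"f{i}" for i in range(7)]
    )
    imp = variable_importance(m, seed=0)
    assert len(imp) == 7
    assert imp.idxmax() == "f0"  # the only separating feature
    assert abs(imp["f6"]) < 1e-9  # constant feature: no effect
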