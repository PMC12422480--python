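"""Class-weighted random forest with out-of-bag evaluation.

Wild call datasets are heavily unbalanced: common call types would dominate
ordinary bootstrap samples and rare types would be chronically
under-represented.  Here each call carries a weight proportional to the
inverse of its class's relative frequency (normalized to mean 1), and that
weight governs the bootstrap *sampling probability* per tree, so rarer call
types are oversampled.  Each call's prediction is the majority vote over
the trees for which it was out of bag (OOB), giving an internal
generalization estimate without a held-out split.

The trees themselves are scikit-learn decision trees; the bagging,
weighting and OOB bookkeeping are explicit so they exactly follow the
oversampling scheme described above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.tree import DecisionTreeClassifier

from .confusion import ConfusionMatrix

__all__ = [
    "RFConfig",
    "WeightedRandomForest",
    "ChanceTestResult",
    "fit_weighted_forest",
    "oob_confusion",
    "chance_test",
    "variable_importance",
    "inverse_frequency_weights",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 1000
    mtry: int | None = None  # None -> floor(sqrt(p)); 5 for the 31-feature table
    class_weighting: str = "inverse_frequency"
    weight_mode: str = "bootstrap"  # "bootstrap" (oversampling) or "fit" (sample_weight)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.class_weighting not in ("inverse_frequency", "none"):
            raise ValueError("class_weighting must be 'inverse_frequency' or 'none'")
        if self.weight_mode not in ("bootstrap", "fit"):
            raise ValueError("weight_mode must be 'bootstrap' or 'fit'")


def inverse_frequency_weights(y: np.ndarray) -> np.ndarray:
    """Per-call weights proportional to 1/(class relative frequency), mean 1."""
    labels, counts = np.unique(y, return_counts=True)
    freq = dict(zip(labels, counts))
    w = np.array([len(y) / freq[l] for l in y], dtype=np.float64)
    return w / w.mean()


@dataclass(frozen=True)
class ChanceTestResult:
    n_agree: int
    n_total: int
    chance_level: float
    p_value: float
    two_tailed: bool = True

    def to_dict(self) -> dict:
        return {
            "n_agree": self.n_agree,
            "n_total": self.n_total,
            "chance_level": self.chance_level,
            "p_value": self.p_value,
            "two_tailed": self.two_tailed,
        }


class WeightedRandomForest:
    """Bagged decision trees with weighted bootstrap and OOB votes."""

    def __init__(self, cfg: RFConfig = RFConfig()):
        self.cfg = cfg
        self._fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray, feature_names=None) -> "WeightedRandomForest":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if np.isnan(X).any():
            raise ValueError("feature matrix contains missing values")
        n, p = X.shape
        self.classes_ = np.array(sorted(set(y)))
        class_counts = pd.Series(y).value_counts()
        if (class_counts < 2).any():
            singles = list(class_counts[class_counts < 2].index)
            logger.warning("classes with a single call: %s", singles)
        self.feature_names_ = (
            list(feature_names) if feature_names is not None else [f"f{i}" for i in range(p)]
        )
        mtry = self.cfg.mtry if self.cfg.mtry is not None else int(np.floor(np.sqrt(p)))
        if mtry > p:
            raise ValueError(f"mtry={mtry} exceeds feature count {p}")
        self.mtry_ = mtry

        if self.cfg.class_weighting == "inverse_frequency":
            w = inverse_frequency_weights(y)
        else:
            w = np.ones(n)
        self.weights_ = w
        prob = w / w.sum()
        # rarer class = larger per-call weight; used for OOB vote tie-breaks
        cls_weight = {c: w[y == c][0] for c in self.classes_}
        self._class_weight = cls_weight

        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.cfg.seed)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.cfg.n_trees)

        self.trees_: list[DecisionTreeClassifier] = []
        self._oob_sets: list[np.ndarray] = []
        vote = np.zeros((n, len(self.classes_)), dtype=np.int64)
        oob_count = np.zeros(n, dtype=np.int64)
        for s in tree_seeds:
            trng = np.random.default_rng(int(s))
            if self.cfg.weight_mode == "bootstrap":
                idx = trng.choice(n, size=n, replace=True, p=prob)
                sw = None
            else:
                idx = trng.choice(n, size=n, replace=True)
                sw = w[idx]
            tree = DecisionTreeClassifier(max_features=mtry, random_state=int(s))
            tree.fit(X[idx], y_idx[idx], sample_weight=sw)
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            self.trees_.append(tree)
            self._oob_sets.append(oob)
            if len(oob):
                pred = tree.predict(X[oob])
                vote[oob, pred] += 1
                oob_count[oob] += 1

        self._X, self._y_idx = X, y_idx
        self.oob_votes_ = vote
        self.oob_counts_ = oob_count
        self.oob_predictions_ = self._majority(vote, oob_count, X)
        self._fitted = True
        return self

    def _majority(self, vote: np.ndarray, oob_count: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Majority OOB vote; ties go to the heavier (rarer) class, then
        lexicographic label order; calls never OOB fall back to the full-forest
        vote (with a warning)."""
        n = vote.shape[0]
        never = np.where(oob_count == 0)[0]
        v = vote.astype(np.float64).copy()
        if len(never):
            logger.warning("%d call(s) were never out of bag; using full-forest vote", len(never))
            for tree in self.trees_:
                v[never, tree.predict(X[never])] += 1
        # tie-break: add epsilon ranks, heavier class first then lexicographic
        order = sorted(
            range(len(self.classes_)),
            key=lambda c: (-self._class_weight[self.classes_[c]], str(self.classes_[c])),
        )
        eps = np.zeros(len(self.classes_))
        for rank, c in enumerate(order):
            eps[c] = (len(order) - rank) * 1e-9
        return self.classes_[np.argmax(v + eps[None, :], axis=1)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("forest is not fitted")
        X = np.asarray(X, dtype=np.float64)
        vote = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int64)
        for tree in self.trees_:
            vote[np.arange(X.shape[0]), tree.predict(X)] += 1
        return self.classes_[np.argmax(vote, axis=1)]

    @property
    def oob_accuracy(self) -> float:
        return float(np.mean(self.oob_predictions_ == self.classes_[self._y_idx]))


def fit_weighted_forest(
    table: pd.DataFrame, cfg: RFConfig = RFConfig()
) -> tuple[WeightedRandomForest, np.ndarray]:
    """Fit on a feature table; returns (model, per-call OOB predictions)."""
    from .features import feature_matrix

    X, y = feature_matrix(table)
    names = [c for c in table.columns if c not in ("call_id", "original_label")]
    model = WeightedRandomForest(cfg).fit(X, y, feature_names=names)
    return model, model.oob_predictions_


def oob_confusion(predictions: np.ndarray, labels: np.ndarray) -> ConfusionMatrix:
    """Cross-tabulate original labels against OOB predictions."""
    return ConfusionMatrix.from_predictions(labels, predictions)


def chance_test(cm: ConfusionMatrix, n_total: int | None = None) -> ChanceTestResult:
    """Exact two-tailed binomial test of OOB agreement against chance 1/k.

    Two-tailed by the minimum-likelihood rule: the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    ``n_total`` overrides the matrix cell sum when the dataset size is known
    independently.
    """
    if cm.k == 0:
        raise ValueError("empty confusion matrix")
    n = n_total if n_total is not None else cm.total
    s = cm.trace
    p0 = 1.0 / cm.k
    res = binomtest(s, n, p0, alternative="two-sided")
    return ChanceTestResult(n_agree=s, n_total=n, chance_level=p0, p_value=float(res.pvalue))


def variable_importance(model: WeightedRandomForest, seed: int = 0) -> pd.Series:
    """Permutation importance (mean decrease in OOB accuracy per feature).

    For every tree, the accuracy on its OOB calls is compared with the
    accuracy after permuting one feature's OOB values; the drops are
    averaged over trees.  Deterministic under a fixed seed.
    """
    if not model._fitted:
        raise RuntimeError("forest is not fitted")
    X, y_idx = model._X, model._y_idx
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    n_used = np.zeros(p)
    for tree, oob in zip(model.trees_, model._oob_sets):
        if len(oob) < 2:
            continue
        Xo = X[oob]
        base = np.mean(tree.predict(Xo) == y_idx[oob])
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(oob)), j]
            drops[j] += base - np.mean(tree.predict(Xp) == y_idx[oob])
            n_used[j] += 1
    with np.errstate(invalid="ignore"):
        mda = np.where(n_used > 0, drops / np.maximum(n_used, 1), 0.0)
    return pd.Series(mda, index=model.feature_names_, name="mean_decrease_accuracy")
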