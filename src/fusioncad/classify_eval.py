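"""Classification and imbalance-aware evaluation.

The native classifier here is AdaBoost with decision stumps, implemented from
its sample-reweighting recurrence: uniform initial weights, per-round
weighted error ``eps_t``, learner weight ``alpha_t = 0.5*ln((1-eps_t)/eps_t)``,
multiplicative weight update normalized by ``Z_t``, and the signed weighted
vote as the strong classifier. Gradient-boosted trees (XGBoost) and a
multilayer perceptron are consumed through established implementations behind
the same fit/predict contract.

Evaluation treats malignant as the positive class and reports, per class and
macro-averaged: accuracy, sensitivity/recall, specificity, precision,
F1-score, Dominance (Recall - Specificity) and the Index Balanced Accuracy

    IBA = (1 + alpha * Dominance) * (Recall * Specificity),  alpha = 0.1,

which discounts models whose class-wise accuracies are unbalanced. A
rank-sum (Wilcoxon/Mann-Whitney style) two-group test with exact enumeration
at small sizes completes the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

from .data import BENIGN, MALIGNANT, FeatureTable

IBA_ALPHA = 0.1
_EPS_CLIP = 1e-10
_EXACT_LIMIT = 20000  # max C(N, nA) for the exact rank-sum enumeration


# --------------------------------------------------------------------------
# native AdaBoost
# --------------------------------------------------------------------------
@dataclass
class AdaBoostModel:
    weak_learners: list = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    T: int = 0

    @property
    def n_rounds(self) -> int:
        return len(self.alphas)


def _as_signed(y: np.ndarray) -> np.ndarray:
    """Map labels to {-1, +1} with malignant (or 1) as +1."""
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        return np.where(y == MALIGNANT, 1, -1)
    return np.where(np.asarray(y, dtype=int) > 0, 1, -1)


def adaboost_train(
    x: np.ndarray, y: np.ndarray, T: int = 50, seed: int = 0
) -> AdaBoostModel:
    """Train boosted decision stumps by the reweighting recurrence.

    Stops early when a round is perfect (``eps_t == 0``) or no better than
    chance (``eps_t >= 0.5``); ``eps_t`` is clipped away from {0, 1} before
    the log so every ``alpha_t`` stays finite.
    """
    x = np.asarray(x, dtype=float)
    ys = _as_signed(y)
    if len(np.unique(ys)) < 2:
        raise ValueError("AdaBoost needs both classes in the training labels")
    if T < 1:
        raise ValueError("T must be >= 1")
    n = len(ys)
    d = np.full(n, 1.0 / n)
    model = AdaBoostModel(T=T)
    for _t in range(T):
        stump = DecisionTreeClassifier(max_depth=1, random_state=seed)
        stump.fit(x, ys, sample_weight=d)
        pred = stump.predict(x)
        eps_raw = float(d[pred != ys].sum())
        if eps_raw >= 0.5 and model.n_rounds > 0:
            break
        eps = float(np.clip(eps_raw, _EPS_CLIP, 1 - _EPS_CLIP))
        alpha = 0.5 * np.log((1 - eps) / eps)
        model.weak_learners.append(stump)
        model.alphas.append(alpha)
        d = d * np.exp(-alpha * ys * pred)
        d = d / d.sum()  # Z_t normalization
        if eps_raw == 0.0 or eps_raw >= 0.5:
            break
    return model


def adaboost_predict(model: AdaBoostModel, x: np.ndarray) -> np.ndarray:
    """Sign of the alpha-weighted vote; exact ties go to the positive class."""
    if model.n_rounds == 0:
        raise ValueError("model has no trained learners")
    x = np.asarray(x, dtype=float)
    score = np.zeros(len(x))
    for alpha, h in zip(model.alphas, model.weak_learners):
        score += alpha * h.predict(x)
    return np.where(score >= 0, 1, -1)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with malignant as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions viewed with benign as the positive class."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def _rate(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def _class_metrics(cm: ConfusionMatrix, alpha: float) -> dict[str, float]:
    recall = _rate(cm.tp, cm.tp + cm.fn, "recall")
    specificity = _rate(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _rate(cm.tp, cm.tp + cm.fp, "precision")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    dominance = recall - specificity
    iba = (1 + alpha * dominance) * (recall * specificity)
    return {
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
        "dominance": dominance,
        "iba": iba,
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix plus derived metrics, per class and macro-averaged.

    The scalar properties expose the malignant (positive-class) values;
    ``per_class`` holds both views and ``macro`` their unweighted mean.
    """

    confusion: ConfusionMatrix
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    alpha: float = IBA_ALPHA

    @property
    def sensitivity(self) -> float:
        return self.per_class[MALIGNANT]["recall"]

    recall = sensitivity

    @property
    def specificity(self) -> float:
        return self.per_class[MALIGNANT]["specificity"]

    @property
    def precision(self) -> float:
        return self.per_class[MALIGNANT]["precision"]

    @property
    def f1(self) -> float:
        return self.per_class[MALIGNANT]["f1"]

    @property
    def iba(self) -> float:
        return self.per_class[MALIGNANT]["iba"]

    @property
    def dominance(self) -> float:
        return self.per_class[MALIGNANT]["dominance"]

    def as_dict(self) -> dict:
        return {
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro": self.macro,
            "alpha": self.alpha,
        }


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    t = _as_signed(y_true)
    p = _as_signed(y_pred)
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == -1) & (p == -1)).sum()),
        fp=int(((t == -1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == -1)).sum()),
    )


def evaluate(y_true, y_pred, alpha: float = IBA_ALPHA) -> EvaluationReport:
    """Full evaluation report; labels may be benign/malignant strings or 0/1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty evaluation input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    cm = confusion_from_labels(y_true, y_pred)
    accuracy = _rate(cm.tp + cm.tn, cm.n, "accuracy")
    per_class = {
        MALIGNANT: _class_metrics(cm, alpha),
        BENIGN: _class_metrics(cm.swapped(), alpha),
    }
    macro = {
        key: float(np.mean([per_class[MALIGNANT][key], per_class[BENIGN][key]]))
        for key in per_class[MALIGNANT]
    }
    return EvaluationReport(
        confusion=cm, accuracy=accuracy, per_class=per_class, macro=macro, alpha=alpha
    )


# --------------------------------------------------------------------------
# rank-sum test
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class RankSumResult:
    w: float  # rank sum of group A over the pooled midranks
    p_value: float
    reject: bool  # H0 rejected at alpha = 0.05
    method: str  # "exact" or "normal"


def wilcoxon_rank_sum(
    group_a, group_b, alpha: float = 0.05
) -> RankSumResult:
    """Two-sided two-sample rank-sum test on pooled midranks.

    W is the rank sum of group A. When the number of rank assignments
    C(N, nA) is small enough the two-sided p-value is computed by exhaustive
    enumeration of all assignments of the pooled midranks; otherwise the
    normal approximation with tie correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:na].sum())
    n = na + nb
    mean_w = na * (n + 1) / 2.0

    if comb(n, na) <= _EXACT_LIMIT:
        dev = abs(w - mean_w)
        count = 0
        total = 0
        for idx in combinations(range(n), na):
            total += 1
            if abs(ranks[list(idx)].sum() - mean_w) >= dev - 1e-9:
                count += 1
        p = count / total
        method = "exact"
    else:
        _, t_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((t_counts**3 - t_counts).sum()) / (n * (n - 1)))
        var_w = na * nb / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:  # all observations identical
            return RankSumResult(w=w, p_value=1.0, reject=False, method="normal")
        z = (w - mean_w) / np.sqrt(var_w)
        p = float(2 * (1 - ndtr(abs(z))))
        method = "normal"
    return RankSumResult(w=w, p_value=float(p), reject=bool(p < alpha), method=method)


# --------------------------------------------------------------------------
# classifier adapters
# --------------------------------------------------------------------------
class _NativeAdaBoostAdapter:
    def __init__(self, T: int = 50, seed: int = 0) -> None:
        self.T, self.seed = T, seed
        self._model: AdaBoostModel | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_NativeAdaBoostAdapter":
        self._model = adaboost_train(x, y, T=self.T, seed=self.seed)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("fit before predict")
        return (adaboost_predict(self._model, x) > 0).astype(int)


CLASSIFIER_NAMES = ("xgboost", "adaboost_native", "mlp")


def classifier_adapters(name: str, seed: int = 0, **params):
    """Uniform fit/predict classifiers over 0/1 integer labels.

    ``xgboost`` and ``mlp`` delegate to established implementations with
    seeded determinism; ``adaboost_native`` is this module's implementation.
    """
    if name == "xgboost":
        from xgboost import XGBClassifier

        defaults = dict(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            tree_method="hist",
        )
        defaults.update(params)
        return XGBClassifier(**defaults)
    if name == "adaboost_native":
        return _NativeAdaBoostAdapter(T=params.get("T", 50), seed=seed)
    if name == "mlp":
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        defaults = dict(hidden_layer_sizes=(64,), max_iter=800, random_state=seed)
        defaults.update(params)
        return make_pipeline(StandardScaler(), MLPClassifier(**defaults))
    raise ValueError(f"unknown classifier {name!r}; valid names: {CLASSIFIER_NAMES}")


def train_and_evaluate(
    train: FeatureTable,
    test: FeatureTable,
    classifier: str = "xgboost",
    seed: int = 0,
    **params,
) -> EvaluationReport:
    """Fit the named classifier on ``train`` and evaluate on ``test``."""
    clf = classifier_adapters(classifier, seed=seed, **params)
    clf.fit(train.x(), train.y())
    pred = np.asarray(clf.predict(test.x()), dtype=int)
    return evaluate(test.y(), pred)
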