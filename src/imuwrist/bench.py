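"""Classifier benchmark under stratified 10-fold cross-validation.

The suite mirrors a classical movement-classification benchmark: a
majority-class baseline (ZeroR) and a one-rule classifier (OneR) are
implemented natively because the study's interpretive claims rest on
them; the remaining algorithms (naive Bayes, logistic regression,
entropy decision tree, random forest, SVM, multilayer perceptron,
k-nearest neighbours) are standard scikit-learn estimators with defaults
chosen to mirror the common benchmarking platform's (scale-sensitive
models are wrapped in a standardizing pipeline).

Evaluation pools the out-of-fold predictions of a stratified k-fold
split into a single accuracy, and computes per-class one-vs-rest ROC
curves whose AUCs are averaged with class-prevalence weights (for a
binary problem the two per-class AUCs coincide, so the weighted average
equals the plain AUC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, InvalidParameterError, UndefinedAUCError
from .features import LabeledDataset

log = logging.getLogger(__name__)

BASELINE_NAMES = ("ZeroR",)

CLASSIFIER_NAMES = (
    "ZeroR", "OneR", "NaiveBayes", "BayesNet", "Logistic",
    "C45Tree", "RandomForest", "SVM", "MLP", "KNN",
)


# ---------------------------------------------------------------------------
# native baselines

class ZeroR(BaseEstimator, ClassifierMixin):
    """Majority-class baseline: ignores the features entirely.

    Ties favour label 0.  Scores are the constant training class
    frequencies, so its ROC is the diagonal and its AUC is 0.5.
    """

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(y) == 0:
            raise InvalidParameterError("empty training set")
        self.classes_ = np.unique(y)
        counts = {c: int((y == c).sum()) for c in self.classes_}
        self.majority_ = max(sorted(counts), key=lambda c: counts[c])
        n = len(y)
        self.prior_ = np.array([counts.get(c, 0) / n for c in self.classes_])
        return self

    def predict(self, X):
        return np.full(len(X), self.majority_, dtype=int)

    def predict_proba(self, X):
        return np.tile(self.prior_, (len(X), 1))


class OneR(BaseEstimator, ClassifierMixin):
    """One-rule classifier: the single best discretized feature.

    Each feature is discretized into equal-frequency bins (at least
    ``min_bucket`` samples per bin); each bin predicts its training
    majority label.  The feature with the lowest training error wins,
    ties going to the lower feature index.  Constant features are
    skipped; if all are constant the rule degenerates to the majority
    class.  ``feature_`` records the winning (0-based) feature index.
    """

    def __init__(self, bins: int = 10, min_bucket: int = 6):
        self.bins = bins
        self.min_bucket = min_bucket

    def _edges(self, x):
        n_bins = max(1, min(self.bins, len(x) // self.min_bucket))
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(x, qs))
        return edges

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise InvalidParameterError("OneR needs at least 2 classes")
        best = None
        for j in range(X.shape[1]):
            x = X[:, j]
            if np.ptp(x) == 0:
                continue
            edges = self._edges(x)
            bins = np.digitize(x, edges)
            rule = {}
            errors = 0
            for b in np.unique(bins):
                yb = y[bins == b]
                vals, counts = np.unique(yb, return_counts=True)
                maj = vals[np.argmax(counts)]
                rule[int(b)] = int(maj)
                errors += len(yb) - counts.max()
            if best is None or errors < best[0]:
                best = (errors, j, edges, rule)
        if best is None:  # all features constant
            self.feature_ = None
            vals, counts = np.unique(y, return_counts=True)
            self.fallback_ = int(vals[np.argmax(counts)])
            return self
        _, self.feature_, self.edges_, self.rule_ = best
        # per-bin class frequencies double as scores for the ROC
        x = X[:, self.feature_]
        bins = np.digitize(x, self.edges_)
        self.bin_proba_ = {}
        for b in np.unique(bins):
            yb = y[bins == b]
            self.bin_proba_[int(b)] = np.array(
                [((yb == c).sum() + 1) / (len(yb) + len(self.classes_))
                 for c in self.classes_]
            )
        self.default_proba_ = np.full(len(self.classes_), 1 / len(self.classes_))
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.feature_ is None:
            return np.full(len(X), self.fallback_, dtype=int)
        bins = np.digitize(X[:, self.feature_], self.edges_)
        maj0 = int(self.classes_[0])
        return np.array([self.rule_.get(int(b), maj0) for b in bins], dtype=int)

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if self.feature_ is None:
            p = np.zeros(len(self.classes_))
            p[list(self.classes_).index(self.fallback_)] = 1.0
            return np.tile(p, (len(X), 1))
        bins = np.digitize(X[:, self.feature_], self.edges_)
        return np.vstack([
            self.bin_proba_.get(int(b), self.default_proba_) for b in bins
        ])


# ---------------------------------------------------------------------------
# configuration

@dataclass
class CVConfig:
    """Cross-validation layout: k folds (default 10), stratified, seeded."""

    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("k must be >= 2")


@dataclass
class ClassifierSpec:
    """A named classifier plus hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ConfigError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the estimator behind a spec name.

    Defaults mirror the usual benchmarking platform: entropy splitting
    for the decision tree, 100 trees for the forest, k=1 neighbours, one
    moderate hidden layer for the MLP.  There is no Bayesian-network
    implementation available, so 'BayesNet' degrades to naive Bayes with
    a logged warning.
    """
    name, p = spec.name, dict(spec.params)
    if name == "ZeroR":
        return ZeroR(**p)
    if name == "OneR":
        return OneR(**p)
    if name == "NaiveBayes":
        return GaussianNB(**p)
    if name == "BayesNet":
        log.warning("BayesNet has no backing implementation; using NaiveBayes")
        return GaussianNB(**p)
    if name == "Logistic":
        p.setdefault("max_iter", 2000)
        return make_pipeline(StandardScaler(), LogisticRegression(**p))
    if name == "C45Tree":
        p.setdefault("criterion", "entropy")
        p.setdefault("min_samples_leaf", 2)
        p.setdefault("random_state", seed)
        return DecisionTreeClassifier(**p)
    if name == "RandomForest":
        p.setdefault("n_estimators", 100)
        p.setdefault("random_state", seed)
        return RandomForestClassifier(**p)
    if name == "SVM":
        p.setdefault("kernel", "rbf")
        return make_pipeline(StandardScaler(), SVC(**p))
    if name == "MLP":
        p.setdefault("hidden_layer_sizes", (64,))
        p.setdefault("max_iter", 500)
        p.setdefault("random_state", seed)
        return make_pipeline(StandardScaler(), MLPClassifier(**p))
    if name == "KNN":
        p.setdefault("n_neighbors", 1)
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**p))
    raise ConfigError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_points(scores, labels):
    """Standard threshold-sweep ROC with trapezoidal AUC.

    Returns ``(fpr, tpr, auc)``; the curve includes (0,0) and (1,1).
    Raises :class:`UndefinedAUCError` when only one class is present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("ROC undefined with a single class")
    fpr, tpr, _ = metrics.roc_curve(labels, scores)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr, tpr = np.r_[fpr, 1.0], np.r_[tpr, 1.0]
    return fpr, tpr, float(metrics.auc(fpr, tpr))


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalResult:
    """Pooled cross-validation outcome for one classifier.

    ``accuracy`` in percent; ``auc`` the class-weighted one-vs-rest AUC
    in [0, 1]; ``roc`` maps each class to its (fpr, tpr) arrays;
    ``per_fold`` lists the per-fold accuracies in percent.
    """

    accuracy: float
    auc: float
    roc: dict = field(default_factory=dict)
    per_fold: list = field(default_factory=list)


@dataclass
class BenchmarkTable:
    """Per-classifier results, in the order the specs were given."""

    rows: dict

    def __getitem__(self, name: str) -> EvalResult:
        return self.rows[name]


def _scores_of(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        return proba[:, -1]
    return model.decision_function(X)


def run_cv(data: LabeledDataset, specs, cv: CVConfig | None = None) -> BenchmarkTable:
    """Evaluate each classifier by pooled out-of-fold prediction.

    The fold partition is shared across classifiers; a fixed seed makes
    folds — and every deterministic classifier's results — reproducible.
    """
    cv = cv or CVConfig()
    if len(data) < cv.k:
        raise ConfigError(f"dataset size {len(data)} < k={cv.k}")
    specs = [ClassifierSpec(s) if isinstance(s, str) else s for s in specs]
    splitter_cls = StratifiedKFold if cv.stratified else KFold
    splitter = splitter_cls(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    folds = list(splitter.split(data.X, data.y))

    rows = {}
    for spec in specs:
        template = make_classifier(spec, seed=cv.seed)
        pred = np.empty(len(data), dtype=int)
        score = np.empty(len(data), dtype=float)
        per_fold = []
        for train_idx, test_idx in folds:
            model = clone(template)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(data.X[train_idx], data.y[train_idx])
            p = model.predict(data.X[test_idx])
            pred[test_idx] = p
            score[test_idx] = _scores_of(model, data.X[test_idx])
            per_fold.append(100.0 * (p == data.y[test_idx]).mean())
        accuracy = 100.0 * (pred == data.y).mean()

        classes, counts = np.unique(data.y, return_counts=True)
        roc = {}
        aucs = []
        for c in classes:
            s = score if c == classes[-1] else -score
            fpr, tpr, auc_c = roc_points(s, (data.y == c).astype(int))
            roc[int(c)] = (fpr, tpr)
            aucs.append(auc_c)
        weighted_auc = float(np.average(aucs, weights=counts))
        rows[spec.name] = EvalResult(
            accuracy=accuracy, auc=weighted_auc, roc=roc, per_fold=per_fold
        )
    return BenchmarkTable(rows=rows)


def summarize(table: BenchmarkTable) -> pd.DataFrame:
    """Report rows (accuracy %, AUC) plus an Average over non-baseline rows.

    Accuracies round to 2 decimals, AUCs to 3; the Average row is the
    unweighted mean over every classifier except the ZeroR baseline.
    """
    if not table.rows:
        raise InvalidParameterError("empty benchmark table")
    records = [
        {"classifier": name, "accuracy": round(res.accuracy, 2),
         "auc": round(res.auc, 3)}
        for name, res in table.rows.items()
    ]
    member = [r for r in records if r["classifier"] not in BASELINE_NAMES]
    if member:
        records.append({
            "classifier": "Average",
            "accuracy": round(float(np.mean([r["accuracy"] for r in member])), 2),
            "auc": round(float(np.mean([r["auc"] for r in member])), 3),
        })
    return pd.DataFrame.from_records(records)
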