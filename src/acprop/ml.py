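"""Classifier scanning and evaluation for AC-propensity classes.

Protein descriptors are the explanatory variables; the per-kinase
ACs/MMPs% class (under a chosen threshold scheme) is the response.  Models
are scored by accuracy (diagonal fraction of the confusion matrix) and
Cohen's kappa, kappa = (Po - Pe) / (1 - Pe), with leave-20%-out (fivefold,
stratified) cross-validation on the training kinases and a held-out test
set of ~20% of kinases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB

from .mmp import CLASS_ORDER, KinasePropensity

LEARNER_FAMILIES = ("random_forest", "gradient_boosting", "naive_bayes")

#: probability floor mirrored from the reference Naive Bayes configuration
NB_PROBABILITY_FLOOR = 1e-4


class AssemblyError(ValueError):
    """Feature matrix could not be assembled."""


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


@dataclass
class FeatureMatrix:
    """Descriptor matrix with class labels and a train/test split tag."""

    X: pd.DataFrame
    y: pd.Series
    split: pd.Series  # "train" / "test" per kinase
    scheme: str
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(c for c in CLASS_ORDER[self.scheme] if c in set(self.y))

    def train(self) -> tuple[pd.DataFrame, pd.Series]:
        m = self.split == "train"
        return self.X[m], self.y[m]

    def test(self) -> tuple[pd.DataFrame, pd.Series]:
        m = self.split == "test"
        return self.X[m], self.y[m]


@dataclass(frozen=True)
class LearnerSpec:
    """A classifier family with its fixed hyperparameters.

    Defaults follow the study settings: 100 trees for the random forest
    (entropy criterion standing in for gain-ratio splitting), 100 boosting
    rounds with eta 0.3 / depth 6 for gradient boosting, and a Gaussian
    Naive Bayes with a 1e-4 probability floor.
    """

    family: str = "random_forest"
    n_estimators: int = 100
    learning_rate: float = 0.3
    max_depth: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")


@dataclass(frozen=True)
class EvaluationReport:
    accuracy: float
    kappa: float
    po: float
    pe: float
    per_class_recall: dict[str, float]
    band: str


def build_feature_matrix(descriptors: pd.DataFrame,
                         propensities: list[KinasePropensity] | dict[str, str],
                         scheme: str = "default", test_fraction: float = 0.2,
                         seed: int = 0) -> FeatureMatrix:
    """Align descriptors with class labels and split train/test by kinase.

    ``propensities`` is either KinasePropensity objects (labels taken under
    ``scheme``) or a ready kinase -> class mapping.  Constant-value columns
    are dropped and recorded.  The split is stratified by class.
    """
    if scheme not in CLASS_ORDER:
        raise ValueError(f"unknown scheme {scheme!r}")
    if isinstance(propensities, dict):
        labels = dict(propensities)
    else:
        attr = {"default": "class_default", "A": "class_A", "B": "class_B"}[scheme]
        labels = {p.kinase_id: getattr(p, attr) for p in propensities}
    if descriptors.empty or not labels:
        raise AssemblyError("empty descriptor matrix or label set")
    missing_desc = sorted(set(labels) - set(descriptors.index))
    missing_lab = sorted(set(descriptors.index) - set(labels))
    if missing_desc or missing_lab:
        raise AssemblyError(
            f"kinases without descriptors: {missing_desc}; without labels: {missing_lab}")
    X = descriptors.loc[sorted(labels)]
    y = pd.Series({k: labels[k] for k in X.index}, name="class")
    const = X.columns[(X.nunique(axis=0) <= 1)].tolist()
    X = X.drop(columns=const)
    if X.isna().any().any():
        raise AssemblyError("descriptor matrix contains missing values")
    train_idx, test_idx = train_test_split(
        X.index, test_size=test_fraction, random_state=seed, stratify=y)
    split = pd.Series("train", index=X.index)
    split[test_idx] = "test"
    return FeatureMatrix(X, y, split, scheme, const)


def _encode(y: pd.Series | np.ndarray, scheme: str) -> tuple[np.ndarray, list[str]]:
    order = [c for c in CLASS_ORDER[scheme] if c in set(np.asarray(y))]
    lut = {c: i for i, c in enumerate(order)}
    return np.array([lut[v] for v in np.asarray(y)]), order


def fit_classifier(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec, scheme: str = "default"):
    """Fit one classifier; returns a model with ``predict`` on feature rows.

    Predictions are decoded back to class-label strings; ties in posterior
    probability resolve to the earlier class in the fixed order.
    """
    codes, order = _encode(y, scheme)
    if len(order) < 2:
        raise DegenerateLabelsError("training labels contain a single class")
    if spec.family == "random_forest":
        model = RandomForestClassifier(n_estimators=spec.n_estimators,
                                       criterion="entropy", random_state=spec.seed,
                                       n_jobs=1)
        model.fit(X.to_numpy(), codes)
    elif spec.family == "gradient_boosting":
        from xgboost import XGBClassifier

        model = XGBClassifier(n_estimators=spec.n_estimators,
                              learning_rate=spec.learning_rate,
                              gamma=0.0, max_depth=spec.max_depth, min_child_weight=1,
                              subsample=1.0, colsample_bytree=1.0, colsample_bylevel=1.0,
                              reg_lambda=1.0, reg_alpha=0.0, tree_method="hist",
                              random_state=spec.seed, n_jobs=1, verbosity=0)
        model.fit(X.to_numpy(), codes)
    else:
        model = GaussianNB()
        model.fit(X.to_numpy(), codes)
        # floor the per-feature variances so no likelihood collapses below ~1e-4
        model.var_ = np.maximum(model.var_, NB_PROBABILITY_FLOOR ** 2)

    class _Wrapped:
        def __init__(self, inner, order):
            self._inner = inner
            self.classes = tuple(order)

        def predict(self, features) -> np.ndarray:
            arr = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features)
            codes = self._inner.predict(arr)
            return np.array([self.classes[int(c)] for c in codes])

    return _Wrapped(model, order)


def leave20_cv(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec, seed: int = 0,
               scheme: str = "default") -> pd.Series:
    """Leave-20%-out (stratified fivefold) out-of-fold predictions.

    Every row is excluded and predicted exactly once; fold assignment is
    stratified by class and seeded.
    """
    if len(X) < 5:
        raise ValueError(f"leave-20%-out needs >= 5 rows, got {len(X)}")
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    preds = pd.Series(index=X.index, dtype=object)
    codes, _ = _encode(y, scheme)
    for tr, te in skf.split(X.to_numpy(), codes):
        model = fit_classifier(X.iloc[tr], y.iloc[tr], spec, scheme)
        preds.iloc[te] = model.predict(X.iloc[te])
    return preds


def confusion_matrix(y_true, y_pred, classes: tuple[str, ...]) -> np.ndarray:
    """Square count matrix indexed by ``classes`` (rows = true, cols = predicted)."""
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[lut[t], lut[p]] += 1
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Fraction of truly identified observations: trace(cm) / N."""
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm)) / float(n)


def cohens_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe).

    Po is the observed accuracy; Pe the chance agreement computed from the
    row and column marginals.
    """
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(cm)) / n
    pe = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if pe >= 1.0 - 1e-12:
        raise ValueError("degenerate marginals: chance agreement Pe = 1")
    return (po - pe) / (1.0 - pe)


_BANDS = ((0.0, "none to slight"), (0.21, "fair"), (0.41, "moderate"),
          (0.61, "substantial"), (0.81, "almost perfect"))


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value."""
    if not -1.0 - 1e-9 <= kappa <= 1.0 + 1e-9:
        raise ValueError("kappa outside [-1, 1]")
    if kappa < 0:
        return "worse than random"
    band = _BANDS[0][1]
    for lo, name in _BANDS:
        if kappa >= lo:
            band = name
    return band


def evaluate(y_true, y_pred, classes: tuple[str, ...]) -> EvaluationReport:
    """Accuracy, kappa, Po/Pe, per-class recall and the qualitative band."""
    cm = confusion_matrix(y_true, y_pred, classes)
    n = cm.sum()
    po = float(np.trace(cm)) / n
    pe = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    kappa = cohens_kappa(cm)
    recall = {}
    for i, c in enumerate(classes):
        row = cm[i].sum()
        recall[c] = float(cm[i, i]) / row if row else float("nan")
    return EvaluationReport(accuracy(cm), kappa, po, pe, recall, kappa_band(kappa))
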