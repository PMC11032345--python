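"""Feature matrix, classifiers, CV machinery and agreement metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from acprop.ml import (AssemblyError, DegenerateLabelsError, LearnerSpec,
                       accuracy, build_feature_matrix, cohens_kappa,
                       confusion_matrix, evaluate, fit_classifier, kappa_band,
                       leave20_cv)


def _labels(n, seed=0, classes=("No ACs", "Low ACs", "High ACs")):
    rng = np.random.default_rng(seed)
    return {f"K{i:03d}": classes[int(rng.integers(len(classes)))] for i in range(n)}


def _descriptors(labels, n_features=12, signal=True, seed=0):
    rng = np.random.default_rng(seed)
    classes = sorted(set(labels.values()))
    rows = {}
    for k, cls in labels.items():
        x = rng.normal(size=n_features)
        if signal:
            x[0] = classes.index(cls) + rng.normal(scale=0.05)
        rows[k] = x
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"f{i}" for i in range(n_features)])


# ---------------------------------------------------------------------------
# matrix assembly

def test_split_sizes_and_constant_drop():
    labels = _labels(80)
    desc = _descriptors(labels)
    desc["const"] = 1.0
    fm = build_feature_matrix(desc, labels, "default", 0.2, seed=3)
    assert (fm.split == "train").sum() == 64
    assert (fm.split == "test").sum() == 16
    assert "const" in fm.dropped_constant and "const" not in fm.X.columns


def test_labels_from_propensities_under_each_scheme():
    from acprop.mmp import kinase_propensity, MatchedMolecularPair

    def prop(kid, n_mmps, n_acs):
        mmps = [MatchedMolecularPair("a", "b", kid, "c", "*F", "*[H]",
                                     3.0 if i < n_acs else 0.1, i < n_acs)
                for i in range(n_mmps)]
        return kinase_propensity(kid, mmps, n_mmps)

    counts = [(100, 0), (100, 0), (200, 1), (200, 1),
              (100, 4), (100, 4), (100, 2), (100, 2)]
    props = [prop(f"k{i}", m, a) for i, (m, a) in enumerate(counts)]
    rng = np.random.default_rng(0)
    desc = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"k{i}" for i in range(8)])
    for scheme, expected in (
            ("default", ["No ACs", "Low ACs", "High ACs", "High ACs"]),
            ("A", ["No ACs", "With ACs", "With ACs", "With ACs"]),
            ("B", ["No ACs", "Low ACs", "High ACs", "Low ACs"])):
        fm = build_feature_matrix(desc, props, scheme, test_fraction=0.5, seed=0)
        got = [fm.y.loc[f"k{2 * i}"] for i in range(4)]
        assert got == expected


def test_assembly_errors():
    labels = _labels(10)
    desc = _descriptors(labels).drop(index=["K000"])
    with pytest.raises(AssemblyError):
        build_feature_matrix(desc, labels)
    with pytest.raises(AssemblyError):
        build_feature_matrix(pd.DataFrame(), {})


# ---------------------------------------------------------------------------
# classifiers

@pytest.mark.parametrize("family", ["random_forest", "gradient_boosting", "naive_bayes"])
def test_separable_data_and_seeded_determinism(family):
    labels = _labels(40, seed=1, classes=("No ACs", "High ACs"))
    desc = _descriptors(labels, signal=True, seed=1)
    spec = LearnerSpec(family=family, seed=5)
    y = pd.Series(labels)
    m1 = fit_classifier(desc, y, spec)
    m2 = fit_classifier(desc, y, spec)
    assert (m1.predict(desc) == np.asarray(y)).mean() == 1.0  # separable
    assert np.array_equal(m1.predict(desc), m2.predict(desc))


def test_single_class_labels_rejected():
    labels = {k: "No ACs" for k in ("a", "b", "c")}
    desc = _descriptors(labels)
    with pytest.raises(DegenerateLabelsError):
        fit_classifier(desc, pd.Series(labels), LearnerSpec())


# ---------------------------------------------------------------------------
# cross-validation

def test_leave20_fold_sizes_coverage_and_determinism():
    labels = _labels(64, seed=2)
    desc = _descriptors(labels, seed=2)
    y = pd.Series(labels).loc[desc.index]
    spec = LearnerSpec(seed=0, n_estimators=20)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
    codes = pd.factorize(y)[0]
    sizes = sorted(len(te) for _, te in skf.split(desc, codes))
    assert sizes == [12, 13, 13, 13, 13]
    p1 = leave20_cv(desc, y, spec, seed=9)
    p2 = leave20_cv(desc, y, spec, seed=9)
    assert p1.notna().all() and len(p1) == 64  # every row predicted exactly once
    assert (p1 == p2).all()


def test_leave20_requires_five_rows():
    labels = _labels(4)
    desc = _descriptors(labels)
    with pytest.raises(ValueError):
        leave20_cv(desc, pd.Series(labels), LearnerSpec())


def test_planted_signal_recovery_kappa():
    labels = _labels(60, seed=4)
    desc = _descriptors(labels, signal=True, seed=4)
    y = pd.Series(labels).loc[desc.index]
    preds = leave20_cv(desc, y, LearnerSpec(seed=1), seed=1)
    cm = confusion_matrix(y, preds, tuple(sorted(set(y))))
    assert cohens_kappa(cm) > 0.4


# ---------------------------------------------------------------------------
# metrics

def test_accuracy_closed_forms():
    assert accuracy(np.diag([3, 4, 5])) == 1.0
    assert accuracy(np.array([[2, 1], [1, 2]])) == pytest.approx(4 / 6)
    assert accuracy(np.array([[0, 3], [2, 0]])) == 0.0
    with pytest.raises(ValueError):
        accuracy(np.zeros((2, 2), dtype=int))


def test_kappa_closed_forms():
    assert cohens_kappa(np.diag([5, 7, 9])) == pytest.approx(1.0)
    assert cohens_kappa(np.array([[1, 1], [1, 1]])) == pytest.approx(0.0)
    # hand-worked: Po = 0.7, Pe = 0.5, kappa = 0.4
    assert cohens_kappa(np.array([[20, 5], [10, 15]])) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        cohens_kappa(np.array([[5, 0], [0, 0]]))  # Pe = 1


def test_kappa_agrees_with_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(0)
    for _ in range(10):
        a = rng.integers(0, 3, size=50)
        b = rng.integers(0, 3, size=50)
        cm = confusion_matrix(a, b, (0, 1, 2))
        assert cohens_kappa(cm) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


@given(st.lists(st.integers(0, 20), min_size=9, max_size=9))
def test_kappa_invariant_under_relabeling(entries):
    cm = np.array(entries).reshape(3, 3)
    if cm.sum() == 0:
        return
    perm = [2, 0, 1]
    permuted = cm[np.ix_(perm, perm)]
    po = np.trace(cm) / cm.sum()
    pe = (cm.sum(1) / cm.sum()) @ (cm.sum(0) / cm.sum())
    if pe >= 1 - 1e-12:
        return
    assert cohens_kappa(permuted) == pytest.approx(cohens_kappa(cm), abs=1e-12)


@given(st.lists(st.integers(0, 10), min_size=4, max_size=4))
def test_kappa_one_iff_perfect_accuracy(entries):
    cm = np.array(entries).reshape(2, 2)
    if cm.sum() == 0 or cm.sum(0).max() == cm.sum() or cm.sum(1).max() == cm.sum():
        return  # degenerate marginals
    if accuracy(cm) == 1.0:
        assert cohens_kappa(cm) == pytest.approx(1.0)
    else:
        assert cohens_kappa(cm) < 1.0


def test_kappa_bands():
    assert kappa_band(0.49) == "moderate"
    assert kappa_band(1.0) == "almost perfect"
    assert kappa_band(-0.1) == "worse than random"
    assert kappa_band(0.1) == "none to slight"
    assert kappa_band(0.3) == "fair"
    assert kappa_band(0.7) == "substantial"


def test_evaluate_report():
    y = ["No ACs"] * 5 + ["High ACs"] * 5
    p = ["No ACs"] * 4 + ["High ACs"] * 6
    rep = evaluate(y, p, ("No ACs", "High ACs"))
    assert rep.accuracy == pytest.approx(0.9)
    assert rep.per_class_recall["No ACs"] == pytest.approx(0.8)
    assert rep.per_class_recall["High ACs"] == pytest.approx(1.0)
    assert -1 <= rep.kappa <= 1 and rep.band
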