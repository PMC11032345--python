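"""Feature selection and chance-correlation control.

Three stages guard the classifiers against the 9920-dimensional descriptor
space:

* **Global feature importance (GFI).**  A surrogate random forest is trained
  to reproduce (overfit) a fitted model's predictions; a feature's score is
  the depth-weighted tally of its splits over all surrogate trees (weight
  1/(1+level), shallower splits weigh more).  Features scoring > 0 are
  retained.
* **Genetic algorithm (GA) wrapper selection.**  Binary chromosomes over the
  candidate features, fitness = Cohen's kappa of leave-20%-out CV of the
  wrapped learner on the selected subset; tournament selection, uniform
  crossover, per-bit mutation, elitism, early stop on stagnation.
* **Y-scrambling.**  Class labels are permuted per trial and the CV is
  re-run, producing a null distribution of accuracy and kappa against which
  the unscrambled model must stand out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .ml import LearnerSpec, cohens_kappa, confusion_matrix, leave20_cv


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by descending surrogate-forest importance."""

    scores: tuple[tuple[str, float], ...]

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(name for name, s in self.scores if s > 0)

    def top(self, n: int) -> tuple[str, ...]:
        return tuple(name for name, _ in self.scores[:n])


@dataclass(frozen=True)
class Chromosome:
    """A binary feature mask with its CV-kappa fitness."""

    mask: tuple[int, ...]
    features: tuple[str, ...]
    fitness: float

    def __post_init__(self):
        if sum(self.mask) < 1:
            raise ValueError("chromosome must select at least one feature")


@dataclass
class GAParams:
    """Wrapper-GA settings; the full-scale defaults are population 100 with
    at most 500 generations, kappa fitness."""

    population: int = 100
    generations: int = 500
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/L
    tournament: int = 3
    elitism: int = 1
    stagnation: int = 50

    def scaled(self, population: int, generations: int) -> "GAParams":
        return GAParams(population, generations, self.crossover_rate,
                        self.mutation_rate, self.tournament, self.elitism,
                        self.stagnation)


@dataclass
class ScramblingReport:
    """Null distribution of CV metrics under label permutation."""

    n_trials: int
    accuracies: np.ndarray
    kappas: np.ndarray
    original_accuracy: float
    original_kappa: float

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_kappa(self) -> float:
        return float(self.kappas.mean())

    @property
    def max_accuracy(self) -> float:
        return float(self.accuracies.max())

    @property
    def max_kappa(self) -> float:
        return float(self.kappas.max())

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "mean_accuracy": self.mean_accuracy, "max_accuracy": self.max_accuracy,
            "mean_kappa": self.mean_kappa, "max_kappa": self.max_kappa,
            "original_accuracy": self.original_accuracy,
            "original_kappa": self.original_kappa,
        }


def global_feature_importance(X: pd.DataFrame, model, seed: int = 0,
                              n_trees: int = 100) -> ImportanceRanking:
    """Depth-weighted split tally over a surrogate forest mimicking ``model``.

    The surrogate is deliberately unconstrained (full-depth trees) so it can
    overfit the model's predictions.  Score(f) = sum over surrogate splits on
    f of 1/(1+level).  Ties are broken by feature name for determinism.
    """
    preds = model.predict(X)
    if len(set(preds)) < 2:
        raise ValueError("degenerate model predictions; surrogate cannot be fit")
    classes = sorted(set(preds))
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[p] for p in preds])
    surrogate = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    surrogate.fit(X.to_numpy(), y)
    scores = np.zeros(X.shape[1])
    for est in surrogate.estimators_:
        tree = est.tree_
        stack = [(0, 0)]  # (node, level)
        while stack:
            node, level = stack.pop()
            left, right = tree.children_left[node], tree.children_right[node]
            if left == -1:
                continue
            scores[tree.feature[node]] += 1.0 / (1 + level)
            stack.append((left, level + 1))
            stack.append((right, level + 1))
    order = sorted(zip(X.columns, scores), key=lambda t: (-t[1], t[0]))
    return ImportanceRanking(tuple((n, float(s)) for n, s in order))


def _cv_kappa(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec, seed: int,
              scheme: str) -> tuple[float, float]:
    preds = leave20_cv(X, y, spec, seed=seed, scheme=scheme)
    classes = tuple(sorted(set(y)))
    cm = confusion_matrix(y, preds, classes)
    return cohens_kappa(cm), float(np.trace(cm)) / cm.sum()


def ga_feature_select(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec,
                      candidates: list[str] | None = None,
                      params: GAParams | None = None, seed: int = 0,
                      scheme: str = "default") -> Chromosome:
    """GA wrapper selection over ``candidates`` maximizing CV kappa.

    All-zero chromosomes are assigned -inf fitness and can never be returned.
    Elitism makes the best fitness non-decreasing across generations; the
    search stops early after ``params.stagnation`` generations without
    improvement.  Fully seeded and deterministic.
    """
    params = params or GAParams()
    candidates = list(candidates) if candidates is not None else list(X.columns)
    if not candidates:
        raise ValueError("empty candidate feature set")
    missing = set(candidates) - set(X.columns)
    if missing:
        raise ValueError(f"candidates not in matrix: {sorted(missing)}")
    L = len(candidates)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    mut = params.mutation_rate if params.mutation_rate is not None else 1.0 / L
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        if mask.sum() == 0:
            return -np.inf
        key = mask.tobytes()
        if key not in cache:
            cols = [c for c, m in zip(candidates, mask) if m]
            kappa, _ = _cv_kappa(X[cols], y, spec, seed, scheme)
            cache[key] = kappa
        return cache[key]

    pop = (rng.random((params.population, L)) < 0.5).astype(np.int8)
    for row in pop:
        if row.sum() == 0:
            row[rng.integers(L)] = 1
    fits = np.array([fitness(m) for m in pop])
    best_i = int(np.argmax(fits))
    best_mask, best_fit = pop[best_i].copy(), float(fits[best_i])
    stagnant = 0
    for _gen in range(params.generations):
        order = np.argsort(-fits)
        new = [pop[i].copy() for i in order[:params.elitism]]
        while len(new) < params.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, params.population, size=params.tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            a, b = parents
            if rng.random() < params.crossover_rate:
                swap = rng.random(L) < 0.5
                child = np.where(swap, a, b).astype(np.int8)
            else:
                child = a.copy()
            flip = rng.random(L) < mut
            child = np.where(flip, 1 - child, child).astype(np.int8)
            if child.sum() == 0:
                child[rng.integers(L)] = 1
            new.append(child)
        pop = np.array(new)
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= params.stagnation:
                break
    features = tuple(c for c, m in zip(candidates, best_mask) if m)
    return Chromosome(tuple(int(v) for v in best_mask), features, best_fit)


def y_scramble(X: pd.DataFrame, y: pd.Series, spec: LearnerSpec,
               features: list[str] | None = None, n_trials: int = 1000,
               seed: int = 0, scheme: str = "default") -> ScramblingReport:
    """Label-permutation null of leave-20%-out accuracy and kappa.

    Per trial the class labels are permuted uniformly at random (preserving
    the class marginals) and the CV is re-run on the chosen feature subset.
    The report carries the per-trial metrics plus the original (unscrambled)
    metrics for contrast.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cols = list(features) if features is not None else list(X.columns)
    Xs = X[cols]
    orig_kappa, orig_acc = _cv_kappa(Xs, y, spec, seed, scheme)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    accs, kappas = np.empty(n_trials), np.empty(n_trials)
    yv = y.to_numpy()
    for t in range(n_trials):
        perm = pd.Series(rng.permutation(yv), index=y.index)
        kappas[t], accs[t] = _cv_kappa(Xs, perm, spec, seed, scheme)
    return ScramblingReport(n_trials, accs, kappas, orig_acc, orig_kappa)
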