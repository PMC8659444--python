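"""SVM validation of a channel selection, and the prediction metrics.

The selected channels (or all channels, for the paired baseline) feed an
RBF-kernel support vector machine.  Three optimizer variants are available:

* ``lm`` — a single dual solve at fixed default hyperparameters
  (C = 1, gamma = 1/n_features), i.e. the plain Lagrange-multiplier fit;
* ``evolutionary`` — a small differential-evolution search over
  (log2 C, log2 gamma);
* ``pso`` — a particle-swarm search over the same space.

The searches score candidates by stratified CV accuracy on the *training*
partition only, and the best variant is likewise adopted on training CV —
never on test performance.  Window-level results are summarized as the
four confusion quadrants (I: true pre-ictal hits, II: false alarms,
III: misses, IV: true normals) and as an event-level *prediction rate*: the
percentage of test seizures with at least one pre-ictal-classified window
inside their prediction horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SvmSpec",
    "ConfusionCounts",
    "EvaluationReport",
    "train_svm",
    "confusion_counts",
    "metrics_from_counts",
    "prediction_rate",
    "run_validation",
]

PREICTAL = "preictal"
NORMAL = "normal"

#: log2 search space for (C, gamma), and the evaluation budget per search
_LOG2_C_RANGE = (-5.0, 15.0)
_LOG2_GAMMA_RANGE = (-15.0, 3.0)
_N_EVALS = 30


@dataclass(frozen=True)
class SvmSpec:
    optimizer: Literal["lm", "evolutionary", "pso"] = "lm"
    kernel: Literal["rbf", "linear"] = "rbf"
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("lm", "evolutionary", "pso"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FittedSvm:
    """A trained decision function plus the search's own CV score."""

    model: SVC
    scaler: StandardScaler
    spec: SvmSpec
    C: float
    gamma: float
    cv_accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(X))


@dataclass(frozen=True)
class ConfusionCounts:
    """Quadrants of the pre-ictal/normal confusion table.

    I: pre-ictal predicted pre-ictal; II: normal predicted pre-ictal;
    III: pre-ictal predicted normal; IV: normal predicted normal.
    """

    I: int
    II: int
    III: int
    IV: int

    def __post_init__(self) -> None:
        if min(self.I, self.II, self.III, self.IV) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.I + self.II + self.III + self.IV


@dataclass
class EvaluationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    prediction_rate: float
    per_seizure_flags: dict[int, bool]
    counts: ConfusionCounts
    optimizer: str
    channels_used: tuple[int, ...]
    C: float
    gamma: float
    train_cv_accuracy: float


def _fit_at(X, y, spec: SvmSpec, C: float, gamma: float) -> SVC:
    return SVC(C=C, gamma=gamma, kernel=spec.kernel, random_state=0).fit(X, y)


def _cv_accuracy(X, y, spec: SvmSpec, C: float, gamma: float) -> float:
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    correct = 0
    for tr, te in skf.split(X, y):
        model = _fit_at(X[tr], y[tr], spec, C, gamma)
        correct += int((model.predict(X[te]) == y[te]).sum())
    return correct / len(y)


def _search_de(score, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Tiny differential evolution (rand/1/bin) on the 2-D log2 space."""
    lo = np.array([_LOG2_C_RANGE[0], _LOG2_GAMMA_RANGE[0]])
    hi = np.array([_LOG2_C_RANGE[1], _LOG2_GAMMA_RANGE[1]])
    n_pop, n_gen = 6, (_N_EVALS - 6) // 6  # 6 + 6*4 = 30 evaluations
    pop = lo + rng.random((n_pop, 2)) * (hi - lo)
    fit = np.array([score(x) for x in pop])
    for _ in range(n_gen):
        for i in range(n_pop):
            a, b, c = rng.choice(n_pop, size=3, replace=False)
            trial = np.clip(pop[a] + 0.8 * (pop[b] - pop[c]), lo, hi)
            cross = rng.random(2) < 0.9
            if not cross.any():
                cross[rng.integers(2)] = True
            trial = np.where(cross, trial, pop[i])
            f = score(trial)
            if f >= fit[i]:
                pop[i], fit[i] = trial, f
    best = int(fit.argmax())
    return pop[best], float(fit[best])


def _search_pso(score, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Tiny particle swarm on the 2-D log2 space."""
    lo = np.array([_LOG2_C_RANGE[0], _LOG2_GAMMA_RANGE[0]])
    hi = np.array([_LOG2_C_RANGE[1], _LOG2_GAMMA_RANGE[1]])
    n_pop, n_iter = 6, _N_EVALS // 6 - 1  # 6 + 6*4 = 30 evaluations
    pos = lo + rng.random((n_pop, 2)) * (hi - lo)
    vel = (rng.random((n_pop, 2)) - 0.5) * (hi - lo) * 0.2
    fit = np.array([score(x) for x in pos])
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(fit.argmax())
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    for _ in range(n_iter):
        r1, r2 = rng.random((n_pop, 2)), rng.random((n_pop, 2))
        vel = 0.7 * vel + 1.5 * r1 * (pbest - pos) + 1.5 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        fit = np.array([score(x) for x in pos])
        better = fit > pbest_fit
        pbest[better], pbest_fit[better] = pos[better], fit[better]
        if pbest_fit.max() > gbest_fit:
            g = int(pbest_fit.argmax())
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    return gbest, gbest_fit


def train_svm(X_train: np.ndarray, y_train: np.ndarray, spec: SvmSpec) -> FittedSvm:
    """Fit an SVM under the requested optimizer variant.

    Standardization (train-set mean/SD) is part of the fitted model.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")
    scaler = StandardScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    default_gamma = 1.0 / X_train.shape[1]
    if spec.optimizer == "lm":
        C, gamma = 1.0, default_gamma
        cv = _cv_accuracy(Xs, y_train, spec, C, gamma)
    else:
        rng = np.random.default_rng(spec.seed)
        cache: dict[tuple[float, float], float] = {}

        def score(x: np.ndarray) -> float:
            key = (round(float(x[0]), 10), round(float(x[1]), 10))
            if key not in cache:
                cache[key] = _cv_accuracy(Xs, y_train, spec, 2.0 ** x[0], 2.0 ** x[1])
            return cache[key]

        search = _search_de if spec.optimizer == "evolutionary" else _search_pso
        best_x, cv = search(score, rng)
        C, gamma = 2.0 ** best_x[0], 2.0 ** best_x[1]
    model = _fit_at(Xs, y_train, spec, C, gamma)
    return FittedSvm(model=model, scaler=scaler, spec=spec, C=C, gamma=gamma, cv_accuracy=cv)


def confusion_counts(predictions: Sequence[str], truths: Sequence[str]) -> ConfusionCounts:
    """Tally the four quadrants of the pre-ictal/normal table."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths differ in length")
    return ConfusionCounts(
        I=int(((predictions == PREICTAL) & (truths == PREICTAL)).sum()),
        II=int(((predictions == PREICTAL) & (truths == NORMAL)).sum()),
        III=int(((predictions == NORMAL) & (truths == PREICTAL)).sum()),
        IV=int(((predictions == NORMAL) & (truths == NORMAL)).sum()),
    )


def metrics_from_counts(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent.

    A metric whose denominator is zero is undefined and returned as NaN,
    never as 0 — a printed 0.00 means "all pre-ictal windows missed", not
    "no pre-ictal windows to miss".
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    accuracy = 100.0 * (c.I + c.IV) / c.total
    sensitivity = 100.0 * c.I / (c.I + c.III) if c.I + c.III else math.nan
    specificity = 100.0 * c.IV / (c.II + c.IV) if c.II + c.IV else math.nan
    return accuracy, sensitivity, specificity


def prediction_rate(
    per_seizure_window_predictions: Mapping[int, Sequence[str]],
    event_rule: Literal["any", "majority"] = "any",
) -> tuple[float, dict[int, bool]]:
    """Event-level rate: % of test seizures flagged as predicted.

    Under the default ``any`` rule a seizure is predicted when at least one
    of its SPH windows is classified pre-ictal; ``majority`` requires more
    than half.  Returns (rate %, per-seizure flags).
    """
    if not per_seizure_window_predictions:
        raise ValueError("no test seizures")
    flags: dict[int, bool] = {}
    for idx, preds in per_seizure_window_predictions.items():
        hits = sum(p == PREICTAL for p in preds)
        flags[idx] = hits >= 1 if event_rule == "any" else hits > len(preds) / 2
    rate = 100.0 * sum(flags.values()) / len(flags)
    return rate, flags


def run_validation(
    train,
    test,
    channels: Sequence[int] | None,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    optimizers: Sequence[str] = ("lm", "evolutionary", "pso"),
    seed: int = 0,
    event_rule: Literal["any", "majority"] = "any",
) -> EvaluationReport:
    """Train each optimizer variant, adopt the best by training CV, report.

    ``train``/``test`` are the LabeledWindow sequences that produced the
    feature matrices (row-aligned); ``channels`` is a 1-based channel subset
    or None for all channels.  The paired selected-vs-all comparison is run
    by calling this twice with identical windows, features and seed.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if channels is not None:
        cols = [c - 1 for c in channels]
        X_train, X_test = X_train[:, cols], X_test[:, cols]
        used = tuple(sorted(channels))
    else:
        used = tuple(range(1, X_train.shape[1] + 1))
    fits = [
        train_svm(X_train, y_train, SvmSpec(optimizer=opt, seed=seed))
        for opt in optimizers
    ]
    best = max(fits, key=lambda f: f.cv_accuracy)
    preds = best.predict(X_test)
    counts = confusion_counts(preds, y_test)
    accuracy, sensitivity, specificity = metrics_from_counts(counts)
    by_seizure: dict[int, list[str]] = {}
    for w, p in zip(test, preds):
        if w.label == PREICTAL:
            by_seizure.setdefault(w.seizure_index, []).append(p)
    rate, flags = prediction_rate(by_seizure, event_rule) if by_seizure else (math.nan, {})
    return EvaluationReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        prediction_rate=rate,
        per_seizure_flags=flags,
        counts=counts,
        optimizer=best.spec.optimizer,
        channels_used=used,
        C=best.C,
        gamma=best.gamma,
        train_cv_accuracy=best.cv_accuracy,
    )
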