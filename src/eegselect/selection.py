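"""Wrapper channel selection: genetic search over binary channel masks
scored by KNN classification of permutation-entropy features.

A chromosome is a binary vector over EEG channels (gene on = the channel's
PE feature is used; at least one gene must be on).  Fitness is stratified
cross-validated accuracy of a K-nearest-neighbors classifier restricted to
the on-genes.  Each generation keeps the fittest individuals and breeds the
rest by fitness-proportionate parent selection, uniform crossover and
per-gene mutation; the search stops when the best fitness stalls or a
generation cap is reached.

KNN is written out explicitly (rather than delegated) because the tie rules
are part of the contract: distance ties resolve to the lower training index,
vote ties to the class of the single nearest neighbor.  That makes every
prediction reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Chromosome",
    "GaConfig",
    "KnnConfig",
    "SelectionResult",
    "knn_classify",
    "chromosome_fitness",
    "selection_probabilities",
    "uniform_crossover",
    "mutate",
    "run_knn_ga",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Chromosome:
    """Binary channel mask; at least one gene must be on."""

    genes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(g in (0, 1) for g in self.genes):
            raise ValueError("genes must be 0/1")
        if sum(self.genes) < 1:
            raise ValueError("a chromosome must have at least one gene on")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def on_indices(self) -> tuple[int, ...]:
        """1-based indices of the selected channels."""
        return tuple(i + 1 for i, g in enumerate(self.genes) if g)

    @property
    def mask(self) -> np.ndarray:
        return np.asarray(self.genes, dtype=bool)


@dataclass(frozen=True)
class GaConfig:
    pop_size: int = 20
    max_generations: int = 30
    crossover_prob: float = 1.0
    mutation_rate: float = 0.01
    reproductive_fraction: float = 0.9
    elitism: int = 1
    convergence_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        for name in ("crossover_prob", "mutation_rate", "reproductive_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class KnnConfig:
    k: int = 5
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class SelectionResult:
    best: Chromosome
    selected_channels: tuple[int, ...]
    fitness_history: list[float]
    generations_run: int
    ga_config: GaConfig
    knn_config: KnnConfig


def knn_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    cfg: KnnConfig = KnnConfig(),
) -> np.ndarray:
    """Majority vote among the k Euclidean-nearest training points.

    Ties are deterministic: equal distances rank by training index, and a
    tied vote goes to the class of the nearest neighbor.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.shape[1] != test_X.shape[1]:
        raise ValueError("train/test feature dimensions differ")
    if cfg.k > len(train_X):
        raise ValueError(f"k={cfg.k} exceeds {len(train_X)} training samples")
    diff = test_X[:, None, :] - train_X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    # stable argsort: equal distances keep ascending training-index order
    order = np.argsort(d2, axis=1, kind="stable")[:, : cfg.k]
    preds = np.empty(len(test_X), dtype=train_y.dtype)
    for i, nbrs in enumerate(order):
        labels, votes = np.unique(train_y[nbrs], return_counts=True)
        top = labels[votes == votes.max()]
        preds[i] = top[0] if len(top) == 1 else train_y[nbrs[0]]
    return preds


def chromosome_fitness(
    chrom: Chromosome,
    X: np.ndarray,
    y: np.ndarray,
    knn_cfg: KnnConfig = KnnConfig(),
    seed: int = 0,
) -> float:
    """Stratified CV accuracy of KNN on the chromosome's channel columns.

    Features are standardized per fold with training-fold statistics, so
    no column's scale dominates the Euclidean metric.  Deterministic given
    ``seed`` (which fixes the fold assignment).
    """
    X = np.asarray(X, dtype=float)[:, chrom.mask]
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("fitness needs both classes present")
    skf = StratifiedKFold(n_splits=knn_cfg.cv_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        pred = knn_classify((X[tr] - mu) / sd, y[tr], (X[te] - mu) / sd, knn_cfg)
        correct += int((pred == y[te]).sum())
    return correct / len(y)


def selection_probabilities(fitnesses: np.ndarray) -> np.ndarray:
    """Fitness-proportionate selection: p_i = f_i / sum(f)."""
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    if total == 0:
        logger.warning("all fitnesses zero; falling back to uniform selection")
        return np.full(len(f), 1.0 / len(f))
    return f / total


def _repair(genes: np.ndarray, rng: np.random.Generator) -> Chromosome:
    if genes.sum() < 1:
        genes = genes.copy()
        genes[rng.integers(len(genes))] = 1
    return Chromosome(tuple(int(g) for g in genes))


def uniform_crossover(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> Chromosome:
    """Each locus copied from either parent with probability 1/2."""
    if len(a) != len(b):
        raise ValueError("parent lengths differ")
    take_a = rng.random(len(a)) < 0.5
    child = np.where(take_a, a.genes, b.genes)
    return _repair(child, rng)


def mutate(c: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    """Flip each gene independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("mutation rate must be in [0, 1]")
    flips = rng.random(len(c)) < rate
    genes = np.asarray(c.genes) ^ flips
    return _repair(genes.astype(int), rng)


def run_knn_ga(
    X: np.ndarray,
    y: np.ndarray,
    ga_cfg: GaConfig = GaConfig(),
    knn_cfg: KnnConfig = KnnConfig(),
) -> SelectionResult:
    """Genetic search for the channel subset maximizing KNN CV accuracy.

    Per generation: evaluate fitness; copy the fittest into the
    non-reproductive slots (at least ``elitism`` of them); fill the
    reproductive fraction with children of fitness-proportionate parents via
    uniform crossover then mutation.  Stops when the best fitness has not
    improved for ``convergence_window`` generations or at the generation
    cap; returns the best chromosome ever evaluated.
    """
    X = np.asarray(X, dtype=float)
    n_genes = X.shape[1]
    rng = np.random.default_rng(ga_cfg.seed)
    cache: dict[tuple[int, ...], float] = {}

    def fitness(c: Chromosome) -> float:
        if c.genes not in cache:
            cache[c.genes] = chromosome_fitness(c, X, y, knn_cfg, seed=ga_cfg.seed)
        return cache[c.genes]

    population = [
        _repair((rng.random(n_genes) < 0.5).astype(int), rng)
        for _ in range(ga_cfg.pop_size)
    ]
    n_breed = int(round(ga_cfg.reproductive_fraction * ga_cfg.pop_size))
    n_breed = min(n_breed, ga_cfg.pop_size - ga_cfg.elitism)

    best_ever: Chromosome | None = None
    best_fit = -np.inf
    history: list[float] = []
    stall = 0
    gen = 0
    for gen in range(1, ga_cfg.max_generations + 1):
        fits = np.array([fitness(c) for c in population])
        gen_best = float(fits.max())
        if gen_best > best_fit + 1e-12:
            best_fit = gen_best
            best_ever = population[int(fits.argmax())]
            stall = 0
        else:
            stall += 1
        history.append(best_fit)
        if stall >= ga_cfg.convergence_window or gen == ga_cfg.max_generations:
            break
        # survivors: the fittest fill the non-reproductive slots
        elite_order = np.argsort(-fits, kind="stable")
        survivors = [population[i] for i in elite_order[: ga_cfg.pop_size - n_breed]]
        probs = selection_probabilities(fits)
        children = []
        for _ in range(n_breed):
            pa, pb = rng.choice(len(population), size=2, p=probs)
            child = (
                uniform_crossover(population[pa], population[pb], rng)
                if rng.random() < ga_cfg.crossover_prob
                else population[pa]
            )
            children.append(mutate(child, ga_cfg.mutation_rate, rng))
        population = survivors + children
    assert best_ever is not None
    return SelectionResult(
        best=best_ever,
        selected_channels=best_ever.on_indices,
        fitness_history=history,
        generations_run=gen,
        ga_config=ga_cfg,
        knn_config=knn_cfg,
    )
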