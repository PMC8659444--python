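"""KNN classifier (with its exact tie rules), GA operators, and the full
channel search, checked against brute-force oracles and the planted
ground truth of the synthetic cohort."""

import numpy as np
import pytest

import eegselect as es
from eegselect.selection import _repair

# ---------------------------------------------------------------- oracle


def oracle_knn(train_X, train_y, test_X, k):
    """Pure-Python exhaustive KNN with the same declared tie rules."""
    preds = []
    for x in test_X:
        dists = sorted(
            (sum((float(a) - float(b)) ** 2 for a, b in zip(x, t)), i)
            for i, t in enumerate(train_X)
        )
        nbrs = [i for _, i in dists[:k]]
        votes = {}
        for i in nbrs:
            votes[train_y[i]] = votes.get(train_y[i], 0) + 1
        top = max(votes.values())
        winners = [lab for lab, v in votes.items() if v == top]
        preds.append(winners[0] if len(winners) == 1 else train_y[nbrs[0]])
    return np.array(preds)


# ---------------------------------------------------------------- KNN


def test_knn_matches_bruteforce_oracle():
    rng = np.random.default_rng(17)
    for trial in range(200):
        n_train = int(rng.integers(6, 41))
        n_test = int(rng.integers(1, 15))
        train_X = rng.normal(size=(n_train, 2))
        train_y = rng.choice(["preictal", "normal"], size=n_train)
        test_X = rng.normal(size=(n_test, 2))
        for k in (1, 3, 5):
            got = es.knn_classify(train_X, train_y, test_X, es.KnnConfig(k=k))
            np.testing.assert_array_equal(got, oracle_knn(train_X, train_y, test_X, k))


def test_knn_zero_distance_and_tie_rules():
    train_X = np.array([[0.0], [1.0], [2.0]])
    train_y = np.array(["a", "b", "b"])
    # test point identical to a training point, k=1 -> that point's label
    assert es.knn_classify(train_X, train_y, [[1.0]], es.KnnConfig(k=1))[0] == "b"
    # equidistant neighbors at k=1: lower training index wins
    assert es.knn_classify(train_X, train_y, [[0.5]], es.KnnConfig(k=1))[0] == "a"
    # vote tie at k=2: class of the single nearest neighbor
    assert es.knn_classify(train_X, train_y, [[0.4]], es.KnnConfig(k=2))[0] == "a"


def test_knn_k_equals_train_size_gives_majority():
    rng = np.random.default_rng(1)
    train_X = rng.normal(size=(9, 3))
    train_y = np.array(["a"] * 5 + ["b"] * 4)
    preds = es.knn_classify(train_X, train_y, rng.normal(size=(20, 3)), es.KnnConfig(k=9))
    assert (preds == "a").all()


def test_knn_input_validation():
    X = np.zeros((3, 2))
    y = np.array(["a", "b", "a"])
    with pytest.raises(ValueError, match="k="):
        es.knn_classify(X, y, X, es.KnnConfig(k=4))
    with pytest.raises(ValueError, match="dimension"):
        es.knn_classify(X, y, np.zeros((2, 3)), es.KnnConfig(k=1))


# ---------------------------------------------------------------- fitness


def test_fitness_on_perfectly_separating_column():
    rng = np.random.default_rng(2)
    n = 100
    X = rng.normal(size=(n, 5))
    y = np.array(["preictal"] * (n // 2) + ["normal"] * (n // 2))
    X[: n // 2, 3] += 10.0  # column 4 separates the classes
    chrom = es.Chromosome((0, 0, 0, 1, 0))
    assert es.chromosome_fitness(chrom, X, y, seed=0) >= 0.95


def test_fitness_on_permuted_labels_is_chance():
    rng = np.random.default_rng(3)
    n = 200
    X = rng.normal(size=(n, 4))
    y = rng.permutation(np.array(["preictal", "normal"] * (n // 2)))
    fit = es.chromosome_fitness(es.Chromosome((1, 1, 1, 1)), X, y, seed=0)
    sigma = 0.5 / np.sqrt(n)  # binomial sd of the accuracy at p = 1/2
    assert abs(fit - 0.5) < 3 * sigma


def test_fitness_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        es.Chromosome((0, 0, 0))
    X = np.zeros((10, 3))
    with pytest.raises(ValueError, match="classes"):
        es.chromosome_fitness(es.Chromosome((1, 0, 0)), X, np.array(["a"] * 10))


def test_fitness_deterministic_given_seed(small_features):
    X, y, _ = small_features
    chrom = es.Chromosome(tuple([1] * X.shape[1]))
    assert es.chromosome_fitness(chrom, X, y, seed=5) == es.chromosome_fitness(
        chrom, X, y, seed=5
    )


# ---------------------------------------------------------------- operators


def test_selection_probabilities():
    np.testing.assert_allclose(es.selection_probabilities([1, 1, 1, 1]), [0.25] * 4)
    np.testing.assert_allclose(es.selection_probabilities([3, 1]), [0.75, 0.25])
    p = es.selection_probabilities(np.random.default_rng(0).random(50))
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(es.selection_probabilities([0.0, 0.0]), [0.5, 0.5])
    with pytest.raises(ValueError):
        es.selection_probabilities([-1.0, 2.0])


def test_fitness_proportionate_sampling_frequencies():
    # empirical parent-draw frequencies match p_i within 3 sigma at 10^4 draws
    fitnesses = np.array([0.9, 0.6, 0.3, 0.15, 0.05])
    p = es.selection_probabilities(fitnesses)
    rng = np.random.default_rng(8)
    n = 10_000
    draws = rng.choice(len(p), size=n, p=p)
    counts = np.bincount(draws, minlength=len(p))
    for i in range(len(p)):
        sigma = np.sqrt(n * p[i] * (1 - p[i]))
        assert abs(counts[i] - n * p[i]) < 3 * sigma


def test_uniform_crossover_properties():
    rng = np.random.default_rng(4)
    a = es.Chromosome((1, 0, 1, 0, 1, 0, 1, 0))
    b = es.Chromosome((0, 1, 1, 0, 0, 1, 1, 0))
    assert es.uniform_crossover(a, a, rng).genes == a.genes
    for _ in range(50):
        child = es.uniform_crossover(a, b, rng)
        assert all(g in (pa, pb) for g, pa, pb in zip(child.genes, a.genes, b.genes))
        assert sum(child.genes) >= 1
    c1 = es.uniform_crossover(a, b, np.random.default_rng(7))
    c2 = es.uniform_crossover(a, b, np.random.default_rng(7))
    assert c1.genes == c2.genes
    with pytest.raises(ValueError):
        es.uniform_crossover(a, es.Chromosome((1, 0)), rng)


def test_mutate():
    rng = np.random.default_rng(5)
    c = es.Chromosome((1, 0, 1, 1, 0))
    assert es.mutate(c, 0.0, rng).genes == c.genes
    assert es.mutate(c, 1.0, rng).genes == (0, 1, 0, 0, 1)
    # flipping off the only on-gene triggers repair back to >= 1
    single = es.Chromosome((0, 1, 0))
    for seed in range(10):
        assert sum(es.mutate(single, 1.0, np.random.default_rng(seed)).genes) >= 1
    assert sum(_repair(np.zeros(4, dtype=int), rng).genes) == 1


# ---------------------------------------------------------------- full GA


def test_ga_recovers_planted_channels(small_features):
    X, y, truth = small_features
    hits = 0
    for seed in range(5):
        res = es.run_knn_ga(X, y, es.GaConfig(seed=seed))
        hits += len(set(res.selected_channels) & truth) >= 1
        assert res.generations_run <= 30
        assert res.selected_channels == res.best.on_indices
        assert all(
            b >= a for a, b in zip(res.fitness_history, res.fitness_history[1:])
        ), "best-so-far history must be non-decreasing"
    assert hits >= 4


def test_ga_fixed_point_without_variation(small_features):
    # no mutation, no crossover, full elitism -> the population cannot move,
    # so the search stalls and stops at the convergence window
    X, y, _ = small_features
    cfg = es.GaConfig(
        pop_size=4, mutation_rate=0.0, crossover_prob=0.0,
        elitism=4, reproductive_fraction=0.0, convergence_window=3, seed=0,
    )
    idx = np.r_[np.where(y == "preictal")[0][:20], np.where(y == "normal")[0][:20]]
    res = es.run_knn_ga(X[idx], y[idx], cfg, es.KnnConfig(k=1, cv_folds=2))
    assert res.generations_run == 1 + cfg.convergence_window
    assert len(set(res.fitness_history)) == 1


def test_ga_deterministic_given_seed(small_features):
    X, y, _ = small_features
    cfg = es.GaConfig(pop_size=6, max_generations=5, seed=3)
    r1 = es.run_knn_ga(X, y, cfg)
    r2 = es.run_knn_ga(X, y, cfg)
    assert r1.best.genes == r2.best.genes
    assert r1.fitness_history == r2.fitness_history
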