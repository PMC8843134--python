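"""Genetic-algorithm operators and end-to-end optimization."""

import numpy as np
import pytest

from fertopt.ga import (
    GAConfig,
    _selection_probs,
    init_population,
    optimize,
    roulette_select,
    two_point_crossover,
    uniform_mutation,
)

BOUNDS = ((0.0, 200.0), (0.0, 300.0), (0.0, 100.0))


def test_config_invariants():
    with pytest.raises(ValueError):
        GAConfig(crossover_rate=1.5)
    with pytest.raises(ValueError):
        GAConfig(mutation_rate=-0.1)
    with pytest.raises(ValueError):
        GAConfig(population=1)
    with pytest.raises(ValueError):
        GAConfig(bounds=((1.0, 1.0),))


def test_init_population_within_bounds_and_deterministic():
    conf = GAConfig(seed=3)
    pop = init_population(conf)
    assert pop.shape == (200, 3)
    for g, (lo, hi) in enumerate(conf.bounds):
        assert np.all(pop[:, g] >= lo) and np.all(pop[:, g] <= hi)
    np.testing.assert_array_equal(pop, init_population(GAConfig(seed=3)))
    tight = GAConfig(bounds=((5.0, 5.0 + 1e-9),) * 3, seed=0)
    assert np.allclose(init_population(tight), 5.0, atol=1e-8)


def test_selection_probabilities_proportional_to_shifted_fitness():
    fit = np.array([0.0, 2.0, 6.0])
    shifted = fit - fit.min() + 0.01 * (fit.max() - fit.min())
    np.testing.assert_allclose(_selection_probs(fit), shifted / shifted.sum())
    # two individuals whose shifted weights are 1:3 select at 25%/75%
    probs = _selection_probs(fit)
    assert probs[2] / probs[1] == pytest.approx(shifted[2] / shifted[1])


def test_roulette_uniform_when_fitness_equal():
    rng = np.random.default_rng(0)
    pop = np.zeros((4, 3))
    fit = np.full(4, 2.5)
    draws = np.array([roulette_select(pop, fit, rng) for _ in range(100_000)])
    counts = np.bincount(draws, minlength=4)
    expected = 25_000
    sd = np.sqrt(100_000 * 0.25 * 0.75)
    assert np.all(np.abs(counts - expected) <= 3 * sd)


def test_roulette_singleton_and_errors():
    rng = np.random.default_rng(1)
    assert roulette_select(np.zeros((1, 3)), [1.0], rng) == 0
    with pytest.raises(ValueError):
        roulette_select(np.zeros((0, 3)), [], rng)
    with pytest.raises(ValueError):
        roulette_select(np.zeros((2, 3)), [np.nan, 1.0], rng)


def test_crossover_identical_parents_idempotent():
    rng = np.random.default_rng(2)
    a = np.array([1.0, 2.0, 3.0])
    ca, cb = two_point_crossover(a, a.copy(), p_c=1.0, rng=rng)
    np.testing.assert_array_equal(ca, a)
    np.testing.assert_array_equal(cb, a)


def test_crossover_disabled_copies_parents():
    rng = np.random.default_rng(3)
    a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    ca, cb = two_point_crossover(a, b, p_c=0.0, rng=rng)
    np.testing.assert_array_equal(ca, a)
    np.testing.assert_array_equal(cb, b)


def test_crossover_enumerates_three_cut_pairs():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([10.0, 20.0, 30.0])
    # cuts (1,2) -> swap gene 1; (1,3) -> swap genes 1..2; (2,3) -> swap gene 2
    expected = {(1.0, 20.0, 3.0), (1.0, 20.0, 30.0), (1.0, 2.0, 30.0)}
    seen = set()
    rng = np.random.default_rng(4)
    for _ in range(300):
        ca, cb = two_point_crossover(a, b, p_c=1.0, rng=rng)
        seen.add(tuple(ca))
        # every child gene comes from one of the parents at that locus
        for child in (ca, cb):
            assert all(child[i] in (a[i], b[i]) for i in range(3))
    assert seen == expected


def test_crossover_rejects_short_chromosomes():
    rng = np.random.default_rng(5)
    with pytest.raises(ValueError):
        two_point_crossover(np.array([1.0]), np.array([2.0]), 1.0, rng)


def test_mutation_rates():
    rng = np.random.default_rng(6)
    x = np.array([50.0, 150.0, 50.0])
    np.testing.assert_array_equal(uniform_mutation(x, 0.0, BOUNDS, rng), x)
    mutated = uniform_mutation(x, 1.0, BOUNDS, rng)
    assert np.all(mutated != x)
    for g, (lo, hi) in enumerate(BOUNDS):
        assert lo <= mutated[g] <= hi


def test_mutation_fraction_matches_binomial():
    rng = np.random.default_rng(7)
    n_genes, p_m = 100_000, 0.04
    x = np.full(n_genes, -1.0)  # outside U(0,1) support: any draw differs
    bounds = [(0.0, 1.0)] * n_genes
    out = uniform_mutation(x, p_m, bounds, rng)
    frac = np.mean(out != x)
    sd = np.sqrt(p_m * (1 - p_m) / n_genes)
    assert abs(frac - p_m) <= 3 * sd


def concave(levels):
    lv = np.atleast_2d(levels)
    return -(
        (lv[:, 0] - 100) ** 2 + (lv[:, 1] - 150) ** 2 + (lv[:, 2] - 50) ** 2
    )


def test_optimize_concave_objective_two_seeds():
    for seed in (1, 2):
        res = optimize(concave, GAConfig(generations=300, seed=seed))
        np.testing.assert_allclose(res.best_levels, [100, 150, 50], atol=2.0)


def test_optimize_monotone_corner():
    res = optimize(
        lambda lv: np.atleast_2d(lv).sum(axis=1),
        GAConfig(generations=300, seed=3),
    )
    target = np.array([200.0, 300.0, 100.0])
    ranges = np.array([200.0, 300.0, 100.0])
    assert np.all(np.abs(res.best_levels - target) <= 0.01 * ranges)


def test_optimize_history_and_bounds():
    evaluated = []

    def probe(lv):
        lv = np.atleast_2d(lv)
        evaluated.append(lv.copy())
        return concave(lv)

    res = optimize(probe, GAConfig(generations=50, population=30, seed=4))
    assert np.all(np.diff(res.history_best) >= 0)  # elitism contract
    assert res.evaluations == 30 * 51
    allpts = np.vstack(evaluated)
    b = np.asarray(BOUNDS)
    assert np.all(allpts >= b[:, 0]) and np.all(allpts <= b[:, 1])
    assert res.best_value == pytest.approx(concave(res.best_levels)[0])


def test_optimize_handles_non_finite_objective():
    def patchy(lv):
        v = concave(lv)
        lv = np.atleast_2d(lv)
        v[lv[:, 0] > 190] = np.nan
        return v

    with pytest.warns(UserWarning, match="non-finite"):
        res = optimize(patchy, GAConfig(generations=20, population=30, seed=5))
    assert np.isfinite(res.best_value)


def test_optimize_deterministic():
    r1 = optimize(concave, GAConfig(generations=30, population=20, seed=6))
    r2 = optimize(concave, GAConfig(generations=30, population=20, seed=6))
    np.testing.assert_array_equal(r1.best_levels, r2.best_levels)
    np.testing.assert_array_equal(r1.history_best, r2.history_best)
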