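"""GA feature selection: fitness closed forms, operator laws, search quality."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acg.features import FeatureTable
from acg.ga import (
    GAConfig,
    Individual,
    crossover,
    evolve,
    fitness,
    init_population,
    mutate,
    pc1_scores,
)


def make_table(values, target=None, standardized=True):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    tgt = pd.DataFrame({"sofa": target if target is not None else np.zeros(n)})
    meta = pd.DataFrame({"group": ["SG"] * n, "severity": 0.0, "cam_icu": False})
    return FeatureTable(values=values, feature_names=[f"x{i}" for i in range(p)],
                        row_index=[(f"P{i}", 1) for i in range(n)],
                        targets=tgt, meta=meta, standardized=standardized)


subset = st.sets(st.integers(0, 29), min_size=1, max_size=15)


class TestInitPopulation:
    def test_default_population_is_thousand_capped_subsets(self):
        cfg = GAConfig()
        pop = init_population(cfg, 1200, np.random.default_rng(0))
        assert len(pop) == 1000
        assert all(1 <= len(ind) <= 15 for ind in pop)

    def test_seeded_reproducibility(self):
        cfg = GAConfig(population_size=50)
        a = init_population(cfg, 100, np.random.default_rng(5))
        b = init_population(cfg, 100, np.random.default_rng(5))
        assert [i.features for i in a] == [i.features for i in b]

    def test_empty_feature_space_rejected(self):
        with pytest.raises(ValueError):
            init_population(GAConfig(), 0, np.random.default_rng(0))


class TestFitness:
    def test_single_column_equal_to_target_is_perfect(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        x = np.column_stack([y, rng.standard_normal(40)])
        table = make_table(x, target=y)
        assert fitness(Individual((0,)), table, y) == pytest.approx(1.0)

    def test_sign_flip_is_irrelevant(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(40)
        table = make_table((-y)[:, None], target=y)
        assert fitness(Individual((0,)), table, y) == pytest.approx(1.0)

    def test_zero_variance_subset_scores_zero(self):
        y = np.arange(10.0)
        table = make_table(np.zeros((10, 3)), target=y)
        assert fitness(Individual((0, 2)), table, y) == 0.0

    def test_null_table_mean_fitness_stays_low(self):
        # Monte-Carlo null: independent target, N=200, 100 single-feature draws
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 100))
        y = rng.standard_normal(200)
        table = make_table(x, target=y)
        vals = [fitness(Individual((int(rng.integers(100)),)), table, y)
                for _ in range(100)]
        assert np.mean(vals) < 0.2

    def test_affine_target_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((50, 8))
        y = rng.standard_normal(50)
        table = make_table(x, target=y)
        ind = Individual((1, 4, 6))
        assert fitness(ind, table, y) == pytest.approx(
            fitness(ind, table, 3.0 * y - 11.0), abs=1e-12)


class TestCrossover:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(a=subset, b=subset, seed=st.integers(0, 2**16))
    def test_child_between_intersection_and_union(self, a, b, seed):
        ia, ib = Individual(tuple(a)), Individual(tuple(b))
        child = crossover(ia, ib, np.random.default_rng(seed))
        feats = set(child.features)
        assert (a & b) <= feats <= (a | b)
        assert 1 <= len(feats) <= 15

    def test_identical_parents_reproduce_exactly(self):
        ind = Individual((2, 5, 9))
        child = crossover(ind, ind, np.random.default_rng(0))
        assert child.features == ind.features

    def test_disjoint_parents_child_size_is_binomial(self):
        # |child| ~ Binomial(8, 0.5) for disjoint size-4 parents
        a, b = Individual((0, 1, 2, 3)), Individual((4, 5, 6, 7))
        rng = np.random.default_rng(7)
        sizes = [len(crossover(a, b, rng)) for _ in range(10_000)]
        assert np.mean(sizes) == pytest.approx(4.0, abs=0.1)


class TestMutate:
    def test_no_rates_no_change(self):
        cfg = GAConfig(p_add=0.0, p_delete=0.0)
        ind = Individual((1, 3, 5))
        assert mutate(ind, cfg, 100, np.random.default_rng(0)).features == ind.features

    def test_size_always_capped(self):
        cfg = GAConfig(p_add=0.3, p_delete=0.3)
        rng = np.random.default_rng(1)
        for _ in range(500):
            ind = Individual(tuple(rng.choice(40, size=12, replace=False)))
            out = mutate(ind, cfg, 40, rng)
            assert 1 <= len(out) <= 15

    def test_surplus_deleted_uniformly(self):
        cfg = GAConfig(p_add=0.0, p_delete=0.0)
        ind = Individual(tuple(range(20)))
        rng = np.random.default_rng(2)
        keep_counts = np.zeros(20)
        n = 4000
        for _ in range(n):
            out = mutate(ind, cfg, 20, rng)
            assert len(out) == 15
            keep_counts[list(out.features)] += 1
        assert np.allclose(keep_counts / n, 0.75, atol=0.03)


class TestEvolve:
    def _structured_table(self, seed, n=60, p=12):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, p))
        y = x[:, 2] + 0.8 * x[:, 7] + 0.6 * rng.standard_normal(n)
        return make_table(x, target=y), y

    def test_history_non_decreasing_under_elitism(self):
        table, y = self._structured_table(0)
        res = evolve(table, y, GAConfig(population_size=60, generations=15, seed=1))
        assert all(a <= b + 1e-12 for a, b in zip(res.fitness_history,
                                                  res.fitness_history[1:]))
        assert res.generations_run == 15

    def test_deterministic_given_seed(self):
        table, y = self._structured_table(1)
        cfg = GAConfig(population_size=40, generations=10, seed=9)
        r1 = evolve(table, y, cfg)
        r2 = evolve(table, y, cfg)
        assert r1.best.features == r2.best.features
        assert r1.fitness_history == r2.fitness_history

    def test_matches_exhaustive_search_on_small_problem(self):
        # brute-force oracle over all 12 singletons + 78 pairs
        for seed in (3, 4, 5):
            table, y = self._structured_table(seed)
            cfg = GAConfig(population_size=100, generations=30, max_features=2,
                           seed=seed)
            res = evolve(table, y, cfg)
            best = max(
                fitness(Individual(c), table, y)
                for r in (1, 2) for c in itertools.combinations(range(12), r)
            )
            assert res.best.fitness >= 0.99 * best

    def test_early_stop_truncates_run(self):
        table, y = self._structured_table(2)
        cfg = GAConfig(population_size=60, generations=200, seed=0,
                       early_stop=True, early_stop_patience=5)
        res = evolve(table, y, cfg)
        assert res.generations_run < 200


class TestPC1Scores:
    def test_single_feature_scores_match_column_up_to_sign(self):
        rng = np.random.default_rng(0)
        col = rng.standard_normal(30)
        z = (col - col.mean()) / col.std(ddof=1)
        table = make_table(z[:, None])
        s = pc1_scores(Individual((0,)), table)
        assert np.allclose(np.abs(s), np.abs(z), atol=1e-9)
        assert abs(s.mean()) < 1e-9

    def test_duplicated_column_gains_sqrt_two(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(25)
        z = (col - col.mean()) / col.std(ddof=1)
        table = make_table(np.column_stack([z, z]))
        s = pc1_scores(Individual((0, 1)), table)
        assert np.allclose(np.abs(s), np.sqrt(2.0) * np.abs(z), atol=1e-9)
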