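"""Genetic-algorithm feature selection with subset-PCA correlation fitness.

An individual is a subset of at most 15 feature columns.  Its fitness is
the absolute Pearson correlation between the first principal component of
the selected (standardised) submatrix and a clinical target — an
unsupervised bottleneck that limits how freely feature combinations can
chase the target.  Evolution follows the study recipe: 1,000 random
subsets, top-2 % elite recombination (shared features kept, one-sided
features inherited with 50 % probability), random fill of the remainder,
and obligatory mutation of children, for 200 generations.

Mutation rates, elite pairing, and elite survival are not pinned down by
the recipe; the defaults here add on average about two features per child
per generation at P ≈ 1,200, pair elites uniformly with replacement, and
carry the elite forward unmutated (``elitism_copy``) so the best fitness
trace is non-decreasing.  Setting ``elitism_copy=False`` restores fully
obligatory mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable, standardize

__all__ = [
    "Individual", "GAConfig", "GAResult",
    "init_population", "fitness", "crossover", "mutate", "evolve", "pc1_scores",
]


@dataclass(frozen=True)
class Individual:
    """A feature subset (sorted index tuple) with its cached fitness."""

    features: tuple[int, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        feats = tuple(sorted(set(int(i) for i in self.features)))
        object.__setattr__(self, "features", feats)
        if len(feats) < 1:
            raise ValueError("an individual needs at least one feature")

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 1000
    max_features: int = 15
    elite_fraction: float = 0.02
    generations: int = 200
    p_inherit_single_parent: float = 0.5
    p_add: float = 0.002
    p_delete: float = 0.05
    elitism_copy: bool = True
    child_fraction: float = 0.5   # share of the next generation bred from elites
    early_stop: bool = False
    early_stop_patience: int = 30
    early_stop_min_gain: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must lie in (0, 1)")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.p_inherit_single_parent, self.p_add, self.p_delete):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")


@dataclass
class GAResult:
    best: Individual
    fitness_history: list[float]
    generations_run: int
    seed: int
    feature_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.best.features),
            "selected_names": self.feature_names,
            "fitness": self.best.fitness,
            "fitness_history": self.fitness_history,
            "generations_run": self.generations_run,
            "seed": self.seed,
        }


def _random_individual(n_features: int, max_features: int, rng: np.random.Generator) -> Individual:
    size = int(rng.integers(1, max_features + 1))
    feats = rng.choice(n_features, size=min(size, n_features), replace=False)
    return Individual(tuple(feats))


def init_population(config: GAConfig, n_features: int, rng: np.random.Generator) -> list[Individual]:
    """population_size uniform subsets of size Uniform{1..max_features}."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return [_random_individual(n_features, config.max_features, rng)
            for _ in range(config.population_size)]


def _target_vector(table: FeatureTable, target) -> np.ndarray:
    if isinstance(target, str):
        y = table.targets[target].to_numpy(dtype=float)
    else:
        y = np.asarray(target, dtype=float)
    if y.shape[0] != table.n_rows:
        raise ValueError("target not aligned with table rows")
    if y.std() == 0:
        raise ValueError("target has zero variance")
    return y


def _pc1(x: np.ndarray) -> np.ndarray:
    """PC1 scores of a column-centred submatrix (zero-mean by construction)."""
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    return u[:, 0] * s[0]


def fitness(ind: Individual, table: FeatureTable, target) -> float:
    """|Pearson r| between the subset's PC1 scores and the clinical target.

    The sign indeterminacy of PC1 is irrelevant under the absolute value.
    A zero-variance submatrix is an uninformative subset: fitness 0.
    """
    y = _target_vector(table, target)
    x = table.values[:, list(ind.features)]
    if x.ndim == 1:
        x = x[:, None]
    if not np.any(x.std(axis=0) > 0):
        return 0.0
    scores = _pc1(x)
    ssd = scores.std()
    if ssd == 0:
        return 0.0
    r = float(np.corrcoef(scores, y)[0, 1])
    return min(abs(r), 1.0)


def pc1_scores(ind: Individual, table: FeatureTable) -> np.ndarray:
    """Per-row PC1 scores of the selected submatrix (zero mean)."""
    x = table.values[:, list(ind.features)]
    return _pc1(x)


def crossover(a: Individual, b: Individual, rng: np.random.Generator,
              p_inherit: float = 0.5, max_features: int = 15) -> Individual:
    """Shared features kept; one-sided features inherited with probability p.

    The child always satisfies a∩b ⊆ child ⊆ a∪b: an empty draw is repaired
    with one uniformly drawn parent feature, and a child above the size cap
    has uniform surplus features deleted from its one-sided inheritance only
    (the shared core is never larger than the cap, so both laws hold).
    """
    sa, sb = set(a.features), set(b.features)
    core = sa & sb
    child = set(core)
    sym = sorted(sa ^ sb)
    if sym:
        keep = rng.random(len(sym)) < p_inherit
        child |= {f for f, k in zip(sym, keep) if k}
    if not child:
        pool = sorted(sa | sb)
        child = {pool[int(rng.integers(len(pool)))]}
    if len(child) > max_features:
        extras = np.array(sorted(child - core))
        n_keep = max_features - len(core)
        child = core | set(int(f) for f in
                           rng.choice(extras, size=n_keep, replace=False))
    return Individual(tuple(child))


def mutate(ind: Individual, config: GAConfig, n_features: int,
           rng: np.random.Generator) -> Individual:
    """Random add/delete, then enforce 1 <= size <= max_features.

    Each absent feature enters with probability p_add, each present feature
    leaves with probability p_delete; surplus beyond the cap is deleted
    uniformly, and an emptied individual receives one uniform feature.
    """
    present = set(ind.features)
    kept = {f for f in present if rng.random() >= config.p_delete}
    if config.p_add > 0:
        absent = np.setdiff1d(np.arange(n_features), np.array(sorted(present), dtype=int))
        added = absent[rng.random(absent.size) < config.p_add]
        kept |= set(int(f) for f in added)
    if not kept:
        kept = {int(rng.integers(n_features))}
    if len(kept) > config.max_features:
        feats = np.array(sorted(kept))
        kept = set(rng.choice(feats, size=config.max_features, replace=False))
    return Individual(tuple(kept))


def evolve(table: FeatureTable, target, config: GAConfig,
           rng: np.random.Generator | None = None) -> GAResult:
    """Run the generational loop and return the best-ever individual.

    Per generation: evaluate fitness, keep the top ``elite_fraction``,
    breed children from uniformly drawn elite pairs (with replacement),
    fill the rest of the population with fresh random subsets, and mutate
    every child.  Fitness evaluations are memoised on the subset.
    """
    if not table.standardized:
        table = standardize(table)
    y = _target_vector(table, target)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_features = table.n_features
    cache: dict[tuple[int, ...], float] = {}

    def fit(ind: Individual) -> Individual:
        if ind.fitness is not None:
            return ind
        val = cache.get(ind.features)
        if val is None:
            val = fitness(ind, table, y)
            cache[ind.features] = val
        return Individual(ind.features, val)

    pop = [fit(ind) for ind in init_population(config, n_features, rng)]
    best = max(pop, key=lambda i: i.fitness)
    history: list[float] = []
    n_elite = max(1, int(round(config.elite_fraction * config.population_size)))
    n_children = max(1, int(round(config.child_fraction * config.population_size)))
    generations_run = 0

    for _ in range(config.generations):
        generations_run += 1
        pop.sort(key=lambda i: (-i.fitness, i.features))
        elite = pop[:n_elite]
        nxt: list[Individual] = []
        if config.elitism_copy:
            nxt.extend(elite)
        for _ in range(n_children):
            pa = elite[int(rng.integers(n_elite))]
            pb = elite[int(rng.integers(n_elite))]
            child = crossover(pa, pb, rng, config.p_inherit_single_parent,
                              config.max_features)
            nxt.append(mutate(child, config, n_features, rng))
        while len(nxt) < config.population_size:
            nxt.append(_random_individual(n_features, config.max_features, rng))
        pop = [fit(ind) for ind in nxt[: config.population_size]]
        gen_best = max(pop, key=lambda i: i.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
        history.append(best.fitness if config.elitism_copy else gen_best.fitness)
        if (config.early_stop and len(history) > config.early_stop_patience
                and history[-1] - history[-1 - config.early_stop_patience]
                <= config.early_stop_min_gain):
            break

    names = [table.feature_names[i] for i in best.features] if table.feature_names else []
    return GAResult(best=best, fitness_history=history,
                    generations_run=generations_run, seed=config.seed,
                    feature_names=names)
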