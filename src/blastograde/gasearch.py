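"""Genetic-algorithm search over network architectures.

Each individual is a 9-gene :class:`~blastograde.neuralnet.Genome`.  Per
generation the population is sorted by classification accuracy (fitness);
the top 10% pass unchanged (elitism), 60% are offspring of
fitness-proportional (roulette) parents via uniform per-gene crossover with
5% per-gene mutation, and the remaining 30% are fresh random genomes.
Fractional counts are reconciled by the largest-remainder rule so every
generation has exactly the configured population size.

Fitness is the accuracy of the trained network on the configured partition.
The original protocol scores on the *test* partition; that leaks the test
set into architecture selection, so ``fitness_partition="validation"`` is
available (and recommended) for honest reporting.

Fitness is cached by genome, so re-evaluating an elite individual is free
and the best-of-generation fitness is exactly non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .neuralnet import (Genome, DataSplit, TRANSFER_FUNCTIONS, TRAINING_FUNCTIONS,
                        NEURON_RANGE, ANNClassifier, TrainedModel, split as make_split)

_GENE_NAMES = ("n1", "n2", "n3", "tf1", "tf2", "tf3", "tf_out", "train_fn", "n_hidden")


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 1000
    elite_fraction: float = 0.10
    offspring_fraction: float = 0.60
    random_fraction: float = 0.30
    mutation_rate: float = 0.05
    fitness_partition: str = "test"     # original protocol; or "validation"
    seed: int = 0
    fitness_max_epochs: int = 1000
    retrain_per_evaluation: bool = False

    def __post_init__(self):
        if self.population_size < 10:
            raise ConfigurationError("population_size must be >= 10")
        total = self.elite_fraction + self.offspring_fraction + self.random_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("elite/offspring/random fractions must sum to 1")
        if self.fitness_partition not in ("test", "validation"):
            raise ConfigurationError("fitness_partition must be 'test' or 'validation'")

    def counts(self) -> tuple[int, int, int]:
        """(elite, offspring, random) counts by the largest-remainder rule."""
        fracs = np.array([self.elite_fraction, self.offspring_fraction,
                          self.random_fraction])
        raw = fracs * self.population_size
        base = np.floor(raw).astype(int)
        short = self.population_size - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
        return int(base[0]), int(base[1]), int(base[2])


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_genome: Genome
    n_elite: int
    n_offspring: int
    n_random: int


@dataclass
class GARun:
    """Results of an architecture search."""

    config: GAConfig
    history: list[GenerationRecord] = field(default_factory=list)
    top_genomes: list[Genome] = field(default_factory=list)
    top_fitness: list[float] = field(default_factory=list)
    top_models: list[TrainedModel] = field(default_factory=list)

    @property
    def best_fitness_trace(self) -> list[float]:
        return [rec.best_fitness for rec in self.history]

    def summary(self) -> str:
        lines = ["Genetic architecture search",
                 "=" * 47,
                 f"population {self.config.population_size}, "
                 f"{self.config.generations} generations, "
                 f"fitness on {self.config.fitness_partition} partition",
                 f"best fitness: {self.history[-1].best_fitness:.4f}"
                 if self.history else "no generations run"]
        for rank, (g, f) in enumerate(zip(self.top_genomes, self.top_fitness), 1):
            lines.append(f"  #{rank}: acc={f:.4f} layers={g.hidden_sizes} "
                         f"tf={g.hidden_transfers}/{g.tf_out} train={g.train_fn}")
        return "\n".join(lines)


def random_genome(rng: np.random.Generator) -> Genome:
    """Draw each of the 9 genes uniformly over its domain."""
    return Genome(
        n1=int(rng.integers(NEURON_RANGE[0], NEURON_RANGE[1] + 1)),
        n2=int(rng.integers(NEURON_RANGE[0], NEURON_RANGE[1] + 1)),
        n3=int(rng.integers(NEURON_RANGE[0], NEURON_RANGE[1] + 1)),
        tf1=str(rng.choice(TRANSFER_FUNCTIONS)),
        tf2=str(rng.choice(TRANSFER_FUNCTIONS)),
        tf3=str(rng.choice(TRANSFER_FUNCTIONS)),
        tf_out=str(rng.choice(TRANSFER_FUNCTIONS)),
        train_fn=str(rng.choice(TRAINING_FUNCTIONS)),
        n_hidden=int(rng.integers(1, 4)),
    )


def fitness(genome: Genome, features, grades, data_split: DataSplit, seed: int = 0,
            partition: str = "test", max_epochs: int = 1000
            ) -> tuple[float, TrainedModel | None]:
    """Train the genome's network and return its partition accuracy.

    Training divergence scores 0 so pathological genomes die out quietly.
    """
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    names = tuple(features.columns) if isinstance(features, pd.DataFrame) else None
    y = np.asarray(grades, dtype=int)
    try:
        model = ANNClassifier(x, y, genome, variable_names=names).fit(
            data_split, seed=seed, max_epochs=max_epochs)
    except Exception:
        return 0.0, None
    idx = np.asarray(data_split.test if partition == "test"
                     else data_split.validation, dtype=int)
    return model.accuracy(x[idx], y[idx]), model


def _crossover_mutate(rng: np.random.Generator, a: Genome, b: Genome,
                      mutation_rate: float) -> Genome:
    child = {}
    fresh = random_genome(rng)  # mutation resamples from the gene's domain
    for gene in _GENE_NAMES:
        child[gene] = getattr(a if rng.random() < 0.5 else b, gene)
        if rng.random() < mutation_rate:
            child[gene] = getattr(fresh, gene)
    return Genome(**child)


def _roulette(rng: np.random.Generator, fits: np.ndarray) -> int:
    total = fits.sum()
    if total <= 0:
        return int(rng.integers(len(fits)))
    return int(rng.choice(len(fits), p=fits / total))


def evolve(config: GAConfig, features, grades, data_split: DataSplit | None = None,
           fitness_fn=None, top_k: int = 3) -> GARun:
    """Run the generational cycle and return records plus the top-k models.

    ``fitness_fn(genome, seed) -> float`` may replace the default
    train-and-score fitness (used by tests and for custom objectives).
    """
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    y = np.asarray(grades, dtype=int)
    if data_split is None and fitness_fn is None:
        data_split = make_split(len(y), config.seed)

    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, tuple[float, TrainedModel | None]] = {}
    eval_counter = [0]

    def evaluate(genome: Genome) -> float:
        key = tuple(getattr(genome, g) for g in _GENE_NAMES)
        if key in cache and not config.retrain_per_evaluation:
            return cache[key][0]
        fseed = (config.seed * 1_000_003 + eval_counter[0] * 9973) % (2 ** 31)
        eval_counter[0] += 1
        if fitness_fn is not None:
            fit, model = float(fitness_fn(genome, fseed)), None
        else:
            fit, model = fitness(genome, features, y, data_split, seed=fseed,
                                 partition=config.fitness_partition,
                                 max_epochs=config.fitness_max_epochs)
        cache[key] = (fit, model)
        return fit

    n_elite, n_offspring, n_random = config.counts()
    population = [random_genome(rng) for _ in range(config.population_size)]
    run = GARun(config=config)

    for gen in range(config.generations):
        fits = np.array([evaluate(g) for g in population])
        order = np.argsort(-fits, kind="stable")  # ties -> lower index first
        population = [population[i] for i in order]
        fits = fits[order]
        run.history.append(GenerationRecord(
            generation=gen, best_fitness=float(fits[0]),
            mean_fitness=float(fits.mean()), best_genome=population[0],
            n_elite=n_elite, n_offspring=n_offspring, n_random=n_random))
        if gen == config.generations - 1:
            break
        elite = population[:n_elite]
        offspring = []
        for _ in range(n_offspring):
            pa = population[_roulette(rng, fits)]
            pb = population[_roulette(rng, fits)]
            offspring.append(_crossover_mutate(rng, pa, pb, config.mutation_rate))
        randoms = [random_genome(rng) for _ in range(n_random)]
        population = elite + offspring + randoms
        assert len(population) == config.population_size

    # rank all evaluated genomes; keep the top-k with their trained models
    ranked = sorted(cache.items(), key=lambda kv: -kv[1][0])
    for key, (fit, model) in ranked[:top_k]:
        genome = Genome(**dict(zip(_GENE_NAMES, key)))
        run.top_genomes.append(genome)
        run.top_fitness.append(fit)
        if model is None and fitness_fn is None:
            _, model = fitness(genome, features, y, data_split, seed=config.seed,
                               partition=config.fitness_partition,
                               max_epochs=config.fitness_max_epochs)
        if model is not None:
            run.top_models.append(model)
    return run
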