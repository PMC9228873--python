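"""Genetic-algorithm hyperparameter search over the autoencoder space.

A genome is a fixed-length integer vector indexing into the hyperparameter
vocabulary: hidden-layer count (2 or 3), width pattern (constant, decreasing
or increasing by powers of two), first-layer width, autoencoder activation,
discriminator activation, learning rate and dropout rate.  Fitness (to be
minimised) is supplied by the caller — in the pipeline it is the mean
cluster KL of a cross-validated training run, typically at a reduced epoch
budget.  The search runs tournament selection, uniform crossover, per-gene
mutation and single elitism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from motiondda.aae import (
    AAEConfig,
    AE_ACTIVATIONS,
    DISC_ACTIVATIONS,
    DROPOUT_CHOICES,
    HIDDEN_LAYER_CHOICES,
    LEARNING_RATE_CHOICES,
    WIDTH_CHOICES,
)

logger = logging.getLogger(__name__)

PATTERNS = ("constant", "decreasing", "increasing")


@dataclass
class SearchSpace:
    """Gene vocabularies; defaults cover the full hyperparameter table."""

    layer_counts: Sequence[int] = HIDDEN_LAYER_CHOICES
    patterns: Sequence[str] = PATTERNS
    widths: Sequence[int] = WIDTH_CHOICES
    ae_activations: Sequence[str] = AE_ACTIVATIONS
    disc_activations: Sequence[str] = DISC_ACTIVATIONS
    learning_rates: Sequence[float] = LEARNING_RATE_CHOICES
    dropouts: Sequence[float] = DROPOUT_CHOICES

    def gene_sizes(self) -> list[int]:
        return [
            len(self.layer_counts), len(self.patterns), len(self.widths),
            len(self.ae_activations), len(self.disc_activations),
            len(self.learning_rates), len(self.dropouts),
        ]


def decode_genome(space: SearchSpace, genome: Sequence[int], **config_overrides) -> AAEConfig:
    """Decode an integer genome into a valid configuration.

    The width pattern halves (decreasing) or doubles (increasing) the base
    width per layer; base-width indices that would leave the vocabulary are
    clamped to the nearest valid index, so every genome decodes.
    """
    g = list(genome)
    n_layers = space.layer_counts[g[0]]
    pattern = space.patterns[g[1]]
    w_idx = g[2]
    if pattern == "decreasing":
        w_idx = max(w_idx, n_layers - 1)
    elif pattern == "increasing":
        w_idx = min(w_idx, len(space.widths) - n_layers)
    base = space.widths[w_idx]
    if pattern == "constant":
        widths = tuple([base] * n_layers)
    elif pattern == "decreasing":
        widths = tuple(space.widths[w_idx - i] for i in range(n_layers))
    else:
        widths = tuple(space.widths[w_idx + i] for i in range(n_layers))
    return AAEConfig(
        hidden_widths=widths,
        ae_activation=space.ae_activations[g[3]],
        disc_activation=space.disc_activations[g[4]],
        learning_rate=space.learning_rates[g[5]],
        dropout=space.dropouts[g[6]],
        **config_overrides,
    )


@dataclass
class GAConfig:
    """Search budget and operators: 50 individuals, 10 generations,
    tournament selection of 10 parents, uniform crossover, 5% per-gene
    mutation, single elitism."""

    population_size: int = 50
    generations: int = 10
    n_parents: int = 10
    tournament_size: int = 3
    mutation_rate: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.generations < 1 or self.n_parents < 2:
            raise ValueError("population_size >= 2, generations >= 1, n_parents >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


def evolve(
    search_space: SearchSpace,
    fitness_fn: Callable[[tuple[int, ...]], float],
    ga_config: GAConfig | None = None,
) -> tuple[tuple[int, ...], float, pd.DataFrame]:
    """Minimise ``fitness_fn`` over genomes of ``search_space``.

    A genome whose fitness evaluation raises is assigned infinite fitness and
    logged.  Returns the best genome, its fitness, and a per-generation
    history of best/mean fitness (mean over finite evaluations).
    """
    cfg = ga_config or GAConfig()
    sizes = search_space.gene_sizes()
    rng = np.random.default_rng(cfg.rng_seed)

    def random_genome() -> tuple[int, ...]:
        return tuple(int(rng.integers(0, s)) for s in sizes)

    def evaluate(genome: tuple[int, ...]) -> float:
        try:
            return float(fitness_fn(genome))
        except Exception:
            logger.warning("fitness evaluation failed for genome %s", genome, exc_info=True)
            return np.inf

    cache: dict[tuple[int, ...], float] = {}

    def fitness(genome: tuple[int, ...]) -> float:
        if genome not in cache:
            cache[genome] = evaluate(genome)
        return cache[genome]

    population = [random_genome() for _ in range(cfg.population_size)]
    history = []
    best_genome, best_fit = None, np.inf
    for gen in range(cfg.generations):
        fits = np.array([fitness(g) for g in population])
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = float(fits[gen_best])
            best_genome = population[gen_best]
        finite = fits[np.isfinite(fits)]
        history.append({
            "generation": gen,
            "best_fitness": best_fit,
            "mean_fitness": float(finite.mean()) if len(finite) else np.inf,
            "best_genome": list(best_genome),
        })
        if gen == cfg.generations - 1:
            break
        # tournament selection of the parent pool
        parents = []
        for _ in range(cfg.n_parents):
            contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
            parents.append(population[int(contenders[np.argmin(fits[contenders])])])
        # next generation: elite + uniform-crossover offspring with mutation
        next_pop = [best_genome]
        while len(next_pop) < cfg.population_size:
            pa, pb = rng.integers(0, cfg.n_parents, size=2)
            child = [
                (parents[pa][i] if rng.random() < 0.5 else parents[pb][i])
                for i in range(len(sizes))
            ]
            for i in range(len(sizes)):
                if rng.random() < cfg.mutation_rate:
                    child[i] = int(rng.integers(0, sizes[i]))
            next_pop.append(tuple(child))
        population = next_pop
    return best_genome, best_fit, pd.DataFrame(history)
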