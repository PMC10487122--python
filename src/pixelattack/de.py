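"""Differential evolution over pixel-edit genomes.

The optimizer follows the classic DE/rand/1 scheme without crossover:
an initial population of random genes, mutation
``offspring_i = gene[r1] + F * (gene[r2] - gene[r3])`` with three mutually
distinct donors per slot, and pairwise parent/offspring survival where the
child replaces its parent only on strict fitness improvement.  The loop stops
early once enough population members cross the attack's decision boundary
(``max(1, ceil(early_stop_fraction * population_size))`` of them), or after
``max_iterations`` generations.

Genomes are real vectors; candidates are quantized onto the image grid at
every evaluation, so out-of-range mutants are legal and simply clip.  All
model queries are batched per generation and parent fitnesses are cached, so
each generation costs ``population_size`` adapter evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import AttackConfig, PerturbationGene, quantize_vector, validate_image
from .fitness import FitnessSpec

__all__ = ["Population", "EvolveOutcome", "init_population", "mutate", "select", "evolve"]


@dataclass
class Population:
    """A fixed-size set of genomes with cached fitnesses."""

    genes: np.ndarray  # (population_size, gene_length), raw reals
    fitnesses: np.ndarray  # (population_size,)
    generation: int = 0

    def __post_init__(self) -> None:
        if self.genes.ndim != 2:
            raise ValueError("genes must be a 2-D array (population x gene length)")
        if self.fitnesses.shape != (self.genes.shape[0],):
            raise ValueError("fitness cache length must equal the gene count")

    @property
    def size(self) -> int:
        return self.genes.shape[0]

    def best_index(self, direction: str) -> int:
        if direction == "maximize":
            return int(np.argmax(self.fitnesses))
        return int(np.argmin(self.fitnesses))


@dataclass
class EvolveOutcome:
    """Everything the attack layer needs from one DE run."""

    population: Population
    best_gene: PerturbationGene
    best_fitness: float
    generations: int
    stop_reason: str  # "early_success" | "max_iterations"
    best_fitness_trace: list[float]
    confidences: np.ndarray  # (population_size, n_classes), final population
    success_flags: np.ndarray  # (population_size,), bool


def _gene_bounds(
    pixels: int, height: int, width: int, channels: int
) -> tuple[np.ndarray, np.ndarray]:
    stride = 2 + channels
    low = np.zeros(pixels * stride)
    high = np.empty(pixels * stride)
    per_edit = np.array([width - 1, height - 1] + [255.0] * channels, dtype=float)
    high[:] = np.tile(per_edit, pixels)
    return low, high


def init_population(
    config: AttackConfig,
    height: int,
    width: int,
    channels: int,
    rng: np.random.Generator,
) -> Population:
    """Draw the initial population uniformly over the (real-relaxed) grid.

    Coordinates are uniform over ``[0, dim - 1]`` and intensities over
    ``[0, 255]``, one gene per population slot, each of length
    ``pixels * (2 + channels)``.  Fitnesses are initialised to NaN and filled
    by the caller's first evaluation.
    """
    low, high = _gene_bounds(config.pixels, height, width, channels)
    genes = rng.uniform(low, high, size=(config.population_size, low.size))
    return Population(genes=genes, fitnesses=np.full(config.population_size, np.nan))


def mutate(
    population: Population, mutant_factor: float, rng: np.random.Generator
) -> np.ndarray:
    """DE/rand/1 mutation: one offspring per slot from three distinct donors.

    Donors may include the slot's own index but are mutually distinct, so the
    difference term never degenerates by construction.  Offspring may leave
    the valid range; quantization handles that at evaluation time.
    """
    if not 0.0 <= mutant_factor <= 1.0:
        raise ValueError("mutant_factor must lie in [0, 1]")
    n = population.size
    if n < 4:
        raise ValueError("mutation needs a population of at least 4")
    offspring = np.empty_like(population.genes)
    for i in range(n):
        r1, r2, r3 = rng.choice(n, size=3, replace=False)
        offspring[i] = population.genes[r1] + mutant_factor * (
            population.genes[r2] - population.genes[r3]
        )
    return offspring


def select(
    parents: Population,
    offspring: np.ndarray,
    offspring_fitness: np.ndarray,
    direction: str,
    epsilon: float = 0.0,
) -> tuple[Population, np.ndarray]:
    """Pairwise survival: the child replaces its parent only if strictly better.

    Ties (and improvements within *epsilon*) preserve the parent.  Returns the
    next generation and the boolean mask of slots where the child survived.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    off_fit = np.asarray(offspring_fitness, dtype=float)
    if offspring.shape != parents.genes.shape or off_fit.shape != parents.fitnesses.shape:
        raise ValueError("offspring arrays must align with the parent population")
    if direction == "maximize":
        replaced = off_fit > parents.fitnesses + epsilon
    else:
        replaced = off_fit < parents.fitnesses - epsilon
    genes = np.where(replaced[:, None], offspring, parents.genes)
    fits = np.where(replaced, off_fit, parents.fitnesses)
    return Population(genes=genes, fitnesses=fits, generation=parents.generation + 1), replaced


def _apply_batch(image: np.ndarray, genes: np.ndarray, channels: int) -> np.ndarray:
    h, w, _ = image.shape
    batch = np.repeat(image[None, ...], genes.shape[0], axis=0)
    stride = 2 + channels
    for i, vec in enumerate(genes):
        q = quantize_vector(vec, h, w, channels).reshape(-1, stride)
        for edit in q:
            batch[i, int(edit[1]), int(edit[0]), :] = edit[2:].astype(np.uint8)
    return batch


def evolve(
    image: np.ndarray,
    model_adapter: Callable[[np.ndarray], np.ndarray],
    config: AttackConfig,
    fitness_spec: FitnessSpec,
    success_predicate: Callable[[np.ndarray], bool] | None = None,
    rng: np.random.Generator | None = None,
) -> EvolveOutcome:
    """Run the full DE loop against one image.

    *model_adapter* maps a batch of images ``(N, H, W, C)`` to per-class
    confidence vectors ``(N, K)`` and must be pure for determinism.
    *success_predicate*, if given, is evaluated on each candidate's confidence
    vector; the loop stops once the surviving population holds at least
    ``max(1, ceil(early_stop_fraction * population_size))`` successes.  The
    best-so-far fitness is monotone in the optimization direction because of
    pairwise elitism.
    """
    arr = validate_image(image)
    h, w, c = arr.shape
    if rng is None:
        rng = np.random.default_rng(config.seed)
    direction = fitness_spec.direction
    n_classes: int | None = None

    def evaluate(genes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nonlocal n_classes
        batch = _apply_batch(arr, genes, c)
        confs = np.asarray(model_adapter(batch), dtype=float)
        if confs.ndim != 2 or confs.shape[0] != genes.shape[0]:
            raise ValueError(
                f"adapter returned shape {confs.shape} for a batch of {genes.shape[0]}"
            )
        if n_classes is None:
            n_classes = confs.shape[1]
        elif confs.shape[1] != n_classes:
            raise ValueError("adapter changed its number of classes mid-run")
        fits = np.array([fitness_spec.score(cl) for cl in confs])
        if success_predicate is not None:
            flags = np.array([bool(success_predicate(cl)) for cl in confs])
        else:
            flags = np.zeros(genes.shape[0], dtype=bool)
        return fits, confs, flags

    population = init_population(config, h, w, c, rng)
    fits, confs, flags = evaluate(population.genes)
    population.fitnesses = fits
    best_idx = population.best_index(direction)
    trace = [float(population.fitnesses[best_idx])]

    threshold = max(1, math.ceil(config.early_stop_fraction * config.population_size))
    stop_reason = "max_iterations"
    generations = 0
    if success_predicate is not None and int(flags.sum()) >= threshold:
        stop_reason = "early_success"
    else:
        for _ in range(config.max_iterations):
            offspring = mutate(population, config.mutant_factor, rng)
            off_fits, off_confs, off_flags = evaluate(offspring)
            population, replaced = select(population, offspring, off_fits, direction)
            confs = np.where(replaced[:, None], off_confs, confs)
            flags = np.where(replaced, off_flags, flags)
            generations += 1
            best_idx = population.best_index(direction)
            trace.append(float(population.fitnesses[best_idx]))
            if success_predicate is not None and int(flags.sum()) >= threshold:
                stop_reason = "early_success"
                break

    best_idx = population.best_index(direction)
    return EvolveOutcome(
        population=population,
        best_gene=PerturbationGene(population.genes[best_idx].copy(), c),
        best_fitness=float(population.fitnesses[best_idx]),
        generations=generations,
        stop_reason=stop_reason,
        best_fitness_trace=trace,
        confidences=confs,
        success_flags=flags,
    )
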