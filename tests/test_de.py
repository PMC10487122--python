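"""Differential-evolution engine: initialization, mutation, selection, loop."""

import numpy as np
import pytest

from pixelattack import (
    AttackConfig,
    FitnessSpec,
    Population,
    evolve,
    init_population,
    make_toy_classifier,
    mutate,
    select,
)


def test_init_population_bounds_and_shape(rng):
    cfg = AttackConfig(population_size=100, seed=0)
    pop = init_population(cfg, 224, 224, 1, rng)
    assert pop.genes.shape == (100, 3)
    assert (pop.genes[:, 0] >= 0).all() and (pop.genes[:, 0] <= 223).all()
    assert (pop.genes[:, 1] >= 0).all() and (pop.genes[:, 1] <= 223).all()
    assert (pop.genes[:, 2] >= 0).all() and (pop.genes[:, 2] <= 255).all()


def test_init_population_is_seed_deterministic():
    cfg = AttackConfig(seed=7)
    a = init_population(cfg, 16, 16, 1, np.random.default_rng(7))
    b = init_population(cfg, 16, 16, 1, np.random.default_rng(7))
    assert np.array_equal(a.genes, b.genes)


def test_three_pixel_greyscale_gene_length(rng):
    cfg = AttackConfig(pixels=3, population_size=10)
    pop = init_population(cfg, 8, 8, 1, rng)
    assert pop.genes.shape == (10, 9)  # (X,Y,I) x 3


def test_population_rejects_misaligned_fitness_cache():
    with pytest.raises(ValueError):
        Population(genes=np.zeros((4, 3)), fitnesses=np.zeros(3))


class _FixedDonorRNG:
    """Stub generator returning preset donor triples."""

    def __init__(self, triples):
        self.triples = list(triples)
        self.calls = 0

    def choice(self, n, size, replace):
        out = np.array(self.triples[self.calls % len(self.triples)])
        self.calls += 1
        return out


def test_mutation_formula_by_hand():
    genes = np.array(
        [[1.0, 1.0, 10.0], [3.0, 3.0, 30.0], [1.0, 1.0, 10.0], [5.0, 5.0, 50.0]]
    )
    pop = Population(genes=genes, fitnesses=np.zeros(4))
    rng = _FixedDonorRNG([(0, 1, 2)] * 4)
    offspring = mutate(pop, 0.5, rng)
    # gene[0] + 0.5 * (gene[1] - gene[2]) = (2, 2, 20)
    assert np.allclose(offspring[0], [2.0, 2.0, 20.0])


def test_mutation_with_zero_factor_copies_a_parent(rng):
    genes = rng.uniform(0, 10, size=(6, 3))
    pop = Population(genes=genes, fitnesses=np.zeros(6))
    offspring = mutate(pop, 0.0, np.random.default_rng(3))
    for child in offspring:
        assert any(np.allclose(child, parent) for parent in genes)


def test_mutation_on_identical_population_is_identity(rng):
    genes = np.tile(np.array([2.0, 3.0, 40.0]), (5, 1))
    pop = Population(genes=genes, fitnesses=np.zeros(5))
    for factor in (0.0, 0.5, 1.0):
        offspring = mutate(pop, factor, np.random.default_rng(1))
        assert np.allclose(offspring, genes)


@pytest.mark.parametrize(
    "direction, parent_fit, child_fit, child_survives",
    [
        ("maximize", 0.4, 0.6, True),  # strict improvement
        ("maximize", 0.5, 0.5, False),  # tie preserves the parent
        ("minimize", 0.3, 0.7, False),  # worse child
        ("minimize", 0.7, 0.3, True),
    ],
)
def test_pairwise_selection(direction, parent_fit, child_fit, child_survives):
    parents = Population(
        genes=np.zeros((4, 3)), fitnesses=np.full(4, parent_fit)
    )
    offspring = np.ones((4, 3))
    new_pop, replaced = select(
        parents, offspring, np.full(4, child_fit), direction
    )
    assert replaced.all() == child_survives
    assert new_pop.size == 4
    assert new_pop.generation == 1
    expected = child_fit if child_survives else parent_fit
    assert np.allclose(new_pop.fitnesses, expected)


def test_select_requires_direction():
    parents = Population(genes=np.zeros((4, 3)), fitnesses=np.zeros(4))
    with pytest.raises(ValueError):
        select(parents, np.zeros((4, 3)), np.zeros(4), "sideways")


def _untargeted_predicate(original_class):
    def pred(cl):
        return int(np.argmax(cl)) != original_class

    return pred


def test_constant_model_never_succeeds(constant_model):
    img = np.zeros((4, 4, 1), dtype=np.uint8)
    cfg = AttackConfig(population_size=10, max_iterations=5, seed=0)
    spec = FitnessSpec("multiclass", "untargeted", 0)
    out = evolve(img, constant_model, cfg, spec, _untargeted_predicate(0))
    assert out.stop_reason == "max_iterations"
    assert out.generations == 5
    assert not out.success_flags.any()


def test_fragile_model_stops_early(fragile_model):
    # any random gene with intensity > 200 flips the class; with 100 genes
    # the initial population alone succeeds with probability ~1-(200/255)^100
    img = np.zeros((8, 8, 1), dtype=np.uint8)
    cfg = AttackConfig(seed=11)
    spec = FitnessSpec("multiclass", "untargeted", 0)
    out = evolve(img, fragile_model, cfg, spec, _untargeted_predicate(0))
    assert out.stop_reason == "early_success"
    assert out.generations <= 3


def test_zero_iteration_budget_returns_initial_best(constant_model):
    img = np.zeros((4, 4, 1), dtype=np.uint8)
    cfg = AttackConfig(population_size=8, max_iterations=0, seed=0)
    spec = FitnessSpec("multiclass", "untargeted", 0)
    out = evolve(img, constant_model, cfg, spec)
    assert out.generations == 0
    assert out.stop_reason == "max_iterations"
    assert len(out.best_fitness_trace) == 1


@pytest.mark.parametrize("seed", range(5))
def test_best_fitness_trace_is_monotone(seed):
    model = make_toy_classifier("linear_multiclass", 3)
    img = np.full((5, 5, 1), 128, dtype=np.uint8)
    cfg = AttackConfig(population_size=20, max_iterations=30, seed=seed)
    spec = FitnessSpec("multiclass", "untargeted", 2)
    out = evolve(img, model, cfg, spec)
    trace = out.best_fitness_trace
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))  # minimizing


def test_evolve_is_deterministic(fragile_model):
    img = np.zeros((6, 6, 1), dtype=np.uint8)
    cfg = AttackConfig(population_size=12, max_iterations=10, seed=42)
    spec = FitnessSpec("multiclass", "untargeted", 0)
    a = evolve(img, fragile_model, cfg, spec, _untargeted_predicate(0))
    b = evolve(img, fragile_model, cfg, spec, _untargeted_predicate(0))
    assert np.array_equal(a.population.genes, b.population.genes)
    assert a.best_fitness == b.best_fitness
    assert a.generations == b.generations
    assert a.best_fitness_trace == b.best_fitness_trace


def test_adapter_contract_violation_is_reported():
    def bad_adapter(batch):
        return np.zeros((batch.shape[0] + 1, 2))

    img = np.zeros((4, 4, 1), dtype=np.uint8)
    cfg = AttackConfig(population_size=5, max_iterations=1, seed=0)
    spec = FitnessSpec("multiclass", "untargeted", 0)
    with pytest.raises(ValueError, match="adapter"):
        evolve(img, bad_adapter, cfg, spec)
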