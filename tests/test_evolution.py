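import numpy as np
import pytest

import evoseg.evolution as evo
from evoseg.evolution import (GAConfig, crossover, init_population,
                              make_offspring, mutate_merge, mutate_split,
                              run_evolution, select_parents)
from evoseg.volume_io import LabelMap
from evoseg.watershed_seg import Individual, random_segmentation


class ConstantModel:
    """Scores every segmentation identically: no improvement possible."""

    def __init__(self, value=0.5):
        self.value = value

    def score_features(self, features):
        return self.value


class IncreasingModel:
    """Every new evaluation scores higher: the run never stalls."""

    def __init__(self):
        self.counter = 0

    def score_features(self, features):
        self.counter += 1
        return self.counter / 1e9


def _individual(flat, shape=(1, 1, 4)):
    return Individual(labels=LabelMap(labels=np.array(flat, dtype=np.int32).reshape(shape)))


def test_config_validation():
    with pytest.raises(ValueError):
        GAConfig(p_crossover=1.5)
    with pytest.raises(ValueError):
        GAConfig(patience=300, max_iterations=200)
    with pytest.raises(ValueError):
        GAConfig(replacement="tournament")
    cfg = GAConfig()
    assert (cfg.population_size, cfg.parents_per_generation,
            cfg.offspring_per_generation) == (30, 30, 15)
    assert (cfg.p_crossover, cfg.p_mutation) == (0.9, 0.1)
    assert (cfg.max_iterations, cfg.patience) == (200, 20)


def test_init_population_scored_and_reproducible(small_pair):
    cfg = GAConfig(population_size=6)
    model = ConstantModel(0.3)
    a = init_population(small_pair.map, cfg, model, np.random.default_rng(1))
    b = init_population(small_pair.map, cfg, model, np.random.default_rng(1))
    assert len(a) == 6
    for ia, ib in zip(a, b):
        assert ia.fitness == 0.3
        np.testing.assert_array_equal(ia.labels.labels, ib.labels.labels)


def test_selection_favours_fit_individuals():
    pop = [_individual([1, 1, 2, 2]) for _ in range(5)]
    for i, ind in enumerate(pop):
        ind.fitness = 1.0 if i == 0 else 0.0
    cfg = GAConfig()
    rng = np.random.default_rng(0)
    parents = select_parents(pop, cfg, rng)
    assert len(parents) == cfg.parents_per_generation == 30
    assert all(p is pop[0] for p in parents)  # all weight on the top individual


def test_selection_uniform_when_fitness_equal():
    pop = [_individual([1, 1, 2, 2]) for _ in range(4)]
    for ind in pop:
        ind.fitness = 0.7
    rng = np.random.default_rng(0)
    counts = np.zeros(4)
    for _ in range(200):
        for p in select_parents(pop, GAConfig(), rng):
            counts[pop.index(p)] += 1
    freq = counts / counts.sum()
    assert np.all(np.abs(freq - 0.25) < 0.05)


def test_crossover_identity_and_coverage():
    a = _individual([1, 1, 2, 2])
    child = crossover(a, a, np.random.default_rng(0))
    # same partition up to renaming
    assert child.labels.n_segments() == 2
    np.testing.assert_array_equal(child.labels.labels > 0, a.labels.labels > 0)


def test_crossover_offspring_are_parental_fragments():
    """Toy foreground of 4 voxels; every reachable offspring is a full
    cover whose segments are subsets of parental segments."""
    a = _individual([1, 1, 2, 2])
    b = _individual([1, 2, 2, 2])
    parental = [{0, 1}, {2, 3}, {0}, {1, 2, 3}]
    for seed in range(100):
        child = crossover(a, b, np.random.default_rng(seed))
        lab = child.labels.labels.ravel()
        assert (lab > 0).all()  # full cover
        assert child.labels.n_segments() <= 4
        for k in child.labels.label_ids():
            voxels = set(np.flatnonzero(lab == k))
            assert any(voxels <= p for p in parental)


def test_crossover_rejects_mismatched_foregrounds():
    with pytest.raises(ValueError):
        crossover(_individual([1, 1, 2, 0]), _individual([1, 2, 2, 2]),
                  np.random.default_rng(0))


def test_merge_reduces_by_one_and_preserves_voxels():
    ind = _individual([1, 1, 2, 3])
    out = mutate_merge(ind, np.random.default_rng(0))
    assert out.labels.n_segments() == 2
    np.testing.assert_array_equal(out.labels.labels > 0, ind.labels.labels > 0)
    # merged result must be a coarsening: each old segment maps into one new
    for k in ind.labels.label_ids():
        assert np.unique(out.labels.labels[ind.labels.labels == k]).size == 1


def test_merge_degenerate_cases():
    single = _individual([1, 1, 1, 1])
    out = mutate_merge(single, np.random.default_rng(0))
    np.testing.assert_array_equal(out.labels.labels, single.labels.labels)
    # two disconnected segments (gap of background): nothing adjacent
    apart = _individual([1, 0, 0, 2])
    out = mutate_merge(apart, np.random.default_rng(0))
    assert out.labels.n_segments() == 2


def test_split_preserves_target_voxels(small_pair):
    rng = np.random.default_rng(0)
    ind = random_segmentation(small_pair.map, rng)
    before = ind.labels.n_segments()
    out = mutate_split(ind, small_pair.map, rng)
    np.testing.assert_array_equal(out.labels.labels > 0, ind.labels.labels > 0)
    if out.labels.n_segments() > before:
        # refinement: every new segment nests inside one old segment
        for k in out.labels.label_ids():
            assert np.unique(ind.labels.labels[out.labels.labels == k]).size == 1


def test_split_single_voxel_segment_is_identity(small_pair):
    lab = np.zeros(small_pair.map.shape, dtype=np.int32)
    fg = small_pair.map.grid > small_pair.map.threshold
    zz, yy, xx = np.nonzero(fg)
    lab[zz[0], yy[0], xx[0]] = 1
    ind = Individual(labels=LabelMap(labels=lab))
    out = mutate_split(ind, small_pair.map, np.random.default_rng(0), max_retries=3)
    np.testing.assert_array_equal(out.labels.labels, ind.labels.labels)


def test_offspring_without_operators_copies_a_parent(small_pair):
    rng = np.random.default_rng(0)
    a = random_segmentation(small_pair.map, rng)
    b = random_segmentation(small_pair.map, rng)
    cfg = GAConfig(p_crossover=0.0, p_mutation=0.0)
    child = make_offspring((a, b), cfg, small_pair.map, np.random.default_rng(1))
    assert any(np.array_equal(child.labels.labels, p.labels.labels) for p in (a, b))


def test_fifteen_offspring_per_generation(small_pair, monkeypatch):
    calls = []
    original = evo.make_offspring

    def counting(*args, **kwargs):
        calls.append(1)
        return original(*args, **kwargs)

    monkeypatch.setattr(evo, "make_offspring", counting)
    cfg = GAConfig(max_iterations=2, patience=2, seed=0)
    run_evolution(small_pair.map, ConstantModel(), cfg)
    assert len(calls) == 2 * cfg.offspring_per_generation


def test_constant_fitness_stops_at_patience(small_pair):
    cfg = GAConfig(max_iterations=50, patience=5, seed=0)
    best, log = run_evolution(small_pair.map, ConstantModel(), cfg)
    assert log.stop_reason == "patience"
    assert len(log.records) == 5
    assert best.fitness == 0.5


def test_population_size_constant_and_coverage(small_pair):
    cfg = GAConfig(max_iterations=3, patience=3, seed=1)
    fg = small_pair.map.grid > small_pair.map.threshold
    for mode in ("generational", "elitist"):
        cfg2 = GAConfig(max_iterations=3, patience=3, seed=1, replacement=mode)
        best, log = run_evolution(small_pair.map, IncreasingModel(), cfg2)
        assert not (fg & (best.labels.labels == 0)).any()
        assert len(log.records) == 3


def test_elitist_best_trajectory_non_decreasing(small_pair):
    rng_model = IncreasingModel()
    cfg = GAConfig(max_iterations=6, patience=6, seed=2, replacement="elitist")
    _, log = run_evolution(small_pair.map, rng_model, cfg)
    bests = [r.best_fitness for r in log.records]
    assert all(b2 >= b1 for b1, b2 in zip(bests, bests[1:]))


def test_run_is_bit_reproducible(small_pair):
    cfg = GAConfig(max_iterations=4, patience=4, seed=7)
    model = ConstantModel()
    best1, log1 = run_evolution(small_pair.map, model, cfg)
    best2, log2 = run_evolution(small_pair.map, model, cfg)
    np.testing.assert_array_equal(best1.labels.labels, best2.labels.labels)
    assert [r.best_fitness for r in log1.records] == [r.best_fitness for r in log2.records]
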