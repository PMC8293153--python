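"""Evolutionary-Optimized Segmentation.

The optimizer maintains a population of candidate segmentations
(:class:`~evoseg.watershed_seg.Individual`) of one density map and
iterates selection -> crossover -> mutation -> replacement, scored by
the ideal-segmentation classifier:

* 30 individuals, initialised as random watershed segmentations;
* 30 parents per generation drawn with probability proportional to
  fitness and paired round-robin into 15 couples;
* each couple yields one offspring: with probability 0.9 a crossover
  (segments of both parents stamped in uniform random order onto the
  empty foreground until it is covered), otherwise a copy of one
  parent; with probability 0.1 the offspring is mutated by merging two
  adjacent segments or splitting one segment along a fresh random
  watershed;
* replacement is either generational (offspring plus fresh random
  segmentations replace everyone) or elitist (the best of the old
  population survive);
* the run stops after 200 generations or 20 consecutive generations
  without a new best fitness, and always returns the best individual
  ever seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import encode_features
from .metrics import matched_iou
from .volume_io import DensityMap, LabelMap, canonicalize_labels
from .watershed_seg import Individual, random_segmentation, random_watershed

__all__ = [
    "GAConfig",
    "RunLog",
    "GenerationRecord",
    "init_population",
    "select_parents",
    "crossover",
    "mutate_merge",
    "mutate_split",
    "make_offspring",
    "run_evolution",
]


@dataclass
class GAConfig:
    """Evolution parameters; the defaults are the protocol constants."""

    population_size: int = 30
    parents_per_generation: int = 30
    offspring_per_generation: int = 15
    p_crossover: float = 0.9
    p_mutation: float = 0.1
    max_iterations: int = 200
    patience: int = 20
    replacement: str = "generational"
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.population_size, self.parents_per_generation,
               self.offspring_per_generation, self.max_iterations) < 1:
            raise ValueError("counts must be positive")
        if self.patience > self.max_iterations:
            raise ValueError("patience must be <= max_iterations")
        if self.replacement not in ("generational", "elitist"):
            raise ValueError("replacement must be 'generational' or 'elitist'")


@dataclass
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    matched_iou: float | None = None


@dataclass
class RunLog:
    seed: int | None = None
    records: list[GenerationRecord] = field(default_factory=list)
    stop_reason: str = ""

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "stop_reason": self.stop_reason,
            "generations": [
                {"generation": r.generation, "best_score": r.best_fitness,
                 "mean_score": r.mean_fitness, "matched_iou": r.matched_iou}
                for r in self.records
            ],
        }


def _score_individual(model, ind: Individual) -> Individual:
    ind.fitness = float(model.score_features(encode_features(ind.labels)))
    return ind


def init_population(dmap: DensityMap, config: GAConfig, model,
                    rng: np.random.Generator) -> list[Individual]:
    """Random segmentation states, each with its fitness assigned."""
    return [_score_individual(model, random_segmentation(dmap, rng))
            for _ in range(config.population_size)]


def select_parents(population: list[Individual], config: GAConfig,
                   rng: np.random.Generator) -> list[Individual]:
    """Fitness-proportional sampling with replacement, round-robin paired.

    The returned list has ``parents_per_generation`` entries; consecutive
    pairs (0-1, 2-3, ...) are the crossover couples.  When every fitness
    is equal (or all zero) sampling falls back to uniform.
    """
    if not population:
        raise ValueError("empty population")
    fit = np.array([ind.fitness if ind.fitness is not None else 0.0
                    for ind in population], dtype=np.float64)
    total = fit.sum()
    if total <= 0 or np.allclose(fit, fit[0]):
        weights = np.full(len(population), 1.0 / len(population))
    else:
        weights = fit / total
    idx = rng.choice(len(population), size=config.parents_per_generation,
                     replace=True, p=weights)
    return [population[i] for i in idx]


def crossover(a: Individual, b: Individual, rng: np.random.Generator) -> Individual:
    """Combine two parents by uniform superposition of their segments.

    Segments from the pooled parental segment sets are drawn uniformly
    without repetition and stamped onto the offspring; a stamped segment
    claims only voxels that are still unlabeled, and the process stops
    as soon as the whole foreground is covered.  Every offspring segment
    is therefore a (possibly truncated) parental segment.
    """
    la, lb = a.labels.labels, b.labels.labels
    if not np.array_equal(la > 0, lb > 0):
        raise ValueError("parents segment different foregrounds")
    fg = la > 0
    n_fg = int(fg.sum())
    pool = [(la, k) for k in a.labels.label_ids()] + \
           [(lb, k) for k in b.labels.label_ids()]
    order = rng.permutation(len(pool))
    out = np.zeros_like(la)
    covered = 0
    next_label = 1
    for i in order:
        src, k = pool[i]
        mask = (src == k) & (out == 0)
        n = int(mask.sum())
        if n == 0:
            continue
        out[mask] = next_label
        next_label += 1
        covered += n
        if covered == n_fg:
            break
    return Individual(labels=canonicalize_labels(LabelMap(out)))


def _adjacent_pairs(lab: np.ndarray) -> set[tuple[int, int]]:
    """Face-adjacent label pairs (6-connectivity), as (lo, hi) tuples."""
    pairs: set[tuple[int, int]] = set()
    base = int(lab.max()) + 1
    for ax in range(3):
        s1 = [slice(None)] * 3
        s2 = [slice(None)] * 3
        s1[ax] = slice(0, -1)
        s2[ax] = slice(1, None)
        u, v = lab[tuple(s1)].ravel(), lab[tuple(s2)].ravel()
        keep = (u > 0) & (v > 0) & (u != v)
        if keep.any():
            lo = np.minimum(u[keep], v[keep]).astype(np.int64)
            hi = np.maximum(u[keep], v[keep]).astype(np.int64)
            for code in np.unique(lo * base + hi):
                pairs.add((int(code // base), int(code % base)))
    return pairs


def mutate_merge(ind: Individual, rng: np.random.Generator) -> Individual:
    """Merge one uniformly chosen segment with a uniformly chosen
    face-adjacent neighbour.  Identity when no adjacent pair exists."""
    lab = ind.labels.labels
    ids = ind.labels.label_ids()
    if ids.size < 2:
        return ind.copy()
    pairs = _adjacent_pairs(lab)
    if not pairs:
        return ind.copy()
    target = int(rng.choice(ids))
    neighbours = sorted({int(q) for p, q in pairs if p == target}
                        | {int(p) for p, q in pairs if q == target})
    if not neighbours:
        return ind.copy()
    other = int(rng.choice(neighbours))
    out = lab.copy()
    fresh = int(lab.max()) + 1
    out[(out == target) | (out == other)] = fresh
    return Individual(labels=canonicalize_labels(LabelMap(out)))


def mutate_split(ind: Individual, dmap: DensityMap, rng: np.random.Generator,
                 max_retries: int = 5) -> Individual:
    """Split one uniformly chosen segment along a fresh random watershed.

    The chosen segment Q is replaced by its intersections with the
    regions of a fresh random watershed; when Q falls inside a single
    region the draw is repeated, and after ``max_retries`` failures the
    mutation is the identity.
    """
    ids = ind.labels.label_ids()
    if ids.size == 0:
        return ind.copy()
    target = int(rng.choice(ids))
    seg_mask = ind.labels.labels == target
    for _ in range(max_retries):
        ws = random_watershed(dmap, rng).labels
        pieces = np.unique(ws[seg_mask])
        pieces = pieces[pieces > 0]
        if pieces.size < 2:
            continue
        out = ind.labels.labels.copy()
        base = int(out.max())
        for j, piece in enumerate(pieces):
            out[seg_mask & (ws == piece)] = base + 1 + j
        return Individual(labels=canonicalize_labels(LabelMap(out)))
    return ind.copy()


def make_offspring(parents: tuple[Individual, Individual], config: GAConfig,
                   dmap: DensityMap, rng: np.random.Generator,
                   events: list | None = None) -> Individual:
    """One offspring from a parent couple.

    Crossover fires with probability ``p_crossover`` (otherwise the
    offspring copies one parent uniformly); one mutation (merge or
    split, equal odds) then fires with probability ``p_mutation``.
    When ``events`` is given, a dict describing which operators fired is
    appended to it.
    """
    a, b = parents
    did_crossover = bool(rng.random() < config.p_crossover)
    if did_crossover:
        child = crossover(a, b, rng)
    else:
        child = (a if rng.random() < 0.5 else b).copy()
        child.fitness = None
    mutation = None
    if rng.random() < config.p_mutation:
        mutation = "merge" if rng.random() < 0.5 else "split"
        if mutation == "merge":
            child = mutate_merge(child, rng)
        else:
            child = mutate_split(child, dmap, rng)
    if events is not None:
        events.append({"crossover": did_crossover, "mutation": mutation})
    return child


def run_evolution(dmap: DensityMap, model, config: GAConfig | None = None,
                  truth: LabelMap | None = None,
                  rng: np.random.Generator | None = None):
    """Full optimization loop; returns ``(best_individual, RunLog)``.

    The best individual ever seen is archived and returned even under
    generational replacement, where it may leave the population.  When
    ``truth`` is given the matched IoU of the archived best is logged
    per generation.
    """
    if config is None:
        config = GAConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    log = RunLog(seed=config.seed)

    population = init_population(dmap, config, model, rng)
    best = max(population, key=lambda i: i.fitness).copy()
    best_fitness = best.fitness
    stall = 0

    for gen in range(1, config.max_iterations + 1):
        parents = select_parents(population, config, rng)
        offspring = []
        for i in range(config.offspring_per_generation):
            pair = (parents[2 * i], parents[2 * i + 1])
            child = make_offspring(pair, config, dmap, rng)
            offspring.append(_score_individual(model, child))

        if config.replacement == "generational":
            refill = [_score_individual(model, random_segmentation(dmap, rng))
                      for _ in range(config.population_size - len(offspring))]
            population = offspring + refill
        else:
            survivors = sorted(population, key=lambda i: -i.fitness)
            keep = config.population_size - len(offspring)
            population = survivors[:keep] + offspring

        gen_best = max(population, key=lambda i: i.fitness)
        if gen_best.fitness > best_fitness:
            best = gen_best.copy()
            best_fitness = best.fitness
            stall = 0
        else:
            stall += 1

        iou = None
        if truth is not None:
            iou, _ = matched_iou(best.labels, truth, mode="all")
        log.records.append(GenerationRecord(
            generation=gen,
            best_fitness=float(best_fitness),
            mean_fitness=float(np.mean([i.fitness for i in population])),
            matched_iou=iou,
        ))
        if stall >= config.patience:
            log.stop_reason = "patience"
            break
    else:
        log.stop_reason = "max_iterations"
    return best, log
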