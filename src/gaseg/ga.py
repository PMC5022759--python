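"""Genetic-algorithm selection of region-growing seed points.

Region growing is exquisitely sensitive to where the initial seeds
("grains") are planted.  When a reference segmentation is available —
e.g. the exact tissue maps shipped with simulated-MRI databases — seed
selection can be posed as an optimization problem: find one seed per
tissue class such that the segmentation grown from those seeds matches
the reference as closely as possible.

The chromosome is a :class:`SeedSet`: one (row, col) coordinate per
class.  Candidate seeds come from simple intensity thresholding (one
disjoint intensity window per class), so every gene stays inside
plausible tissue for its class.  Fitness is the summed squared pixelwise
difference between the grown segmentation's per-class binary maps and
the reference maps; on 0/1 maps this is simply the total number of
misclassified pixels per class, and it is zero exactly when the
segmentation reproduces the reference.  Selection is by tournament,
reproduction by per-class uniform crossover and candidate-constrained
mutation, and elitism guarantees the best cost never increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, DataError, SeedError
from .growing import GrowConfig, segment
from .phantom import ReferenceSegmentation, TISSUE_CLASSES

Coord = Tuple[int, int]
Window = Tuple[float, float]


@dataclass(frozen=True)
class SeedSet:
    """One seed coordinate per tissue class — the GA chromosome."""

    class_order: Tuple[int, ...]
    coords: Tuple[Coord, ...]

    def __post_init__(self):
        if len(self.class_order) != len(self.coords):
            raise ConfigurationError("one coordinate per class required")

    def coords_by_class(self) -> Dict[int, Coord]:
        return dict(zip(self.class_order, self.coords))

    def validate(self, shape: Tuple[int, int]) -> None:
        rows, cols = shape
        for (r, c) in self.coords:
            if not (0 <= r < rows and 0 <= c < cols):
                raise SeedError(f"seed {(r, c)} outside image of shape {shape}")
        if len(set(self.coords)) != len(self.coords):
            raise SeedError(f"seed coordinates must be distinct: {self.coords}")

    def to_dict(self) -> dict:
        return {str(c): [int(r), int(s)]
                for c, (r, s) in zip(self.class_order, self.coords)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SeedSet":
        classes = tuple(sorted(int(k) for k in d))
        return cls(class_order=classes,
                   coords=tuple(tuple(int(v) for v in d[str(c)]) for c in classes))


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the seed-search GA.

    Defaults: population 30, 50 generations, crossover 0.9, mutation 0.1,
    2 elites, tournament size 3, early stop after 10 stalled generations.
    """

    population_size: int = 30
    generations: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    elitism_count: int = 2
    tournament_size: int = 3
    stall_generations: int = 10
    rng_seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.elitism_count < 1 or self.elitism_count >= self.population_size:
            raise ConfigurationError(
                "elitism_count must satisfy 1 <= elitism_count < population_size"
            )
        if self.tournament_size < 2:
            raise ConfigurationError("tournament_size must be >= 2")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "generations": self.generations,
            "crossover_rate": self.crossover_rate,
            "mutation_rate": self.mutation_rate,
            "elitism_count": self.elitism_count,
            "tournament_size": self.tournament_size,
            "stall_generations": self.stall_generations,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GAConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class FitnessResult:
    """Cost of a segmentation against the reference, per class and total.

    On binary maps the squared pixelwise difference is the mismatch
    count, so ``total_cost`` is the total number of per-class label
    disagreements and is zero iff the segmentation matches the reference
    on every class map.
    """

    total_cost: float
    per_class_cost: Dict[int, float]


def candidate_seeds(image: np.ndarray,
                    class_intensity_windows: Mapping[int, Window]
                    ) -> Dict[int, np.ndarray]:
    """Threshold the image into per-class candidate-seed masks.

    Class ``c``'s mask selects pixels whose intensity lies in its closed
    window ``[lo, hi]``.  Windows must be pairwise disjoint, so the
    candidate masks are pixel-disjoint by construction and any seed set
    drawn from them has distinct coordinates.
    """
    arr = np.asarray(image, dtype=np.float64)
    items = sorted(class_intensity_windows.items(), key=lambda kv: kv[1][0])
    for (c1, w1), (c2, w2) in zip(items, items[1:]):
        if w1[1] >= w2[0]:
            raise ConfigurationError(
                f"intensity windows overlap: class {c1} {w1} vs class {c2} {w2}"
            )
    masks = {}
    for c, (lo, hi) in class_intensity_windows.items():
        if lo > hi:
            raise ConfigurationError(f"window for class {c} is empty: {(lo, hi)}")
        mask = (arr >= lo) & (arr <= hi)
        if not mask.any():
            raise ConfigurationError(
                f"no candidate pixels for class {c} in window {(lo, hi)}; "
                "widen the window"
            )
        masks[c] = mask
    return masks


def windows_from_means(class_means: Mapping[int, float],
                       classes: Sequence[int] = TISSUE_CLASSES
                       ) -> Dict[int, Window]:
    """Disjoint intensity windows at the midpoints between class means.

    Each tissue class gets the interval between the midpoints to its
    neighboring means (including the background mean below the dimmest
    tissue); the brightest class is open upward to +inf.
    """
    ordered = sorted(class_means.items(), key=lambda kv: kv[1])
    windows: Dict[int, Window] = {}
    eps = 1e-9
    for i, (c, m) in enumerate(ordered):
        if c not in classes:
            continue
        lo = -np.inf if i == 0 else (ordered[i - 1][1] + m) / 2.0 + eps
        hi = np.inf if i == len(ordered) - 1 else (m + ordered[i + 1][1]) / 2.0
        windows[c] = (lo, hi)
    return windows


def windows_from_reference(image: np.ndarray,
                           ref: ReferenceSegmentation) -> Dict[int, Window]:
    """Windows at midpoints between per-class mean intensities under ``ref``.

    The background mean is taken over pixels outside every class mask.
    This is the supervised analogue of histogram thresholding: the
    reference tells us where each tissue lives, the image tells us how
    bright it is there.
    """
    arr = np.asarray(image, dtype=np.float64)
    fg = np.zeros(arr.shape, dtype=bool)
    means = {}
    for c, m in ref.masks.items():
        means[c] = float(arr[m].mean())
        fg |= m
    means[0] = float(arr[~fg].mean()) if (~fg).any() else min(means.values()) - 1.0
    return windows_from_means(means, classes=tuple(ref.masks))


def naive_seeds(image: np.ndarray,
                windows: Mapping[int, Window],
                class_order: Sequence[int] = TISSUE_CLASSES) -> SeedSet:
    """Fixed naive baseline: first row-major pixel inside each window.

    Emulates an uninformed manual pick — typically a pixel on the outer
    boundary of its tissue — and is fully deterministic, which makes it
    a reproducible "manual selection" baseline to compare the GA against.
    """
    masks = candidate_seeds(image, {c: windows[c] for c in class_order})
    coords = []
    for c in class_order:
        idx = np.flatnonzero(masks[c].ravel())[0]
        coords.append(tuple(int(v) for v in divmod(int(idx), image.shape[1])))
    return SeedSet(class_order=tuple(class_order), coords=tuple(coords))


def fitness(pred: np.ndarray, ref: ReferenceSegmentation) -> FitnessResult:
    """Summed squared difference between per-class binary maps.

    For each class the predicted label map is binarized and compared
    pixelwise with the reference class mask; squared differences of 0/1
    maps count mismatches.  Lower is fitter; 0 means the prediction
    reproduces the reference exactly on all class maps.
    """
    labels = np.asarray(pred)
    if labels.shape != ref.shape:
        raise DataError(
            f"prediction shape {labels.shape} != reference shape {ref.shape}"
        )
    per_class = {}
    for c, mask in ref.masks.items():
        per_class[c] = float(np.count_nonzero((labels == c) != mask))
    return FitnessResult(total_cost=float(sum(per_class.values())),
                         per_class_cost=per_class)


def tournament_select(population: Sequence[SeedSet],
                      fitnesses: Sequence[float],
                      cfg: GAConfig,
                      rng: np.random.Generator) -> SeedSet:
    """Return the lowest-cost member of a uniform tournament.

    ``tournament_size`` entrants are drawn uniformly *with replacement*;
    ties are broken toward the lowest population index, keeping the
    draw deterministic given the generator state.
    """
    if len(population) == 0:
        raise ConfigurationError("cannot select from an empty population")
    idx = rng.integers(0, len(population), size=cfg.tournament_size)
    best = min(idx, key=lambda i: (fitnesses[i], i))
    return population[best]


def crossover(a: SeedSet, b: SeedSet,
              rng: np.random.Generator) -> Tuple[SeedSet, SeedSet]:
    """Per-class uniform crossover: swap each class's coordinate w.p. 0.5."""
    if a.class_order != b.class_order:
        raise ConfigurationError("parents disagree on class order")
    swap = rng.random(len(a.coords)) < 0.5
    ca = [bc if s else ac for ac, bc, s in zip(a.coords, b.coords, swap)]
    cb = [ac if s else bc for ac, bc, s in zip(a.coords, b.coords, swap)]
    return (SeedSet(a.class_order, tuple(ca)),
            SeedSet(a.class_order, tuple(cb)))


def mutate(s: SeedSet,
           candidates: Mapping[int, np.ndarray],
           mutation_rate: float,
           rng: np.random.Generator) -> SeedSet:
    """Resample each class's coordinate from its candidate mask w.p. rate.

    ``candidates`` maps class -> boolean candidate mask (or an (m, 2)
    coordinate array).  The result stays inside each class's candidates.
    """
    coords = list(s.coords)
    for i, c in enumerate(s.class_order):
        if rng.random() < mutation_rate:
            coords[i] = _draw_candidate(candidates[c], rng)
    return SeedSet(s.class_order, tuple(coords))


def _candidate_coords(mask_or_coords: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask_or_coords)
    if arr.dtype == bool:
        return np.argwhere(arr)
    return arr.reshape(-1, 2)


def _draw_candidate(mask_or_coords: np.ndarray,
                    rng: np.random.Generator) -> Coord:
    coords = _candidate_coords(mask_or_coords)
    if len(coords) == 0:
        raise ConfigurationError("empty candidate mask")
    r, c = coords[rng.integers(0, len(coords))]
    return (int(r), int(c))


def ga_optimize(image: np.ndarray,
                ref: ReferenceSegmentation,
                candidates: Mapping[int, np.ndarray],
                grow_cfg: GrowConfig,
                ga_cfg: GAConfig,
                ) -> Tuple[SeedSet, List[float]]:
    """Evolve seed sets to minimize segmentation cost against ``ref``.

    Each individual is scored by growing a full segmentation from its
    seeds and evaluating :func:`fitness` against the reference.  Elitism
    copies the ``elitism_count`` best individuals unchanged into the next
    generation, so the best cost per generation is non-increasing.  The
    run stops after ``generations`` generations, after
    ``stall_generations`` generations without improvement, or as soon as
    the cost reaches its global lower bound of zero.  Identical
    ``rng_seed`` (and inputs) reproduce the run bit-for-bit.

    Returns the best seed set found and the best-cost history, one entry
    per evaluated generation (entry 0 is the initial population).
    """
    grow_cfg.validate()
    ga_cfg.validate()
    arr = np.asarray(image, dtype=np.float64)
    classes = tuple(grow_cfg.class_order)
    cand = {c: _candidate_coords(candidates[c]) for c in classes}
    for c, coords in cand.items():
        if len(coords) == 0:
            raise ConfigurationError(f"no candidate seeds for class {c}")
    rng = np.random.default_rng(ga_cfg.rng_seed)

    cache: Dict[Tuple[Coord, ...], float] = {}

    def evaluate(s: SeedSet) -> float:
        key = s.coords
        if key not in cache:
            cache[key] = fitness(segment(arr, s, grow_cfg), ref).total_cost
        return cache[key]

    def random_individual() -> SeedSet:
        return SeedSet(classes,
                       tuple(_draw_candidate(cand[c], rng) for c in classes))

    population = [random_individual() for _ in range(ga_cfg.population_size)]
    costs = [evaluate(s) for s in population]

    history: List[float] = []
    best_cost = np.inf
    best_seed: Optional[SeedSet] = None
    stall = 0

    for gen in range(ga_cfg.generations + 1):
        order = sorted(range(len(population)), key=lambda i: (costs[i], i))
        gen_best = costs[order[0]]
        if gen_best < best_cost:
            best_cost, best_seed = gen_best, population[order[0]]
            stall = 0
        elif gen > 0:
            stall += 1
        history.append(best_cost)
        if len(history) > 1 and history[-1] > history[-2]:
            raise AssertionError("elitism violated: best cost increased")
        if gen == ga_cfg.generations or best_cost == 0 \
                or stall >= ga_cfg.stall_generations:
            break
        elites = [population[i] for i in order[:ga_cfg.elitism_count]]
        next_pop = list(elites)
        while len(next_pop) < ga_cfg.population_size:
            p1 = tournament_select(population, costs, ga_cfg, rng)
            p2 = tournament_select(population, costs, ga_cfg, rng)
            if rng.random() < ga_cfg.crossover_rate:
                c1, c2 = crossover(p1, p2, rng)
            else:
                c1, c2 = p1, p2
            for child in (c1, c2):
                if len(next_pop) < ga_cfg.population_size:
                    next_pop.append(
                        mutate(child, cand, ga_cfg.mutation_rate, rng))
        population = next_pop
        costs = [evaluate(s) for s in population]

    assert best_seed is not None
    return best_seed, history
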