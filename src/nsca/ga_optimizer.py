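"""Genetic-algorithm maturation of negative-selection detectors.

Each GA run evolves ONE detector: chromosomes are fixed-point binary
encodings of a center in [0, 1]^Q; the raw fitness f of a candidate is
its maximal safe radius (distance to the nearest padded self sample), and
the selection fitness f* = delta * f / s divides by a diversity factor

    s = sum_i 1 / (1 + dist(candidate, accepted detector i))

so candidates crowding previously accepted detectors are penalized.  The
loop is the classic generational GA: roulette-wheel selection,
multi-point crossover, per-bit mutation, with elitism.  Repeating the run
N_d times, feeding accepted detectors into the diversity term, yields a
mature detector set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import InvariantError
from .nsa_core import Detector, DetectorSet, SelfSet, R_MIN, max_safe_radius


@dataclass
class GaParams:
    population_size: int = 50
    generations: int = 100
    crossover_points: int = 2
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # None -> 1 / chromosome bits
    bits_per_gene: int = 16
    delta: float = 1.0
    elitism_count: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise InvariantError("population_size must be >= 2")
        if not 0 <= self.crossover_rate <= 1:
            raise InvariantError("crossover_rate must be in [0, 1]")
        if self.mutation_rate is not None \
                and not 0 <= self.mutation_rate <= 1:
            raise InvariantError("mutation_rate must be in [0, 1]")


def decode_bits(bits: np.ndarray, n_genes: int, bits_per_gene: int
                ) -> np.ndarray:
    """Fixed-point decode: each gene's unsigned integer / (2^bits - 1).

    Accepts a single chromosome (1-D) or a population (2-D); total decode,
    always lands in [0, 1]^n_genes.
    """
    bits = np.asarray(bits)
    single = bits.ndim == 1
    pop = np.atleast_2d(bits).astype(np.uint64)
    if pop.shape[1] != n_genes * bits_per_gene:
        raise InvariantError("chromosome length mismatch")
    weights = (1 << np.arange(bits_per_gene - 1, -1, -1)).astype(np.uint64)
    ints = pop.reshape(pop.shape[0], n_genes, bits_per_gene) @ weights
    out = ints.astype(float) / float((1 << bits_per_gene) - 1)
    return out[0] if single else out


def initial_fitness(center: np.ndarray, self_set: SelfSet) -> float:
    """Raw fitness f = maximal safe radius, floored at 0 when infeasible."""
    f = max_safe_radius(center, self_set)
    return f if f > R_MIN else 0.0


def diversity_factor(center: np.ndarray,
                     selected: list[Detector]) -> float:
    """s = sum_i 1/(1 + dist); empty selection -> 1 (identity convention)."""
    if not selected:
        return 1.0
    centers = np.vstack([d.center for d in selected])
    d = cdist(np.atleast_2d(center), centers)[0]
    return float(np.sum(1.0 / (1.0 + d)))


def updated_fitness(f: float, s: float, delta: float = 1.0) -> float:
    """f* = delta * f / s."""
    if s <= 0:
        raise InvariantError("diversity factor must be positive")
    return delta * f / s


def roulette_select(fitnesses: np.ndarray, count: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Sample ``count`` indices with replacement, probability ~ fitness.

    All-zero fitness falls back to uniform selection.
    """
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise InvariantError("roulette selection needs non-negative fitness")
    total = f.sum()
    p = None if total == 0 else f / total
    return rng.choice(f.size, size=count, replace=True, p=p)


def crossover(parent_a: np.ndarray, parent_b: np.ndarray, n_points: int,
              rng: np.random.Generator, crossover_rate: float = 1.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-point crossover of two bit strings.

    ``n_points`` distinct interior cut positions are drawn uniformly and
    segments alternate between parents.  With probability
    1 - crossover_rate the parents pass through unchanged.
    """
    a = np.asarray(parent_a).astype(bool)
    b = np.asarray(parent_b).astype(bool)
    if a.shape != b.shape:
        raise InvariantError("parents must have equal length")
    if n_points >= a.size:
        raise InvariantError("too many crossover points")
    if rng.random() >= crossover_rate:
        return a.copy(), b.copy()
    cuts = np.sort(rng.choice(np.arange(1, a.size), size=n_points,
                              replace=False))
    take_b = np.zeros(a.size, dtype=bool)
    flip = False
    prev = 0
    for c in list(cuts) + [a.size]:
        take_b[prev:c] = flip
        flip = not flip
        prev = c
    child1 = np.where(take_b, b, a)
    child2 = np.where(take_b, a, b)
    return child1, child2


def mutate(bits: np.ndarray, rate: float,
           rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise InvariantError("mutation rate must be in [0, 1]")
    bits = np.asarray(bits).astype(bool)
    flips = rng.random(bits.shape) < rate
    return bits ^ flips


def _evaluate(pop_bits: np.ndarray, n_genes: int, p: GaParams,
              self_set: SelfSet, selected: list[Detector]
              ) -> tuple[np.ndarray, np.ndarray]:
    """(raw safe radii floored at 0, selection fitness f*) per individual."""
    centers = decode_bits(pop_bits, n_genes, p.bits_per_gene)
    d_self = cdist(centers, self_set.rows).min(axis=1) - self_set.r_self
    f = np.where(d_self > R_MIN, d_self, 0.0)
    if selected:
        sel = np.vstack([d.center for d in selected])
        s = (1.0 / (1.0 + cdist(centers, sel))).sum(axis=1)
    else:
        s = np.ones(centers.shape[0])
    return f, p.delta * f / s


def evolve_one_detector(self_set: SelfSet, selected: list[Detector],
                        p: GaParams, rng: np.random.Generator,
                        detector_id: int = 0,
                        trace: list | None = None) -> Detector:
    """One full GA run -> one mature detector.

    The returned detector's radius is its full safe radius and its fitness
    the diversity-adjusted f*; it is guaranteed self-tolerant (radius
    strictly clears every padded self sample).
    """
    n_genes = self_set.rows.shape[1]
    n_bits = n_genes * p.bits_per_gene
    mut_rate = p.mutation_rate if p.mutation_rate is not None else 1.0 / n_bits
    pop = rng.random((p.population_size, n_bits)) < 0.5
    f, fstar = _evaluate(pop, n_genes, p, self_set, selected)
    best_bits, best_f, best_fstar = None, 0.0, -np.inf
    for gen in range(p.generations):
        # elitism: carry the current best individuals over unchanged
        elite_idx = np.argsort(-fstar)[: p.elitism_count]
        elite = pop[elite_idx].copy()
        parents = roulette_select(fstar, p.population_size, rng)
        children = []
        for i in range(0, p.population_size - 1, 2):
            c1, c2 = crossover(pop[parents[i]], pop[parents[i + 1]],
                               p.crossover_points, rng, p.crossover_rate)
            children.extend([c1, c2])
        if len(children) < p.population_size:  # odd population size
            children.append(pop[parents[-1]].copy())
        pop = np.array(children[: p.population_size])
        pop = mutate(pop, mut_rate, rng)
        pop[: p.elitism_count] = elite
        f, fstar = _evaluate(pop, n_genes, p, self_set, selected)
        gi = int(np.argmax(fstar))
        if fstar[gi] > best_fstar:
            best_bits, best_f, best_fstar = pop[gi].copy(), f[gi], fstar[gi]
        if trace is not None:
            # per-generation population best; with elitism this never drops
            trace.append((detector_id, gen, float(f[gi]), float(fstar[gi]),
                          float(fstar.mean())))
    if best_bits is None or best_f <= 0.0:
        raise InvariantError(
            "GA found no candidate clearing the self region; enlarge the "
            "space or reduce R_self"
        )
    center = decode_bits(best_bits, n_genes, p.bits_per_gene)
    return Detector(center=center, radius=float(best_f),
                    fitness=float(best_fstar), id=detector_id)


def generate_detector_set(self_set: SelfSet, n_detectors: int, p: GaParams,
                          rng: np.random.Generator | None = None,
                          class_label: int = 0,
                          self_convention: str = "self_is_rest",
                          trace: list | None = None) -> DetectorSet:
    """Run the GA ``n_detectors`` times, feeding accepted detectors into the
    diversity term so later runs are pushed away from covered regions."""
    if n_detectors < 1:
        raise InvariantError("n_detectors must be >= 1")
    if rng is None:
        rng = np.random.default_rng(p.seed)
    detectors: list[Detector] = []
    for did in range(n_detectors):
        detectors.append(
            evolve_one_detector(self_set, detectors, p, rng,
                                detector_id=did, trace=trace)
        )
    return DetectorSet(detectors=detectors, class_label=class_label,
                       r_self=self_set.r_self,
                       self_convention=self_convention)
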