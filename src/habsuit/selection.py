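"""Variable selection with a simple genetic algorithm.

A chromosome is one inclusion flag per candidate preference curve; its
fitness is the best TSS the flagged model can reach on the training set
over a grid of decision thresholds. The GA uses tournament selection,
uniform crossover, per-bit mutation and elitism, and prefers parsimonious
models when fitness ties (fewer variables win; remaining ties break on
lexicographic bit order). Curve parameters are frozen during the search:
selection chooses variables, not parameter values.

Because the fitness of a bit pattern is deterministic given the training
set, evaluations are memoised; on small candidate rosters the GA therefore
visits each subset at most once, and :func:`exhaustive_search` provides the
global optimum to compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .hsi import SuitabilityModel
from .metrics import optimal_threshold

#: Fitness sentinel for an all-zero (empty) chromosome — below any TSS.
INVALID_FITNESS = -1.0


@dataclass
class GAConfig:
    """Settings of the simple genetic algorithm.

    ``mutation_rate=None`` means the conventional 1/L per bit. Search stops
    early after ``stagnation_patience`` generations without improvement.
    """

    population_size: int = 50
    n_generations: int = 100
    crossover_rate: float = 0.7
    mutation_rate: float | None = None
    tournament_size: int = 3
    elitism_count: int = 1
    stagnation_patience: int = 25
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("population_size", "n_generations", "tournament_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if rate is not None and not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count > self.population_size:
            raise ConfigurationError("elitism_count must be in [0, population_size]")
        if self.stagnation_patience < 1:
            raise ConfigurationError("stagnation_patience must be >= 1")


class FitnessEvaluator:
    """Memoised TSS fitness of variable subsets on one training set.

    Precomputes the per-record log-SI matrix of every candidate curve once,
    so evaluating a subset is a masked row sum followed by a threshold scan.
    """

    def __init__(self, hpcs, training_records: pd.DataFrame, labels,
                 grid_step: float = 0.01):
        if not hpcs:
            raise DataError("need at least one candidate HPC")
        self.hpcs = list(hpcs)
        self.labels = np.asarray(labels, dtype=int)
        self.grid_step = grid_step
        probe = SuitabilityModel(hpcs=self.hpcs, threshold=0.5)
        si = probe.si_table(training_records).to_numpy(dtype=float)
        if np.isnan(si).any():
            raise DataError("training records must be complete for all candidates")
        self._zero = si == 0.0
        with np.errstate(divide="ignore"):
            self._log_si = np.where(self._zero, 0.0, np.log(np.where(si > 0, si, 1.0)))
        self.n_candidates = len(self.hpcs)
        self._cache: dict = {}
        self.n_evaluations = 0

    def hsi(self, bits) -> np.ndarray:
        mask = np.asarray(bits, dtype=bool)
        m = int(mask.sum())
        if m == 0:
            raise DataError("empty chromosome has no model")
        hsi = np.exp(self._log_si[:, mask].sum(axis=1) / m)
        hsi[self._zero[:, mask].any(axis=1)] = 0.0
        return hsi

    def fitness(self, bits) -> tuple[float, float]:
        """(best TSS, TSS-optimal threshold) of the subset; memoised."""
        key = tuple(int(b) for b in bits)
        if key in self._cache:
            return self._cache[key]
        if not any(key):
            result = (INVALID_FITNESS, 0.0)
        else:
            self.n_evaluations += 1
            thr, tss = optimal_threshold(self.hsi(key), self.labels, self.grid_step)
            result = (tss, thr)
        self._cache[key] = result
        return result


def fitness(bits, hpcs, training_records, labels, grid_step: float = 0.01) -> float:
    """One-off TSS fitness of a chromosome (see :class:`FitnessEvaluator`)."""
    return FitnessEvaluator(hpcs, training_records, labels, grid_step).fitness(bits)[0]


def _rank_key(tss: float, bits: tuple):
    # higher TSS first, then fewer variables, then lexicographic bit order
    return (-tss, sum(bits), bits)


@dataclass
class SearchResult:
    model: SuitabilityModel
    bits: tuple
    tss: float
    threshold: float
    log: pd.DataFrame = field(repr=False)
    n_evaluations: int = 0


def optimize_model(hpcs, training_set, config: GAConfig | None = None,
                   grid_step: float = 0.01) -> SearchResult:
    """Run the GA and return the best model with its TSS-optimal threshold.

    ``training_set`` is a :class:`~habsuit.sampling.TrainingSet` or a
    DataFrame carrying a binary ``label`` column. The search log records
    per-generation best and mean fitness and the best bit pattern.
    """
    config = config if config is not None else GAConfig()
    records = getattr(training_set, "records", training_set)
    labels = records["label"].to_numpy(dtype=int)
    ev = FitnessEvaluator(hpcs, records, labels, grid_step)
    L = ev.n_candidates
    rng = np.random.default_rng(config.seed)
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / L

    def repair(bits: np.ndarray) -> np.ndarray:
        if not bits.any():
            bits[rng.integers(L)] = True
        return bits

    pop = [repair(rng.random(L) < 0.5) for _ in range(config.population_size)]
    scores = [ev.fitness(ind)[0] for ind in pop]

    log_rows = []
    best_bits, best_tss = None, -np.inf
    stagnant = 0
    for gen in range(config.n_generations):
        order = sorted(range(len(pop)),
                       key=lambda i: _rank_key(scores[i], tuple(map(int, pop[i]))))
        gen_best = pop[order[0]]
        gen_best_tss = scores[order[0]]
        improved = gen_best_tss > best_tss or (
            best_bits is not None
            and gen_best_tss == best_tss
            and _rank_key(gen_best_tss, tuple(map(int, gen_best)))
            < _rank_key(best_tss, best_bits)
        )
        if best_bits is None or improved:
            best_bits = tuple(map(int, gen_best))
            best_tss = gen_best_tss
            stagnant = 0
        else:
            stagnant += 1
        log_rows.append({
            "generation": gen,
            "best_tss": best_tss,
            "mean_tss": float(np.mean(scores)),
            "best_bits": "".join(map(str, best_bits)),
        })
        if stagnant >= config.stagnation_patience:
            break

        elite = [pop[i].copy() for i in order[: config.elitism_count]]
        children = list(elite)
        while len(children) < config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), config.tournament_size)
                winner = min(contenders,
                             key=lambda i: _rank_key(scores[i], tuple(map(int, pop[i]))))
                parents.append(pop[winner])
            p1, p2 = parents
            if rng.random() < config.crossover_rate:
                take = rng.random(L) < 0.5  # uniform crossover
                child = np.where(take, p1, p2)
            else:
                child = p1.copy()
            flip = rng.random(L) < mut_rate
            child = np.logical_xor(child, flip)
            children.append(repair(child))
        pop = children[: config.population_size]
        scores = [ev.fitness(ind)[0] for ind in pop]

    tss, thr = ev.fitness(best_bits)
    mask = np.array(best_bits, dtype=bool)
    model = SuitabilityModel(hpcs=[h for h, keep in zip(ev.hpcs, mask) if keep],
                             threshold=thr)
    return SearchResult(model=model, bits=best_bits, tss=tss, threshold=thr,
                        log=pd.DataFrame(log_rows), n_evaluations=ev.n_evaluations)


def exhaustive_search(hpcs, training_set, grid_step: float = 0.01) -> SearchResult:
    """Best subset by full enumeration (2^L - 1 candidates); L <= ~16."""
    records = getattr(training_set, "records", training_set)
    labels = records["label"].to_numpy(dtype=int)
    ev = FitnessEvaluator(hpcs, records, labels, grid_step)
    L = ev.n_candidates
    if L > 20:
        raise ConfigurationError("exhaustive search is limited to 20 candidates")
    best_key, best = None, None
    for code in range(1, 2**L):
        bits = tuple((code >> i) & 1 for i in range(L))
        tss, thr = ev.fitness(bits)
        key = _rank_key(tss, bits)
        if best_key is None or key < best_key:
            best_key, best = key, (bits, tss, thr)
    bits, tss, thr = best
    mask = np.array(bits, dtype=bool)
    model = SuitabilityModel(hpcs=[h for h, keep in zip(ev.hpcs, mask) if keep],
                             threshold=thr)
    log = pd.DataFrame([{"generation": 0, "best_tss": tss, "mean_tss": tss,
                         "best_bits": "".join(map(str, bits))}])
    return SearchResult(model=model, bits=bits, tss=tss, threshold=thr,
                        log=log, n_evaluations=ev.n_evaluations)
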