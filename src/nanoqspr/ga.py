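"""Genetic-algorithm descriptor selection wrapped around cross-validated PLS.

A chromosome is a bit mask over the descriptor pool.  Fitness of a
chromosome is the leave-one-out RMSECV (minimized; R^2 maximization is
selectable) of a PLS model restricted to the selected descriptors, with
the component count chosen per chromosome as the best among the
candidate LV counts.  The search uses tournament selection, uniform
crossover, per-bit mutation and elitism, with a repair step that flips
random bits until the subset-size constraint holds.  All randomness
flows from a single integer seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ModelingTable
from .preprocess import DEFAULT_DDOF
from .validation import fit_statistics, loo_cross_validate
from .pls import fit_pls


@dataclass
class GAConfig:
    """GA hyperparameters; defaults are conventional GA-PLS settings."""

    population_size: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # per bit; default 2 / pool size
    elitism_count: int = 2
    tournament_size: int = 3
    min_subset: int = 1
    max_subset: int | None = None  # default: pool size
    lv_candidates: tuple[int, ...] = (1, 2, 3)
    fitness: str = "RMSECV"  # or "R2"
    ddof: int = DEFAULT_DDOF
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.min_subset < 1:
            raise ValueError("min_subset must be >= 1")
        if self.max_subset is not None and self.max_subset < self.min_subset:
            raise ValueError("max_subset must be >= min_subset")
        if self.fitness not in ("RMSECV", "R2"):
            raise ValueError(f"unknown fitness {self.fitness!r}")


@dataclass
class GAResult:
    """Outcome of a GA run; ``best_fitness`` is re-evaluated fresh at the end."""

    best_descriptors: list[str]
    best_n_lv: int
    best_fitness: float
    trajectory: list[float]       # best-so-far fitness per generation
    n_evaluations: int
    config: GAConfig

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["config"]["lv_candidates"] = list(self.config.lv_candidates)
        Path(path).write_text(json.dumps(d, indent=1))

    def trajectory_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"generation": range(len(self.trajectory)), "best_fitness": self.trajectory}
        ).to_csv(path, index=False)


def evaluate_chromosome(
    table: ModelingTable,
    descriptors: list[str],
    n_lv: int,
    fitness: str = "RMSECV",
    ddof: int = DEFAULT_DDOF,
) -> float:
    """Fitness of a descriptor subset at a fixed LV count (lower is better).

    RMSECV delegates to :func:`~nanoqspr.validation.loo_cross_validate`;
    the R^2 variant returns ``-R2`` so that minimization is uniform.
    """
    if not descriptors:
        raise ValueError("empty descriptor subset")
    if n_lv > len(descriptors):
        raise ValueError("n_lv exceeds subset size")
    if fitness == "RMSECV":
        _, rmsecv, _ = loo_cross_validate(table, n_lv, descriptors=descriptors, ddof=ddof)
        return rmsecv
    model = fit_pls(table.subset_descriptors(descriptors), n_lv, ddof=ddof)
    r2, _ = fit_statistics(model, table.subset_descriptors(descriptors))
    return -r2


def _score(table, pool, bits, cfg, cache, counter):
    """Best (fitness, n_lv) over the LV candidates for a chromosome."""
    key = bits.tobytes()
    if key in cache:
        return cache[key]
    names = [pool[j] for j in np.flatnonzero(bits)]
    best = (np.inf, 0)
    for a in cfg.lv_candidates:
        if a > len(names):
            continue
        try:
            f = evaluate_chromosome(table, names, a, cfg.fitness, cfg.ddof)
        except ValueError:
            continue
        counter[0] += 1
        if f < best[0]:
            best = (f, a)
    cache[key] = best
    return best


def _repair(bits: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> None:
    """Flip random bits in place until lo <= popcount <= hi."""
    while bits.sum() < lo:
        off = np.flatnonzero(~bits)
        bits[rng.choice(off)] = True
    while bits.sum() > hi:
        on = np.flatnonzero(bits)
        bits[rng.choice(on)] = False


def run_ga(table: ModelingTable, pool: list[str] | None = None, config: GAConfig | None = None) -> GAResult:
    """Seeded GA search over descriptor subsets (and LV count) of *pool*.

    Returns the best chromosome found, its LV count and a freshly
    re-evaluated fitness, plus the best-so-far trajectory.
    """
    cfg = config or GAConfig()
    if pool is None:
        pool = table.descriptor_names
    if not pool:
        raise ValueError("empty descriptor pool")
    missing = [n for n in pool if n not in table.descriptor_names]
    if missing:
        raise KeyError(f"pool descriptors not in table: {missing}")
    nbits = len(pool)
    lo = cfg.min_subset
    hi = cfg.max_subset if cfg.max_subset is not None else nbits
    hi = min(hi, nbits)
    pmut = cfg.mutation_prob if cfg.mutation_prob is not None else min(1.0, 2.0 / nbits)
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, tuple[float, int]] = {}
    counter = [0]

    popn = np.zeros((cfg.population_size, nbits), dtype=bool)
    for i in range(cfg.population_size):
        k = int(rng.integers(lo, hi + 1))
        popn[i, rng.choice(nbits, size=k, replace=False)] = True

    scores = [_score(table, pool, ind, cfg, cache, counter) for ind in popn]
    order = np.argsort([s[0] for s in scores], kind="stable")
    best_bits = popn[order[0]].copy()
    best_fit, best_lv = scores[order[0]]
    trajectory = [best_fit]

    for _ in range(cfg.generations):
        elite_idx = order[: cfg.elitism_count]
        new = [popn[i].copy() for i in elite_idx]
        while len(new) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, size=cfg.tournament_size)
                winner = min(contenders, key=lambda i: scores[i][0])
                parents.append(popn[winner])
            if rng.random() < cfg.crossover_prob:
                mask = rng.random(nbits) < 0.5
                child = np.where(mask, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(nbits) < pmut
            child = child ^ flip
            _repair(child, lo, hi, rng)
            new.append(child)
        popn = np.array(new)
        scores = [_score(table, pool, ind, cfg, cache, counter) for ind in popn]
        order = np.argsort([s[0] for s in scores], kind="stable")
        if scores[order[0]][0] < best_fit:
            best_bits = popn[order[0]].copy()
            best_fit, best_lv = scores[order[0]]
        trajectory.append(best_fit)

    best_names = [pool[j] for j in np.flatnonzero(best_bits)]
    # fresh re-evaluation: the reported fitness never comes from the cache
    final_fit = evaluate_chromosome(table, best_names, best_lv, cfg.fitness, cfg.ddof)
    return GAResult(
        best_descriptors=best_names,
        best_n_lv=best_lv,
        best_fitness=final_fit,
        trajectory=trajectory,
        n_evaluations=counter[0],
        config=cfg,
    )


def exhaustive_search(
    table: ModelingTable,
    pool: list[str],
    max_size: int,
    lv_candidates: tuple[int, ...] = (1, 2, 3),
    fitness: str = "RMSECV",
    ddof: int = DEFAULT_DDOF,
) -> tuple[list[str], int, float]:
    """Enumerate every subset of *pool* up to ``max_size`` (oracle for small pools)."""
    from itertools import combinations

    best = (np.inf, 0, ())
    for k in range(1, max_size + 1):
        for combo in combinations(pool, k):
            for a in lv_candidates:
                if a > k:
                    continue
                try:
                    f = evaluate_chromosome(table, list(combo), a, fitness, ddof)
                except ValueError:
                    continue
                if f < best[0]:
                    best = (f, a, combo)
    return list(best[2]), best[1], best[0]
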