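"""Genetic function approximation (GFA) descriptor selection.

A population of fixed-size descriptor subsets is evolved against Friedman's
revised lack-of-fit (LOF) score of each subset's OLS fit:

    LOF = (SSE / n) / [1 − λ (c + d·p) / n]²

where ``SSE`` is the training sum of squared errors, ``c`` the number of
non-constant model terms, ``p`` the number of descriptors appearing in them
(for purely linear terms ``c = p`` = subset size), ``d`` a smoothness
penalty weighting model size, ``n`` the training-set size and ``λ`` a safety
factor keeping the denominator positive.  Lower LOF is better; at fixed
model size LOF is monotone in SSE.

The genetic operators are tournament selection (size 2), uniform crossover
sampling the child's genes from the two parents' descriptor-set union, and
per-gene mutation swapping a descriptor for a uniformly random unused one.
An elite copy of the best chromosome survives every generation, so the best
LOF is non-increasing.  A fitness cache keyed by descriptor set avoids
re-fitting; results are identical with or without it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import DescriptorTable
from .mlr import LinearModel, fit_mlr, predict
from .validation import loo_cv, r_squared

__all__ = ["GfaConfig", "GfaResult", "lof", "evolve", "exhaustive_search",
           "sweep_subset_size"]


@dataclass(frozen=True)
class GfaConfig:
    """GFA run parameters (defaults follow the study's published settings)."""

    population_size: int = 1000
    generations: int = 5000
    mutation_probability: float = 0.1
    smoothness: float = 0.5  # d in the LOF formula
    lam: float = 0.99        # λ safety factor
    subset_size: int = 5
    top_n: int = 10
    seed: int = 0
    patience: int | None = None  # optional early stop on stalled best LOF

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_probability <= 1:
            raise ValueError("mutation_probability must lie in [0, 1]")
        if self.population_size < 2 or self.generations < 0:
            raise ValueError("population_size >= 2 and generations >= 0 required")
        if self.subset_size < 1 or self.top_n < 1:
            raise ValueError("subset_size and top_n must be positive")


@dataclass(frozen=True)
class GfaResult:
    """Ranked distinct models with their scores and the search trajectory."""

    models: tuple[LinearModel, ...]
    lof_values: tuple[float, ...]
    r2_values: tuple[float, ...]
    r2cv_values: tuple[float, ...]
    evaluation_count: int
    best_lof_per_generation: tuple[float, ...]

    @property
    def best(self) -> LinearModel:
        return self.models[0]


def lof(sse: float, n: int, c: int, d: float, p: int, lam: float) -> float:
    """Friedman's revised lack-of-fit score (lower is better)."""
    if sse < 0:
        raise ValueError("sse must be non-negative")
    if n < 1:
        raise ValueError("n must be positive")
    shrink = 1.0 - lam * (c + d * p) / n
    if shrink <= 0:
        raise ValueError(
            f"model too large for sample size: lambda*(c + d*p) = "
            f"{lam * (c + d * p):.3f} >= n = {n}"
        )
    return (sse / n) / shrink**2


def _make_sse(table: DescriptorTable, cache: dict):
    """Fast cached SSE of the OLS fit on a descriptor-index subset.

    Rank-deficient subsets score +inf so the search discards them instead of
    silently pseudo-inverting.
    """
    design = np.column_stack([np.ones(table.n_samples), table.values])
    y = table.response

    def sse_of(subset_idx: frozenset) -> float:
        hit = cache.get(subset_idx)
        if hit is None:
            cols = [0] + [i + 1 for i in sorted(subset_idx)]
            X = design[:, cols]
            beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < len(cols):
                hit = np.inf
            else:
                r = y - X @ beta
                hit = float(r @ r)
            cache[subset_idx] = hit
        return hit

    return sse_of


def evolve(table: DescriptorTable, config: GfaConfig) -> GfaResult:
    """Run the GFA search and return the ``top_n`` distinct best models."""
    names = table.descriptor_names
    n_desc = len(names)
    k = config.subset_size
    if n_desc < k:
        raise ValueError(f"{n_desc} descriptors cannot form subsets of size {k}")
    rng = np.random.default_rng(config.seed)
    cache: dict[frozenset, float] = {}
    all_idx = np.arange(n_desc)
    sse_of = _make_sse(table, cache)

    def score(chrom: frozenset) -> float:
        k_ = len(chrom)
        return lof(sse_of(chrom), table.n_samples, k_, config.smoothness,
                   k_, config.lam)

    # initial population of distinct random subsets (or every subset if the
    # space is smaller than the population)
    from math import comb
    population: list[frozenset] = []
    if comb(n_desc, k) <= config.population_size:
        population = [frozenset(c) for c in itertools.combinations(range(n_desc), k)]
    else:
        seen: set[frozenset] = set()
        while len(population) < config.population_size:
            chrom = frozenset(rng.choice(all_idx, size=k, replace=False).tolist())
            if chrom not in seen:
                seen.add(chrom)
                population.append(chrom)

    fitness = [score(c) for c in population]
    best_per_gen: list[float] = [min(fitness)]
    stall = 0

    for _ in range(config.generations):
        order = np.argsort(fitness, kind="stable")
        elite = population[int(order[0])]
        children: list[frozenset] = [elite]
        while len(children) < len(population):
            parents = []
            for _ in range(2):  # two size-2 tournaments
                a, b = rng.integers(0, len(population), size=2)
                parents.append(population[a] if fitness[a] <= fitness[b]
                               else population[b])
            # uniform set-crossover: genes carried by both parents are always
            # inherited; the remaining slots are drawn from the symmetric
            # difference (dropping shared genes would destroy heritability)
            shared = sorted(parents[0] & parents[1])
            diff = sorted(parents[0] ^ parents[1])
            need = k - len(shared)
            genes = shared + (
                rng.choice(diff, size=need, replace=False).tolist()
                if need < len(diff) else diff
            )
            # per-gene mutation into an unused descriptor
            current = set(genes)
            for g_pos in range(len(genes)):
                if rng.random() < config.mutation_probability:
                    unused = [i for i in range(n_desc) if i not in current]
                    if unused:
                        new_gene = int(rng.choice(unused))
                        current.discard(genes[g_pos])
                        genes[g_pos] = new_gene
                        current.add(new_gene)
            # repair: top up if crossover union was too small
            while len(current) < k:
                extra = int(rng.choice([i for i in range(n_desc)
                                        if i not in current]))
                current.add(extra)
            children.append(frozenset(current))
        population = children
        fitness = [score(c) for c in population]
        gen_best = min(fitness)
        if gen_best < best_per_gen[-1] - 1e-15:
            stall = 0
        else:
            stall += 1
        best_per_gen.append(min(gen_best, best_per_gen[-1]))
        if config.patience is not None and stall >= config.patience:
            break

    # rank every distinct subset ever evaluated, refit the winners
    ranked = sorted(
        ((c, s) for c, s in cache.items() if np.isfinite(s)),
        key=lambda kv: (
            lof(kv[1], table.n_samples, len(kv[0]), config.smoothness,
                len(kv[0]), config.lam),
            tuple(sorted(kv[0])),
        ),
    )[: config.top_n]
    models, lofs, r2s, r2cvs = [], [], [], []
    for chrom, sse in ranked:
        subset = tuple(names[i] for i in sorted(chrom))
        model = fit_mlr(table, subset)
        models.append(model)
        lofs.append(lof(sse, table.n_samples, len(chrom), config.smoothness,
                        len(chrom), config.lam))
        y = table.response
        r2s.append(r_squared(y, predict(model, table), float(np.mean(y))))
        r2cvs.append(loo_cv(table, subset)[0])
    return GfaResult(
        models=tuple(models),
        lof_values=tuple(lofs),
        r2_values=tuple(r2s),
        r2cv_values=tuple(r2cvs),
        evaluation_count=len(cache),
        best_lof_per_generation=tuple(best_per_gen),
    )


def exhaustive_search(table: DescriptorTable, subset_size: int,
                      config: GfaConfig | None = None) -> tuple[tuple[str, ...], float]:
    """Enumerate every subset of ``subset_size`` and return the LOF minimizer.

    Feasible only for small descriptor pools; used as an exact reference for
    the genetic search.
    """
    config = config or GfaConfig(subset_size=subset_size)
    names = table.descriptor_names
    best_subset, best_lof = None, np.inf
    for combo in itertools.combinations(range(len(names)), subset_size):
        subset = tuple(names[i] for i in combo)
        sse = fit_mlr(table, subset).sse
        score = lof(sse, table.n_samples, subset_size, config.smoothness,
                    subset_size, config.lam)
        if score < best_lof:
            best_subset, best_lof = subset, score
    return best_subset, best_lof


def sweep_subset_size(table: DescriptorTable, sizes, config: GfaConfig,
                      tolerance: float = 0.01):
    """Best R² and LOO R²cv for each candidate subset size.

    Returns a pandas DataFrame (columns ``size``, ``r2``, ``r2cv``) plus the
    recommended size: the smallest size beyond which R²cv stops improving by
    more than ``tolerance``.
    """
    import pandas as pd

    rows = []
    for size in sizes:
        res = evolve(table, replace(config, subset_size=size, top_n=1))
        rows.append({"size": int(size), "r2": res.r2_values[0],
                     "r2cv": res.r2cv_values[0]})
    df = pd.DataFrame(rows)
    recommended = int(df["size"].iloc[0])
    for i in range(1, len(df)):
        if df["r2cv"].iloc[i] > df["r2cv"].iloc[:i].max() + tolerance:
            recommended = int(df["size"].iloc[i])
    return df, recommended
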