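"""Genetic-algorithm search for the VMD hyperparameters (k, alpha).

The search space is by default the box k in [2, 10] (integer), alpha in
[100, 5000]. Chromosomes are fixed-length bit strings (4 bits for k, 12
for alpha, Gray-decoded so single bit flips are local moves), evolved by
tournament selection, one-point crossover, bit-flip mutation and single-
individual elitism. Fitness is the minimum approximate entropy over the
resulting VMD modes: the best (k, alpha) is the one that concentrates the
most regular (artifact-like) component into a single mode. Lower is
better; the search minimizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .apen import ApEnParams, approximate_entropy
from .vmd import VMDParams, vmd_decompose

__all__ = ["GAConfig", "GAResult", "vmd_fitness", "ga_optimize"]

K_BITS = 4
ALPHA_BITS = 12


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 10
    n_iter: int = 30
    k_range: tuple[int, int] = (2, 10)
    alpha_range: tuple[float, float] = (100.0, 5000.0)
    p_crossover: float = 0.8
    p_mutation: float = 0.05
    seed: int | None = None
    elitism: int = 1
    tournament_size: int = 2

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.k_range[0] > self.k_range[1] or self.alpha_range[0] > self.alpha_range[1]:
            raise ValueError("ranges must be non-empty")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GAResult:
    best_k: int
    best_alpha: float
    best_fitness: float
    fitness_history: list  # best fitness of each generation's population


def _gray_to_int(bits: np.ndarray) -> int:
    val = 0
    acc = 0
    for b in bits:
        acc ^= int(b)
        val = (val << 1) | acc
    return val


def _decode(chrom: np.ndarray, cfg: GAConfig) -> tuple[int, float]:
    k_int = _gray_to_int(chrom[:K_BITS])
    a_int = _gray_to_int(chrom[K_BITS:])
    k_lo, k_hi = cfg.k_range
    a_lo, a_hi = cfg.alpha_range
    k = k_lo + int(round(k_int / (2**K_BITS - 1) * (k_hi - k_lo)))
    alpha = a_lo + a_int / (2**ALPHA_BITS - 1) * (a_hi - a_lo)
    return k, alpha


def vmd_fitness(
    x: np.ndarray,
    fs: float,
    k: int,
    alpha: float,
    apen_params: ApEnParams | None = None,
    vmd_params: VMDParams | None = None,
) -> float:
    """Minimum mode ApEn after a VMD at (k, alpha). Lower = a more
    regular, artifact-concentrated mode exists."""
    base = vmd_params if vmd_params is not None else VMDParams()
    params = VMDParams(
        k=k,
        alpha=alpha,
        tau=base.tau,
        tol=base.tol,
        max_iter=base.max_iter,
        init=base.init,
        seed=base.seed,
    )
    res = vmd_decompose(x, fs, params)
    return min(approximate_entropy(m, apen_params) for m in res.modes)


def ga_optimize(x, fs: float, cfg: GAConfig, fitness_fn=vmd_fitness) -> GAResult:
    """Minimize fitness_fn(x, fs, k, alpha) over the (k, alpha) box.

    Deterministic under a fixed cfg.seed. Fitness values are cached per
    decoded (k, alpha), so repeated genotypes cost nothing.
    """
    rng = np.random.default_rng(cfg.seed)
    n_bits = K_BITS + ALPHA_BITS
    pop = rng.integers(0, 2, size=(cfg.pop_size, n_bits), dtype=np.uint8)

    cache: dict[tuple[int, float], float] = {}

    def evaluate(chrom) -> float:
        key = _decode(chrom, cfg)
        if key not in cache:
            cache[key] = float(fitness_fn(x, fs, key[0], key[1]))
        return cache[key]

    history: list[float] = []
    fitness = np.array([evaluate(c) for c in pop])
    best_i = int(np.argmin(fitness))
    best_chrom, best_fit = pop[best_i].copy(), float(fitness[best_i])
    history.append(best_fit)

    for _ in range(cfg.n_iter):
        children = []
        if cfg.elitism >= 1:
            children.append(best_chrom.copy())
        while len(children) < cfg.pop_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.pop_size, size=cfg.tournament_size)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]].copy())
            a, b = parents
            if rng.random() < cfg.p_crossover:
                cut = int(rng.integers(1, n_bits))
                a2 = np.concatenate([a[:cut], b[cut:]])
                b2 = np.concatenate([b[:cut], a[cut:]])
                a, b = a2, b2
            for child in (a, b):
                flips = rng.random(n_bits) < cfg.p_mutation
                child[flips] ^= 1
                if len(children) < cfg.pop_size:
                    children.append(child)
        pop = np.array(children, dtype=np.uint8)
        fitness = np.array([evaluate(c) for c in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_fit = float(fitness[gen_best])
            best_chrom = pop[gen_best].copy()
        history.append(best_fit)

    k, alpha = _decode(best_chrom, cfg)
    return GAResult(
        best_k=k, best_alpha=alpha, best_fitness=best_fit, fitness_history=history
    )
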