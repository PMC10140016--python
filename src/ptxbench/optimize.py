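"""Small real-coded genetic algorithm and an NSGA-II-style multi-objective GA.

Both operate on bounded real decision vectors with optional periodic
(phase-like) dimensions, evaluate populations in batch, and are fully
deterministic for a given ``numpy.random.Generator``.  They are intentionally
compact: population sizes here are tens to hundreds and objective evaluation
(batched field superposition) dominates the runtime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GAConfig", "ga_minimize", "nsga2"]


@dataclass
class GAConfig:
    """Hyperparameters shared by the single- and multi-objective GA."""

    population: int | None = None  # default 20 * n_dim, capped below
    generations: int = 60
    crossover_prob: float = 0.9
    mutation_prob: float = 0.25
    mutation_sigma: float = 0.25  # fraction of the variable range, decays
    elite: int = 2
    max_population: int = 400

    def resolve_population(self, n_dim: int) -> int:
        pop = self.population if self.population else 20 * n_dim
        pop = min(pop, self.max_population)
        return max(8, pop + pop % 2)


def _init_population(pop, lower, upper, rng):
    return lower + rng.random((pop, len(lower))) * (upper - lower)


def _repair(x, lower, upper, periodic):
    span = upper - lower
    if periodic.any():
        x[:, periodic] = lower[periodic] + np.mod(
            x[:, periodic] - lower[periodic], span[periodic]
        )
    rest = ~periodic
    x[:, rest] = np.clip(x[:, rest], lower[rest], upper[rest])
    return x


def _offspring(parents, lower, upper, periodic, cfg, frac_done, rng):
    pop, n_dim = parents.shape
    span = upper - lower
    perm = rng.permutation(pop)
    a, b = parents[perm[: pop // 2]], parents[perm[pop // 2:]]
    # blend (BLX-0.5) crossover
    do = rng.random(pop // 2) < cfg.crossover_prob
    alpha = rng.random((pop // 2, n_dim)) * 1.5 - 0.25
    c1 = np.where(do[:, None], a + alpha * (b - a), a)
    c2 = np.where(do[:, None], b + alpha * (a - b), b)
    children = np.concatenate([c1, c2])
    # gaussian mutation with a decaying step size
    sigma = cfg.mutation_sigma * (1.0 - 0.9 * frac_done)
    mutate = rng.random(children.shape) < cfg.mutation_prob
    children = children + mutate * rng.normal(0.0, sigma, children.shape) * span
    return _repair(children, lower, upper, periodic)


def ga_minimize(
    fun_batch,
    lower,
    upper,
    periodic=None,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Minimize ``fun_batch`` (maps (pop, n) -> (pop,)) over a box.

    Returns ``(x_best, f_best)``.
    """
    cfg = config or GAConfig()
    rng = rng or np.random.default_rng(0)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n_dim = len(lower)
    periodic = (
        np.zeros(n_dim, dtype=bool) if periodic is None
        else np.asarray(periodic, dtype=bool)
    )
    pop_n = cfg.resolve_population(n_dim)

    x = _init_population(pop_n, lower, upper, rng)
    f = np.asarray(fun_batch(x), dtype=float)
    for gen in range(cfg.generations):
        # binary tournament selection
        i, j = rng.integers(0, pop_n, (2, pop_n))
        parents = np.where((f[i] <= f[j])[:, None], x[i], x[j])
        children = _offspring(
            parents, lower, upper, periodic, cfg, gen / max(1, cfg.generations), rng
        )
        fc = np.asarray(fun_batch(children), dtype=float)
        merged_x = np.concatenate([x, children])
        merged_f = np.concatenate([f, fc])
        keep = np.argsort(merged_f, kind="stable")[:pop_n]
        x, f = merged_x[keep], merged_f[keep]
    best = int(np.argmin(f))
    return x[best].copy(), float(f[best])


# ---------------------------------------------------------------------------
# multi-objective (NSGA-II style)
# ---------------------------------------------------------------------------

def _nondominated_sort(f: np.ndarray) -> np.ndarray:
    """Pareto rank (0 = non-dominated) for a (n, m) objective matrix."""
    n = len(f)
    dominated_by = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        le = np.all(f[i] <= f, axis=1)
        lt = np.any(f[i] < f, axis=1)
        dominates = le & lt
        dominates[i] = False
        for j in np.where(dominates)[0]:
            dominated_by[i].append(j)
        dom_count[i] = np.sum(np.all(f <= f[i], axis=1) & np.any(f < f[i], axis=1))
    rank = np.full(n, -1, dtype=int)
    current = np.where(dom_count == 0)[0]
    r = 0
    while len(current):
        rank[current] = r
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.array(sorted(set(nxt)), dtype=int)
        r += 1
    return rank


def _crowding(f: np.ndarray) -> np.ndarray:
    n, m = f.shape
    dist = np.zeros(n)
    for k in range(m):
        order = np.argsort(f[:, k], kind="stable")
        fk = f[order, k]
        span = fk[-1] - fk[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0 and n > 2:
            dist[order[1:-1]] += (fk[2:] - fk[:-2]) / span
    return dist


def nsga2(
    fun_batch,
    lower,
    upper,
    periodic=None,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Bi-objective minimization; returns the final non-dominated set (X, F)."""
    cfg = config or GAConfig()
    rng = rng or np.random.default_rng(0)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n_dim = len(lower)
    periodic = (
        np.zeros(n_dim, dtype=bool) if periodic is None
        else np.asarray(periodic, dtype=bool)
    )
    pop_n = cfg.resolve_population(n_dim)

    x = _init_population(pop_n, lower, upper, rng)
    f = np.asarray(fun_batch(x), dtype=float)
    for gen in range(cfg.generations):
        rank = _nondominated_sort(f)
        crowd = _crowding(f)
        i, j = rng.integers(0, pop_n, (2, pop_n))
        better = (rank[i] < rank[j]) | ((rank[i] == rank[j]) & (crowd[i] >= crowd[j]))
        parents = np.where(better[:, None], x[i], x[j])
        children = _offspring(
            parents, lower, upper, periodic, cfg, gen / max(1, cfg.generations), rng
        )
        fc = np.asarray(fun_batch(children), dtype=float)
        mx = np.concatenate([x, children])
        mf = np.concatenate([f, fc])
        mrank = _nondominated_sort(mf)
        # environmental selection: fill by rank, break ties by crowding
        selected: list[int] = []
        r = 0
        while len(selected) < pop_n:
            front = np.where(mrank == r)[0]
            if len(front) == 0:
                break
            if len(selected) + len(front) <= pop_n:
                selected.extend(front.tolist())
            else:
                c = _crowding(mf[front])
                order = np.argsort(-c, kind="stable")
                need = pop_n - len(selected)
                selected.extend(front[order[:need]].tolist())
            r += 1
        idx = np.array(selected[:pop_n])
        x, f = mx[idx], mf[idx]

    rank = _nondominated_sort(f)
    front = np.where(rank == 0)[0]
    # deduplicate near-identical objective pairs
    ff = f[front]
    order = np.lexsort((ff[:, 1], ff[:, 0]))
    front = front[order]
    keep = [front[0]]
    for idx in front[1:]:
        if not np.allclose(f[idx], f[keep[-1]], rtol=1e-9, atol=1e-12):
            keep.append(idx)
    keep = np.array(keep)
    return x[keep], f[keep]
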