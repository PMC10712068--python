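"""Elitist multi-objective selection machinery (NSGA-II).

Implements the pieces of the NSGA-II algorithm that are independent of the
genome representation: constraint-dominated non-dominated sorting, crowding
distance, binary tournament selection and elitist environmental selection.
Constraint handling follows the constraint-domination rule: a feasible
solution always beats an infeasible one, infeasible solutions are compared by
total constraint violation, and feasible solutions by Pareto dominance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dominates",
    "nondominated_sort",
    "crowding_distance",
    "environmental_selection",
    "tournament_pick",
]


def dominates(fa: np.ndarray, fb: np.ndarray, cva: float = 0.0, cvb: float = 0.0) -> bool:
    """Constraint-domination: does solution a dominate solution b?"""
    if cva == 0.0 and cvb > 0.0:
        return True
    if cva > 0.0 and cvb == 0.0:
        return False
    if cva > 0.0 and cvb > 0.0:
        return cva < cvb
    return bool(np.all(fa <= fb) and np.any(fa < fb))


def nondominated_sort(F: np.ndarray, cv: np.ndarray | None = None) -> list[np.ndarray]:
    """Fast non-dominated sorting into fronts (front 0 = non-dominated).

    ``F`` is (n, m) objective values (minimized); ``cv`` is per-solution total
    constraint violation (0 = feasible).
    """
    F = np.asarray(F, dtype=float)
    n = F.shape[0]
    cv = np.zeros(n) if cv is None else np.asarray(cv, dtype=float)

    # vectorized pairwise domination matrix: D[i, j] = i dominates j
    feas = cv == 0
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    D = (feas[:, None] & feas[None, :] & le & lt)
    D |= feas[:, None] & ~feas[None, :]
    D |= ~feas[:, None] & ~feas[None, :] & (cv[:, None] < cv[None, :])

    n_dominating = D.sum(axis=0)
    fronts: list[np.ndarray] = []
    assigned = np.zeros(n, dtype=bool)
    current = np.flatnonzero(n_dominating == 0)
    while current.size:
        fronts.append(current)
        assigned[current] = True
        n_dominating = n_dominating - D[current].sum(axis=0)
        current = np.flatnonzero((n_dominating == 0) & ~assigned)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (boundary members infinite)."""
    F = np.asarray(F, dtype=float)
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        col = F[order, j]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = col[-1] - col[0]
        if span == 0:
            continue
        dist[order[1:-1]] += (col[2:] - col[:-2]) / span
    return dist


def rank_and_crowding(F: np.ndarray, cv: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-solution front rank and crowding distance."""
    fronts = nondominated_sort(F, cv)
    n = np.asarray(F).shape[0]
    rank = np.empty(n, dtype=int)
    crowd = np.empty(n, dtype=float)
    for r, front in enumerate(fronts):
        rank[front] = r
        crowd[front] = crowding_distance(np.asarray(F)[front])
    return rank, crowd


def environmental_selection(F: np.ndarray, cv: np.ndarray, k: int) -> np.ndarray:
    """Pick the k survivors: fill whole fronts, split the last by crowding."""
    fronts = nondominated_sort(F, cv)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= k:
            chosen.extend(int(i) for i in front)
        else:
            crowd = crowding_distance(np.asarray(F)[front])
            order = np.argsort(-crowd, kind="stable")
            chosen.extend(int(front[i]) for i in order[: k - len(chosen)])
            break
    return np.array(chosen, dtype=np.intp)


def tournament_pick(
    rank: np.ndarray, crowd: np.ndarray, cv: np.ndarray, rng: np.random.Generator
) -> int:
    """Binary tournament: feasibility, then rank, then crowding distance."""
    i, j = rng.integers(0, len(rank), size=2)
    if cv[i] != cv[j] and (cv[i] == 0 or cv[j] == 0):
        return int(i if cv[i] < cv[j] else j)
    if cv[i] > 0 and cv[j] > 0:
        return int(i if cv[i] < cv[j] else j)
    if rank[i] != rank[j]:
        return int(i if rank[i] < rank[j] else j)
    if crowd[i] != crowd[j]:
        return int(i if crowd[i] > crowd[j] else j)
    return int(i)
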