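"""Multi-objective survival selection.

Implements strong Pareto dominance (every objective strictly lower), Pareto
rank (PR, the domination count) and Pareto count (PC, the dominated-set
size), fast non-dominated sorting into fronts, NSGA-style crowding
distance, and four selectors over a combined parent+offspring population:

``select_evo_diverse``
    whole non-dominated fronts first, then the crowding-distance tail of
    the first partially-admitted front (the diversity-preserving selector);
``select_mea``
    truncation on total energy (the single-objective memetic baseline);
``select_mea_pr``
    lexicographic (PR ascending, total energy ascending);
``select_mea_prpc``
    lexicographic (PR ascending, PC descending, total energy ascending).

All Pareto quantities are computed only within the current combined
population (no archive). Individuals passed to the selectors must expose
``.objectives`` (with ``as_array``) and ``.total_energy``; ties everywhere
are broken by stable input order so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError


def _as_matrix(objective_list) -> np.ndarray:
    rows = []
    for o in objective_list:
        rows.append(o.as_array() if hasattr(o, "as_array") else np.asarray(o, dtype=float))
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2:
        raise InputError("objective vectors must share one dimensionality")
    return mat


def dominates(u, v) -> bool:
    """Strong dominance: every component of u strictly below v's."""
    ua = u.as_array() if hasattr(u, "as_array") else np.asarray(u, dtype=float)
    va = v.as_array() if hasattr(v, "as_array") else np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise InputError(f"dimension mismatch: {ua.shape} vs {va.shape}")
    return bool(np.all(ua < va))


def _dominance_matrix(mat: np.ndarray) -> np.ndarray:
    """dom[i, j] True iff individual i strongly dominates individual j."""
    return np.all(mat[:, None, :] < mat[None, :, :], axis=2)


def pareto_rank(objective_list) -> np.ndarray:
    """PR[i]: number of individuals strongly dominating i (0 = front)."""
    mat = _as_matrix(objective_list)
    return _dominance_matrix(mat).sum(axis=0)


def pareto_count(objective_list) -> np.ndarray:
    """PC[i]: number of individuals strongly dominated by i."""
    mat = _as_matrix(objective_list)
    return _dominance_matrix(mat).sum(axis=1)


@dataclass(frozen=True)
class FrontPartition:
    """Ordered non-dominated fronts (index lists into the input) plus the
    per-individual domination count (PR) and dominated-set size (PC).

    Front generation stops at the first front whose inclusion brings the
    cumulative size to >= N, so the last front may be only partially needed
    by a selector.
    """

    fronts: tuple
    pr: np.ndarray
    pc: np.ndarray


def fast_nondominated_sort(objective_list, n: int) -> FrontPartition:
    """Peel non-dominated fronts by the count-decrement algorithm.

    F1 holds the PR-0 individuals; each next front collects the individuals
    whose domination count reaches 0 once the previous front's dominated
    sets are discounted. Stops once the cumulative front size reaches n.
    """
    if len(objective_list) == 0:
        raise InputError("objective list must be non-empty")
    if n < 1:
        raise InputError(f"population size must be >= 1, got {n}")
    mat = _as_matrix(objective_list)
    dom = _dominance_matrix(mat)
    pr = dom.sum(axis=0)
    pc = dom.sum(axis=1)

    counts = pr.astype(int).copy()
    assigned = np.zeros(len(mat), dtype=bool)
    current = np.flatnonzero(counts == 0)
    assigned[current] = True
    fronts = []
    total = 0
    while current.size:
        fronts.append(tuple(int(i) for i in current))
        total += current.size
        if total >= n:
            break
        # Decrement domination counts of everything the front dominates.
        counts -= dom[current].sum(axis=0)
        current = np.flatnonzero((counts == 0) & ~assigned)
        assigned[current] = True
    return FrontPartition(fronts=tuple(fronts), pr=pr, pc=pc)


def crowding_distance(front_objectives) -> np.ndarray:
    """Per-individual crowding distance within one front.

    Per objective, members are sorted ascending; the two extremes get +inf
    and interior members accumulate the normalized gap between their
    neighbors. A degenerate objective (max == min) contributes 0 to
    interior members. The final distance is the sum over objectives.
    """
    mat = _as_matrix(front_objectives)
    m = len(mat)
    dist = np.zeros(m)
    for k in range(mat.shape[1]):
        order = np.argsort(mat[:, k], kind="stable")
        vals = mat[order, k]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        span = vals[-1] - vals[0]
        if span > 0 and m > 2:
            gaps = (vals[2:] - vals[:-2]) / span
            interior = order[1:-1]
            finite = ~np.isinf(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def _combined(parents, offspring):
    pop = list(parents) + list(offspring)
    if not pop:
        raise InputError("empty combined population")
    return pop


def select_evo_diverse(parents, offspring, n: int):
    """Front-then-crowding survival: admit whole fronts F1..Ft while they
    fit, then fill the remaining slots from F_{t+1} in descending crowding
    distance (stable input order on ties). Output size is exactly n."""
    pop = _combined(parents, offspring)
    objs = [p.objectives for p in pop]
    part = fast_nondominated_sort(objs, n)
    chosen = []
    for front in part.fronts:
        if len(chosen) + len(front) <= n:
            chosen.extend(front)
            if len(chosen) == n:
                break
        else:
            need = n - len(chosen)
            front_objs = [objs[i] for i in front]
            dist = crowding_distance(front_objs)
            # Descending crowding distance, stable on ties.
            order = np.argsort(-dist, kind="stable")
            chosen.extend(front[i] for i in order[:need])
            break
    if len(chosen) < n:
        raise InputError(
            f"combined population of {len(pop)} cannot fill n={n}")
    return [pop[i] for i in chosen]


def select_mea(parents, offspring, n: int):
    """Truncation on total energy (lowest n of the combined population)."""
    pop = _combined(parents, offspring)
    totals = np.array([p.total_energy for p in pop])
    order = np.argsort(totals, kind="stable")
    return [pop[i] for i in order[:n]]


def select_mea_pr(parents, offspring, n: int):
    """Sort by Pareto rank (ascending), then total energy (ascending)."""
    pop = _combined(parents, offspring)
    pr = pareto_rank([p.objectives for p in pop])
    totals = np.array([p.total_energy for p in pop])
    order = np.lexsort((totals, pr))  # stable: input index is final tiebreak
    return [pop[i] for i in order[:n]]


def select_mea_prpc(parents, offspring, n: int):
    """Sort by PR (ascending), PC (descending), total energy (ascending)."""
    pop = _combined(parents, offspring)
    objs = [p.objectives for p in pop]
    pr = pareto_rank(objs)
    pc = pareto_count(objs)
    totals = np.array([p.total_energy for p in pop])
    order = np.lexsort((totals, -pc, pr))
    return [pop[i] for i in order[:n]]


SELECTORS = {
    "evo_diverse": select_evo_diverse,
    "mea": select_mea,
    "mea_pr": select_mea_pr,
    "mea_prpc": select_mea_prpc,
}
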