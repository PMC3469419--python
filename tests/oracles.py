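"""Independent oracles used by the test suite.

Everything here deliberately avoids the code paths it checks: shortest paths
by Floyd-Warshall on an adjacency matrix, LP optima by brute-force vertex
enumeration, and the one-sided Welch test from the textbook formulas.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import t as t_dist


def floyd_warshall(nodes: list, edges: list[tuple]) -> np.ndarray:
    """All-pairs shortest path lengths by the classic triple loop."""
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for u, v in edges:
        D[index[u], index[v]] = 1.0
        D[index[v], index[u]] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def lp_vertex_maximum(S: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                      c: np.ndarray, tol: float = 1e-9) -> float:
    """max c.v subject to S v = 0, lower <= v <= upper, by enumerating the
    basic feasible solutions of the (bounded) polytope.

    Every vertex fixes at least n - rank(S) variables at a bound; we try all
    such selections and bound assignments, solving the remaining square-ish
    system.  Intended for n <= 8 only.
    """
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if m else 0
    best = -np.inf
    if np.all(lower <= 0) and np.all(upper >= 0):
        best = 0.0  # the zero flux vector is always a vertex candidate
    for free in itertools.combinations(range(n), r):
        free = list(free)
        fixed = [j for j in range(n) if j not in free]
        S_free = S[:, free]
        if np.linalg.matrix_rank(S_free) < r:
            continue
        for choice in itertools.product((0, 1), repeat=len(fixed)):
            v = np.zeros(n)
            for j, up in zip(fixed, choice):
                v[j] = upper[j] if up else lower[j]
            rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m)
            sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lower - tol) or np.any(v > upper + tol):
                continue
            best = max(best, float(c @ v))
    return best


def welch_one_sided_greater(x, y) -> tuple[float, float, float]:
    """Textbook one-sided (x > y) Welch statistic, Welch-Satterthwaite df
    and p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) / nx
    vy = y.var(ddof=1) / ny
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (nx - 1) + vy ** 2 / (ny - 1))
    return float(t), float(df), float(t_dist.sf(t, df))


def random_toy_fba_problem(rng: np.random.Generator):
    """A small random reconstruction plus objective for oracle comparison.

    Up to 6 internal/exchange reactions over up to 5 metabolites with finite
    bounds containing zero, and a 1-2 component objective; with the attached
    drains the LP stays at <= 8 variables.
    """
    from rhizomod.network_model import MetabolicModel, Reaction
    from rhizomod.optimization import ObjectiveFunction

    n_mets = int(rng.integers(3, 6))
    mets = [f"x{i}[c]" for i in range(n_mets)]
    n_internal = int(rng.integers(2, 6))
    reactions = []
    # one or two uptake exchanges so nonzero flux is possible
    n_ex = int(rng.integers(1, 3))
    for e in range(n_ex):
        reactions.append(Reaction(id=f"EX{e}", stoichiometry={mets[e % n_mets]: 1.0},
                                  reversible=False, lower_bound=0.0,
                                  upper_bound=float(rng.integers(1, 11))))
    for j in range(min(n_internal, 6 - n_ex - 1)):
        a, b = rng.choice(n_mets, size=2, replace=False)
        coeff = float(rng.integers(1, 3))
        reversible = bool(rng.random() < 0.3)
        lb = -float(rng.integers(1, 11)) if reversible else 0.0
        reactions.append(Reaction(
            id=f"R{j}", stoichiometry={mets[a]: -coeff, mets[b]: 1.0},
            reversible=reversible, lower_bound=lb,
            upper_bound=float(rng.integers(1, 11))))
    model = MetabolicModel.from_reactions(reactions)
    present = model.metabolite_ids  # only species that appear in reactions
    n_of = min(int(rng.integers(1, 3)), len(present))
    targets = rng.choice(len(present), size=n_of, replace=False)
    of = ObjectiveFunction({present[i]: 1.0 for i in targets})
    return model, of
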