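"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct formula evaluation, exhaustive
enumeration, fixed-step integration — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- correlation -----------------------------------------------------------


def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment formula evaluated directly."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def threshold_edges_brute(corr: np.ndarray, names, threshold, absolute=False):
    edges = set()
    for i, j in itertools.combinations(range(len(names)), 2):
        r = corr[i, j]
        if (abs(r) if absolute else r) >= threshold:
            edges.add(tuple(sorted((names[i], names[j]))))
    return edges


# --- hierarchical clustering ----------------------------------------------


def average_linkage_brute(dist: np.ndarray):
    """Naive average-linkage agglomeration.

    Returns (merges, cophenetic) where merges is a list of
    (cluster_a_members, cluster_b_members, height) and cophenetic is the full
    leaf-pair cophenetic distance matrix.
    """
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        merges.append((sorted(clusters[a]), sorted(clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges, coph


def same_cluster_pairs_brute(partition, names):
    edges = set()
    for cluster in partition:
        for a, b in itertools.combinations(sorted(cluster), 2):
            edges.add((a, b))
    return edges


# --- Fisher exact ----------------------------------------------------------


def fisher_two_sided_brute(a: int, b: int, m: int) -> float:
    """Two-sided Fisher exact P for [[a, m-a], [b, m-b]] by full enumeration.

    Hypergeometric over tables with fixed margins; sums every table whose
    probability does not exceed the observed one.
    """
    row1, row2 = m, m
    col1 = a + b
    def prob(k: int) -> float:
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(row1 + row2, col1)
        )
    k_min = max(0, col1 - row2)
    k_max = min(row1, col1)
    p_obs = prob(a)
    return sum(p for k in range(k_min, k_max + 1) if (p := prob(k)) <= p_obs * (1 + 1e-12))


# --- graphs ----------------------------------------------------------------


def max_cliques_brute(nodes, edges):
    """All maximum cliques by subset enumeration (n <= ~15)."""
    nodes = sorted(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    best_size = 0
    best = []
    for size in range(1, len(nodes) + 1):
        found = []
        for sub in itertools.combinations(nodes, size):
            if all(b in adj[a] for a, b in itertools.combinations(sub, 2)):
                found.append(set(sub))
        if found:
            best_size, best = size, found
    return best_size, best


def all_dags(nodes):
    """Every DAG on the given nodes (use only for <= 3 nodes: 25 DAGs)."""
    pairs = list(itertools.permutations(nodes, 2))
    seen = []
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        edges = [p for p, m in zip(pairs, mask) if m]
        parents = {n: frozenset(u for u, v in edges if v == n) for n in nodes}
        if any((u, v) in edges and (v, u) in edges for u, v in edges):
            continue
        if _is_acyclic(nodes, edges):
            seen.append(parents)
    return seen


def _is_acyclic(nodes, edges) -> bool:
    children = {n: [] for n in nodes}
    for u, v in edges:
        children[u].append(v)
    state = {n: 0 for n in nodes}

    def visit(n):
        if state[n] == 1:
            return False
        if state[n] == 2:
            return True
        state[n] = 1
        ok = all(visit(c) for c in children[n])
        state[n] = 2
        return ok

    return all(visit(n) for n in nodes)


def single_edit_dags_brute(nodes, parents, max_parents):
    """All acyclic single-edge-edit variants of a DAG, by filtering all DAGs...

    Actually: generate candidates directly (add/del/rev on every ordered
    pair) and keep the acyclic ones within the parent cap.
    """
    current = {(u, v) for v, ps in parents.items() for u in ps}
    results = set()
    for u, v in itertools.permutations(nodes, 2):
        candidates = []
        if (u, v) in current:
            candidates.append(current - {(u, v)})                      # delete
            candidates.append((current - {(u, v)}) | {(v, u)})         # reverse
        elif (v, u) not in current:
            candidates.append(current | {(u, v)})                      # add
        for edges in candidates:
            if not _is_acyclic(nodes, edges):
                continue
            ps = {n: frozenset(a for a, b in edges if b == n) for n in nodes}
            if max(len(s) for s in ps.values()) > max_parents:
                continue
            results.add(frozenset((n, ps[n]) for n in nodes))
    return results


# --- BDe -------------------------------------------------------------------


def bde_brute(codes: np.ndarray, levels, parents_idx, ess: float) -> float:
    """BDe log score evaluated directly from lgamma, one node at a time."""
    total = 0.0
    n_vars = codes.shape[1]
    for i in range(n_vars):
        ps = sorted(parents_idx[i])
        r = levels[i]
        q = 1
        for p in ps:
            q *= levels[p]
        a_jk = ess / (q * r)
        a_j = ess / q
        for j, combo in enumerate(itertools.product(*[range(levels[p]) for p in ps]) if ps else [()]):
            rows = np.all(codes[:, ps] == np.array(combo, dtype=int), axis=1) if ps else np.ones(len(codes), bool)
            n_j = int(rows.sum())
            total += math.lgamma(a_j) - math.lgamma(a_j + n_j)
            for k in range(r):
                n_jk = int(np.sum(codes[rows, i] == k))
                total += math.lgamma(a_jk + n_jk) - math.lgamma(a_jk)
    return total


# --- ODE -------------------------------------------------------------------


def _rk4_python(rho, alpha, state0, grid, steps_per_interval):
    (a11, a12), (a21, a22) = alpha
    s = list(map(float, state0))
    out = [list(s)]

    def f(x, y, a, b):
        return (
            rho - a11 * x * a - a12 * x * b,
            rho - a21 * y * a - a22 * y * b,
            rho - a11 * x * a - a21 * y * a,
            rho - a12 * x * b - a22 * y * b,
        )

    for g in range(len(grid) - 1):
        h = (grid[g + 1] - grid[g]) / steps_per_interval
        for _ in range(steps_per_interval):
            x, y, a, b = s
            k1 = f(x, y, a, b)
            k2 = f(x + h / 2 * k1[0], y + h / 2 * k1[1], a + h / 2 * k1[2], b + h / 2 * k1[3])
            k3 = f(x + h / 2 * k2[0], y + h / 2 * k2[1], a + h / 2 * k2[2], b + h / 2 * k2[3])
            k4 = f(x + h * k3[0], y + h * k3[1], a + h * k3[2], b + h * k3[3])
            s = [
                s[d] + h / 6 * (k1[d] + 2 * k2[d] + 2 * k3[d] + k4[d])
                for d in range(4)
            ]
        out.append(list(s))
    return np.array(out).T


try:  # numba shrinks the fixed-step oracle from minutes to seconds
    from numba import njit

    @njit(cache=False)
    def _rk4_numba(rho, a11, a12, a21, a22, x, y, a, b, grid, steps_per_interval):
        n = grid.shape[0]
        out = np.empty((4, n))
        out[0, 0], out[1, 0], out[2, 0], out[3, 0] = x, y, a, b
        for g in range(n - 1):
            h = (grid[g + 1] - grid[g]) / steps_per_interval
            for _ in range(steps_per_interval):
                k1x = rho - a11 * x * a - a12 * x * b
                k1y = rho - a21 * y * a - a22 * y * b
                k1a = rho - a11 * x * a - a21 * y * a
                k1b = rho - a12 * x * b - a22 * y * b
                x2, y2, a2, b2 = x + h / 2 * k1x, y + h / 2 * k1y, a + h / 2 * k1a, b + h / 2 * k1b
                k2x = rho - a11 * x2 * a2 - a12 * x2 * b2
                k2y = rho - a21 * y2 * a2 - a22 * y2 * b2
                k2a = rho - a11 * x2 * a2 - a21 * y2 * a2
                k2b = rho - a12 * x2 * b2 - a22 * y2 * b2
                x3, y3, a3, b3 = x + h / 2 * k2x, y + h / 2 * k2y, a + h / 2 * k2a, b + h / 2 * k2b
                k3x = rho - a11 * x3 * a3 - a12 * x3 * b3
                k3y = rho - a21 * y3 * a3 - a22 * y3 * b3
                k3a = rho - a11 * x3 * a3 - a21 * y3 * a3
                k3b = rho - a12 * x3 * b3 - a22 * y3 * b3
                x4, y4, a4, b4 = x + h * k3x, y + h * k3y, a + h * k3a, b + h * k3b
                k4x = rho - a11 * x4 * a4 - a12 * x4 * b4
                k4y = rho - a21 * y4 * a4 - a22 * y4 * b4
                k4a = rho - a11 * x4 * a4 - a21 * y4 * a4
                k4b = rho - a12 * x4 * b4 - a22 * y4 * b4
                x += h / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
                y += h / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
                a += h / 6 * (k1a + 2 * k2a + 2 * k3a + k4a)
                b += h / 6 * (k1b + 2 * k2b + 2 * k3b + k4b)
            out[0, g + 1], out[1, g + 1], out[2, g + 1], out[3, g + 1] = x, y, a, b
        return out

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def rk4_oracle(rho, alpha, state0, grid, dt):
    """Fixed-step classical RK4 on the competition model, sampled on ``grid``."""
    steps = max(1, round((grid[1] - grid[0]) / dt))
    if HAVE_NUMBA:
        (a11, a12), (a21, a22) = alpha
        x, y, a, b = map(float, state0)
        return _rk4_numba(
            float(rho), float(a11), float(a12), float(a21), float(a22),
            x, y, a, b, np.asarray(grid, dtype=float), steps,
        )
    return _rk4_python(rho, alpha, state0, grid, steps)
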