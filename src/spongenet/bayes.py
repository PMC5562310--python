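"""Static Bayesian-network inference over discretized expression data.

Expression values are quantile-discretized per miRNA, candidate structures
are scored with the Bayesian Dirichlet equivalence (BDe) marginal likelihood,
and the structure space is searched by simulated annealing over single-edge
changes (add / delete / reverse), tracking the single best network visited.

The BDe score for node *i* with ``r_i`` levels and parent-configuration count
``q_i`` uses the likelihood-equivalent uniform prior ``alpha_ijk = ess /
(q_i * r_i)``:

    score_i = sum_j [ lnG(a_ij) - lnG(a_ij + N_ij)
                      + sum_k ( lnG(a_ijk + N_ijk) - lnG(a_ijk) ) ]

with ``a_ij = sum_k a_ijk`` and ``N_ijk`` the count of samples where node i
takes level k under parent configuration j.  The score is decomposable, so
the search re-scores only the families a move touches.  Markov-equivalent
DAGs receive identical scores (checked in the test suite), and the implicit
complexity penalty favors sparse graphs on independent data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .network import new_network

__all__ = [
    "DiscreteMatrix",
    "DAGModel",
    "BayesConfig",
    "quantile_discretize",
    "bde_score",
    "family_score",
    "local_moves",
    "anneal_search",
    "dag_to_network",
]


# ---------------------------------------------------------------------------
# discretization


@dataclass
class DiscreteMatrix:
    """Integer-coded samples x miRNAs matrix with per-column level counts."""

    mirna_ids: list[str]
    codes: np.ndarray  # (n_samples, n_vars) ints
    levels: list[int]
    boundaries: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        for j, lv in enumerate(self.levels):
            col = codes[:, j]
            if col.min() < 0 or col.max() > lv - 1:
                raise ValueError(f"codes out of range for column {self.mirna_ids[j]}")
        self.codes = codes.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]


def quantile_discretize(data: pd.DataFrame, levels: int = 3) -> DiscreteMatrix:
    """Split each column at its empirical quantiles into equal-count bins.

    Cut values are the ``j/levels`` empirical quantiles; a value equal to a
    cut is assigned to the lower bin.  Constant columns collapse to a single
    level (all code 0) with a warning.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    n = data.shape[0]
    if levels > n:
        raise ValueError(f"levels={levels} exceeds sample count {n}")
    codes = np.empty(data.shape, dtype=np.int64)
    used_levels: list[int] = []
    boundaries: list[np.ndarray] = []
    for j, col in enumerate(data.columns):
        x = data[col].to_numpy(dtype=float)
        cuts = np.quantile(x, [q / levels for q in range(1, levels)])
        c = np.searchsorted(cuts, x, side="left")
        if np.all(x == x[0]):
            warnings.warn(f"constant column {col!r}; single level", stacklevel=2)
            codes[:, j] = 0
            used_levels.append(1)
            boundaries.append(np.array([]))
            continue
        codes[:, j] = c
        used_levels.append(levels)
        boundaries.append(cuts)
    return DiscreteMatrix(
        mirna_ids=list(data.columns),
        codes=codes,
        levels=used_levels,
        boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# DAGs


@dataclass
class DAGModel:
    """Directed acyclic graph over miRNA ids with an optional BDe score."""

    nodes: list[str]
    parents: dict[str, frozenset[str]] = field(default_factory=dict)
    score: float | None = None

    def __post_init__(self) -> None:
        self.parents = {n: frozenset(self.parents.get(n, ())) for n in self.nodes}
        unknown = {p for ps in self.parents.values() for p in ps} - set(self.nodes)
        if unknown:
            raise ValueError(f"parents reference unknown nodes {sorted(unknown)}")
        if self.topological_order() is None:
            raise ValueError("graph is cyclic")

    @classmethod
    def empty(cls, nodes) -> "DAGModel":
        return cls(nodes=list(nodes))

    def edges(self) -> set[tuple[str, str]]:
        return {(p, c) for c, ps in self.parents.items() for p in ps}

    def topological_order(self) -> list[str] | None:
        """Kahn's algorithm; None when a cycle exists."""
        indeg = {n: len(self.parents[n]) for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].append(child)
        queue = [n for n in self.nodes if indeg[n] == 0]
        order = []
        while queue:
            n = queue.pop()
            order.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return order if len(order) == len(self.nodes) else None

    def with_move(self, move: tuple[str, str, str]) -> "DAGModel":
        """Apply an ('add'|'del'|'rev', u, v) move; validity checked by ctor."""
        kind, u, v = move
        parents = dict(self.parents)
        if kind == "add":
            parents[v] = parents[v] | {u}
        elif kind == "del":
            parents[v] = parents[v] - {u}
        elif kind == "rev":
            parents[v] = parents[v] - {u}
            parents[u] = parents[u] | {v}
        else:
            raise ValueError(f"unknown move {kind!r}")
        return DAGModel(nodes=list(self.nodes), parents=parents, score=None)


def _reachable(parents: dict[str, frozenset[str]], src: str, dst: str) -> bool:
    """True when a directed path src -> ... -> dst exists."""
    children: dict[str, list[str]] = {n: [] for n in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
    stack, seen = [src], {src}
    while stack:
        n = stack.pop()
        if n == dst:
            return True
        for c in children[n]:
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def _move_is_legal(
    parents: dict[str, frozenset[str]], move: tuple[str, str, str], max_parents: int
) -> bool:
    kind, u, v = move
    if u == v:
        return False
    if kind == "add":
        if u in parents[v] or v in parents[u]:
            return False
        if len(parents[v]) >= max_parents:
            return False
        return not _reachable(parents, v, u)
    if kind == "del":
        return u in parents[v]
    if kind == "rev":
        if u not in parents[v]:
            return False
        if len(parents[u]) + 1 > max_parents:
            return False
        trimmed = dict(parents)
        trimmed[v] = parents[v] - {u}
        return not _reachable(trimmed, u, v)
    return False


def local_moves(dag: DAGModel, max_parents: int = 4) -> list[DAGModel]:
    """All DAGs one legal edge addition, deletion or reversal away."""
    out = []
    for u in dag.nodes:
        for v in dag.nodes:
            if u == v:
                continue
            if u in dag.parents[v]:
                kinds = ("del", "rev")
            elif v in dag.parents[u]:
                continue  # handled from the (v, u) ordering
            else:
                kinds = ("add",)
            for kind in kinds:
                move = (kind, u, v)
                if _move_is_legal(dag.parents, move, max_parents):
                    out.append(dag.with_move(move))
    return out


# ---------------------------------------------------------------------------
# BDe score


def family_score(
    data: DiscreteMatrix,
    node: str,
    parents: frozenset[str] | set[str],
    ess: float = 1.0,
) -> float:
    """BDe log marginal likelihood contribution of one (node, parents) family."""
    if ess <= 0:
        raise ValueError("ess must be positive")
    idx = {n: j for j, n in enumerate(data.mirna_ids)}
    i = idx[node]
    pidx = sorted(idx[p] for p in parents)
    r = data.levels[i]
    q = int(np.prod([data.levels[j] for j in pidx])) if pidx else 1
    a_jk = ess / (q * r)
    a_j = ess / q

    child = data.codes[:, i]
    if pidx:
        shape = [data.levels[j] for j in pidx]
        config = np.ravel_multi_index(
            tuple(data.codes[:, j] for j in pidx), dims=shape
        )
    else:
        config = np.zeros(data.n_samples, dtype=np.int64)
    joint = np.bincount(config * r + child, minlength=q * r).reshape(q, r)
    n_j = joint.sum(axis=1)
    observed = n_j > 0
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j[observed]))
        + np.sum(gammaln(a_jk + joint[observed]) - gammaln(a_jk))
    )
    # unobserved configurations contribute exactly 0
    return score


def bde_score(dag: DAGModel, data: DiscreteMatrix, ess: float = 1.0) -> float:
    """Total BDe log score: sum of per-family terms (decomposable)."""
    return sum(family_score(data, n, dag.parents[n], ess) for n in dag.nodes)


# ---------------------------------------------------------------------------
# simulated annealing


@dataclass(frozen=True)
class BayesConfig:
    levels: int = 3
    ess: float = 1.0
    max_parents: int = 4
    initial_temperature: float = 1.0
    cooling_factor: float = 0.999
    moves_per_temperature: int = 100
    max_iterations: int = 20_000
    n_best: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.n_best != 1:
            raise ValueError("only single-best tracking is implemented")


def anneal_search(data: DiscreteMatrix, config: BayesConfig | None = None) -> DAGModel:
    """Metropolis simulated annealing over DAG structures.

    Starts from the empty graph.  Each iteration proposes one uniformly drawn
    single-edge change (add / delete / reverse); proposals that would create
    a cycle or exceed the parent cap are discarded (a null iteration).  Score
    improvements are always accepted, deteriorations with Boltzmann
    probability ``exp(delta / T)`` under geometric cooling.  Returns the
    highest-scoring DAG ever visited, with its score; fully reproducible from
    the seed.

    Note: the source description of the acceptance rule ("higher score
    accepted with a probability") inverts the standard convention; standard
    Metropolis annealing is implemented.
    """
    config = config or BayesConfig()
    rng = np.random.default_rng(config.seed)
    nodes = list(data.mirna_ids)
    p = len(nodes)
    if p < 2:
        raise ValueError("need at least 2 variables")

    parents: dict[str, frozenset[str]] = {n: frozenset() for n in nodes}
    cache: dict[tuple[str, frozenset[str]], float] = {}

    def fam(node: str, ps: frozenset[str]) -> float:
        key = (node, ps)
        if key not in cache:
            cache[key] = family_score(data, node, ps, config.ess)
        return cache[key]

    score = sum(fam(n, parents[n]) for n in nodes)
    best_parents = dict(parents)
    best_score = score

    temperature = config.initial_temperature
    for it in range(config.max_iterations):
        if it and it % config.moves_per_temperature == 0:
            temperature *= config.cooling_factor
        # uniform over the 2*p*(p-1) (ordered pair, slot) cells; each legal
        # neighbor occupies exactly one cell, so accepted proposals are
        # uniform over the legal neighborhood
        u_i, v_i = divmod(int(rng.integers(p * (p - 1))), p - 1)
        v_i += v_i >= u_i
        u, v = nodes[u_i], nodes[v_i]
        slot = int(rng.integers(2))
        if u in parents[v]:
            kind = "del" if slot == 0 else "rev"
        elif v in parents[u]:
            continue
        else:
            if slot == 1:
                continue
            kind = "add"
        move = (kind, u, v)
        if not _move_is_legal(parents, move, config.max_parents):
            continue

        delta = 0.0
        if kind == "add":
            new_v = parents[v] | {u}
            delta = fam(v, new_v) - fam(v, parents[v])
        elif kind == "del":
            new_v = parents[v] - {u}
            delta = fam(v, new_v) - fam(v, parents[v])
        else:  # reversal touches both families
            new_v = parents[v] - {u}
            new_u = parents[u] | {v}
            delta = (
                fam(v, new_v)
                - fam(v, parents[v])
                + fam(u, new_u)
                - fam(u, parents[u])
            )
        accept = delta >= 0 or rng.random() < math.exp(
            max(delta / max(temperature, 1e-300), -745.0)
        )
        if not accept:
            continue
        parents[v] = new_v
        if kind == "rev":
            parents[u] = new_u
        score += delta
        if score > best_score:
            best_score = score
            best_parents = dict(parents)

    best = DAGModel(nodes=nodes, parents=best_parents, score=None)
    # recompute from the cache-backed families: guards against drift of the
    # incrementally updated running score
    best = replace(best, score=bde_score(best, data, config.ess))
    return best


def dag_to_network(dag: DAGModel):
    """Undirected skeleton; the learned direction is kept as an edge attribute."""
    g = new_network(dag.nodes, "bayes")
    for parent, child in sorted(dag.edges()):
        g.add_edge(parent, child, direction=f"{parent}->{child}")
    return g
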