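"""Differential connectivity between two miRNA networks.

Quantifies edge loss/gain between a condition pair (e.g. healthy control vs
sepsis): edge counts and percentage change, a Fisher exact test on edge
counts against the total number of possible pairs, a Yates-corrected
chi-square on total edge distances (cluster method), the kept / lost /
gained edge partition, and the two node groups of the sponging hypothesis:

* C group ("connected"): the largest node set pairwise connected in *both*
  conditions — the maximum clique of the intersection graph.
* S group ("sponged"): nodes well connected in the first condition that are
  completely isolated in the second.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from scipy import stats

from .network import canonical_edge, edge_set

__all__ = [
    "ComparisonReport",
    "pct_change",
    "edge_count_test",
    "distance_test",
    "edge_diff",
    "find_c_group",
    "find_s_group",
    "compare_networks",
]


def pct_change(e_a: int, e_b: int) -> tuple[float, str]:
    """Percentage change in edge count: ``100 |a-b| / max(a, b)``.

    The direction ("increase", "decrease" or "none") is returned separately.
    This denominator convention is the one consistent with all published
    percentage figures for these networks.
    """
    if e_a < 0 or e_b < 0:
        raise ValueError("edge counts must be non-negative")
    if e_a == e_b == 0:
        warnings.warn("both edge counts are zero", stacklevel=2)
        return 0.0, "none"
    value = 100.0 * abs(e_a - e_b) / max(e_a, e_b)
    if e_a == e_b:
        return 0.0, "none"
    return value, ("decrease" if e_b < e_a else "increase")


def edge_count_test(e_a: int, e_b: int, n_nodes: int) -> float:
    """Two-sided Fisher exact P for a difference in edge counts.

    The 2x2 table is ``[[e_a, M-e_a], [e_b, M-e_b]]`` with
    ``M = C(n_nodes, 2)`` possible edges; the two-sided P sums all
    hypergeometric tables with probability <= the observed one.
    """
    m = math.comb(n_nodes, 2)
    for e in (e_a, e_b):
        if not (0 <= e <= m):
            raise ValueError(f"edge count {e} exceeds C({n_nodes},2) = {m}")
    return float(stats.fisher_exact([[e_a, m - e_a], [e_b, m - e_b]])[1])


def distance_test(d_a: float, d_b: float) -> float:
    """Yates-corrected 1-df chi-square on two distance totals vs equality.

    The published analysis applies a count-based goodness-of-fit test to
    continuous distance totals; reproduced as stated, but it should be read
    as a descriptive index rather than a calibrated P-value.
    """
    if d_a < 0 or d_b < 0:
        raise ValueError("distances must be non-negative")
    if d_a == d_b == 0:
        raise ValueError("chi-square undefined when both totals are zero")
    expected = (d_a + d_b) / 2.0
    stat = sum((abs(d - expected) - 0.5) ** 2 / expected for d in (d_a, d_b))
    return float(stats.chi2.sf(stat, df=1))


def edge_diff(
    net_a: nx.Graph, net_b: nx.Graph
) -> tuple[set[tuple[str, str]], set[tuple[str, str]], set[tuple[str, str]]]:
    """(kept, lost, gained) canonical edge sets between condition A and B."""
    ea, eb = edge_set(net_a), edge_set(net_b)
    return ea & eb, ea - eb, eb - ea


def _max_clique(g: nx.Graph) -> set[str]:
    """Exact maximum clique; ties broken by lexicographically smallest set."""
    best: tuple[int, tuple[str, ...]] | None = None
    for clique in nx.find_cliques(g):
        key = (-len(clique), tuple(sorted(clique)))
        if best is None or key < best:
            best = key
    assert best is not None
    return set(best[1])


def find_c_group(net_a: nx.Graph, net_b: nx.Graph) -> set[str]:
    """Largest node set completely connected in both networks.

    Exact maximum clique of the intersection graph (feasible at these node
    counts).  When the intersection has no edges the result degenerates to a
    single node (flagged in :func:`compare_networks` reports).
    """
    kept, _, _ = edge_diff(net_a, net_b)
    inter = nx.Graph()
    inter.add_nodes_from(set(net_a.nodes()) | set(net_b.nodes()))
    inter.add_edges_from(kept)
    return _max_clique(inter)


def find_s_group(net_a: nx.Graph, net_b: nx.Graph, min_degree_a: int = 4) -> set[str]:
    """Nodes with degree >= ``min_degree_a`` in A that are isolated in B."""
    return {
        n
        for n in net_a.nodes()
        if net_a.degree(n) >= min_degree_a
        and (n not in net_b or net_b.degree(n) == 0)
    }


@dataclass
class ComparisonReport:
    """Full connectivity comparison of a network pair."""

    label_a: str
    label_b: str
    n_nodes: int
    edges_a: int
    edges_b: int
    pct_change: float
    direction: str
    fisher_p: float
    kept: set[tuple[str, str]] = field(default_factory=set)
    lost: set[tuple[str, str]] = field(default_factory=set)
    gained: set[tuple[str, str]] = field(default_factory=set)
    c_group: set[str] = field(default_factory=set)
    s_group: set[str] = field(default_factory=set)
    c_group_degenerate: bool = False
    total_distance_a: float | None = None
    total_distance_b: float | None = None
    distance_chi2_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n_nodes": self.n_nodes,
            "edges_a": self.edges_a,
            "edges_b": self.edges_b,
            "pct_change": self.pct_change,
            "direction": self.direction,
            "fisher_p": self.fisher_p,
            "kept": sorted(map(list, self.kept)),
            "lost": sorted(map(list, self.lost)),
            "gained": sorted(map(list, self.gained)),
            "c_group": sorted(self.c_group),
            "s_group": sorted(self.s_group),
            "c_group_degenerate": self.c_group_degenerate,
        }
        if self.total_distance_a is not None:
            d.update(
                total_distance_a=self.total_distance_a,
                total_distance_b=self.total_distance_b,
                distance_chi2_p=self.distance_chi2_p,
            )
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def compare_networks(
    net_a: nx.Graph,
    net_b: nx.Graph,
    label_a: str = "A",
    label_b: str = "B",
    min_degree_a: int = 4,
    n_nodes: int | None = None,
) -> ComparisonReport:
    """Build a :class:`ComparisonReport` for a pair of networks.

    ``n_nodes`` defaults to the union node count; pass an explicit value to
    reproduce published conventions (e.g. 15 nodes for the cluster networks).
    Distance statistics are filled in when both networks carry per-edge
    ``distance`` attributes (the cluster method).
    """
    nodes = set(net_a.nodes()) | set(net_b.nodes())
    n = n_nodes if n_nodes is not None else len(nodes)
    ea, eb = net_a.number_of_edges(), net_b.number_of_edges()
    pct, direction = pct_change(ea, eb)
    kept, lost, gained = edge_diff(net_a, net_b)
    c_group = find_c_group(net_a, net_b)
    report = ComparisonReport(
        label_a=label_a,
        label_b=label_b,
        n_nodes=n,
        edges_a=ea,
        edges_b=eb,
        pct_change=pct,
        direction=direction,
        fisher_p=edge_count_test(ea, eb, n),
        kept=kept,
        lost=lost,
        gained=gained,
        c_group=c_group,
        s_group=find_s_group(net_a, net_b, min_degree_a=min_degree_a),
        c_group_degenerate=len(kept) == 0,
    )

    def _has_distance(g: nx.Graph) -> bool:
        return g.number_of_edges() > 0 and all(
            "distance" in d for _, _, d in g.edges(data=True)
        )

    if _has_distance(net_a) and _has_distance(net_b):
        from .cluster import total_distance

        report.total_distance_a = total_distance(net_a)
        report.total_distance_b = total_distance(net_b)
        report.distance_chi2_p = distance_test(
            report.total_distance_a, report.total_distance_b
        )
    return report


def diff_graph(net_a: nx.Graph, net_b: nx.Graph) -> nx.Graph:
    """Union graph with a kept/lost/gained status attribute per edge."""
    kept, lost, gained = edge_diff(net_a, net_b)
    g = nx.Graph()
    g.add_nodes_from(set(net_a.nodes()) | set(net_b.nodes()))
    for status, edges in (("kept", kept), ("lost", lost), ("gained", gained)):
        for u, v in edges:
            g.add_edge(u, v, status=status)
    return g
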