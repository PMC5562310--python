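"""miRNA network container and serialization.

Networks are undirected :class:`networkx.Graph` objects whose nodes are miRNA
ids and whose edges carry optional attributes (``r`` for correlation networks,
``distance``/``strength_bin`` for cluster networks, ``direction`` for the
undirected skeleton of a learned DAG).  The construction method is stored in
``G.graph["method"]``.

Isolated nodes are significant here — the central observation of the analysis
is that nodes *lose* all their edges — so every writer preserves degree-0
nodes explicitly.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "canonical_edge",
    "new_network",
    "edge_set",
    "write_network_tsv",
    "read_network_tsv",
    "write_network_graphml",
    "read_network_graphml",
    "write_expression",
    "read_expression",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Unordered pair in lexicographic order."""
    if u == v:
        raise ValueError(f"self-loop {u!r}")
    return (u, v) if u <= v else (v, u)


def new_network(nodes, method: str) -> nx.Graph:
    if method not in ("correlation", "cluster", "bayes"):
        raise ValueError(f"unknown method label {method!r}")
    g = nx.Graph(method=method)
    g.add_nodes_from(nodes)
    return g


def edge_set(g: nx.Graph) -> set[tuple[str, str]]:
    """Edges as canonical (lexicographically ordered) pairs."""
    return {canonical_edge(u, v) for u, v in g.edges()}


def write_network_tsv(g: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV with an explicit node table.

    Two sections: ``#node`` lines enumerating every node (so isolated nodes
    survive the round trip), then one edge per line with attribute columns.
    """
    path = Path(path)
    attrs = sorted({k for _, _, d in g.edges(data=True) for k in d})
    with path.open("w") as fh:
        fh.write(f"#method\t{g.graph.get('method', '')}\n")
        for node in sorted(g.nodes()):
            fh.write(f"#node\t{node}\n")
        fh.write("\t".join(["node_a", "node_b", *attrs]) + "\n")
        for u, v in sorted(edge_set(g)):
            d = g.edges[u, v]
            row = [u, v] + [_fmt(d[k]) if k in d else "" for k in attrs]
            fh.write("\t".join(row) + "\n")


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.12g}"
    return str(value)


def _parse(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def read_network_tsv(path: str | Path) -> nx.Graph:
    path = Path(path)
    g = nx.Graph()
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#method\t"):
                g.graph["method"] = line.split("\t", 1)[1]
                continue
            if line.startswith("#node\t"):
                g.add_node(line.split("\t", 1)[1])
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["node_a", "node_b"]:
                    raise ValueError(f"{path}:{lineno}: malformed header {header}")
                continue
            u, v, *vals = fields
            attrs = {
                key: _parse(raw)
                for key, raw in zip(header[2:], vals)
                if raw != ""
            }
            g.add_edge(u, v, **attrs)
    return g


def write_network_graphml(g: nx.Graph, path: str | Path) -> None:
    # GraphML holds scalar attributes only; flatten e.g. bin-edge lists
    out = g.copy()
    for key, value in list(out.graph.items()):
        if isinstance(value, (list, tuple)):
            out.graph[key] = ",".join(str(v) for v in value)
    nx.write_graphml(out, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_expression(data: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Expression table: first column ``sample_id``, then one column per miRNA.

    Values are written with 12 significant digits so a write/read cycle is
    lossless at that precision.
    """
    data.to_csv(path, sep=sep, index_label="sample_id", float_format="%.12g")


def read_expression(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    data = pd.read_csv(path, sep=sep, index_col="sample_id")
    if data.isna().any().any():
        raise ValueError(f"{path}: missing values in expression table")
    if (data.values <= 0).any():
        raise ValueError(f"{path}: expression values must be strictly positive")
    return data
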