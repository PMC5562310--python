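"""Hierarchical-cluster network construction.

The miRNAs (not the subjects) are the clustered objects: each miRNA's profile
across subjects is a feature vector.  The agglomeration tree is cut into a
fixed number of clusters (default 4, the cut the source analysis settled on)
and every within-cluster pair becomes an edge.  Edge strength is the
cophenetic distance between the pair, binned into six strength groups.

Defaults mirror the SPSS hierarchical-cluster routine the analysis named:
between-groups (average) linkage on squared Euclidean distances.  Profiles
are z-scored per miRNA by default — the 16 miRNAs span seven orders of
magnitude of abundance, so unstandardized distances would be dominated by the
most abundant one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .network import new_network

__all__ = [
    "ClusterConfig",
    "Dendrogram",
    "hierarchical_cluster",
    "cut_to_clusters",
    "cluster_network",
    "total_distance",
    "default_bin_edges",
]

_METRICS = {
    "squared_euclidean": "sqeuclidean",
    "euclidean": "euclidean",
    "correlation_distance": "correlation",
}
_LINKAGES = {"average", "complete", "ward"}


@dataclass(frozen=True)
class ClusterConfig:
    n_clusters: int = 4
    metric: str = "squared_euclidean"
    linkage: str = "average"
    #: Five increasing cut points defining six strength bins on cophenetic
    #: distance; ``None`` derives them from the six-quantile points of the
    #: network's own edge distances (recorded on the graph for reproducibility).
    bin_edges: tuple[float, ...] | None = None
    standardize: bool = True
    #: Edge distances: cophenetic (tree merge height, default) or the raw
    #: pairwise dissimilarity between the two profiles.
    distance_source: str = "cophenetic"

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.distance_source not in ("cophenetic", "pairwise"):
            raise ValueError(f"unknown distance_source {self.distance_source!r}")
        if self.bin_edges is not None:
            edges = tuple(float(e) for e in self.bin_edges)
            if len(edges) != 5 or any(
                b <= a for a, b in zip(edges, edges[1:])
            ):
                raise ValueError("bin_edges must be 5 strictly increasing values")
            object.__setattr__(self, "bin_edges", edges)


@dataclass
class Dendrogram:
    """Agglomeration result: leaf ids plus the scipy linkage matrix."""

    leaf_ids: list[str]
    linkage_matrix: np.ndarray
    #: condensed raw pairwise dissimilarities, in pdist order over leaf_ids
    pairwise: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def cophenetic_matrix(self) -> pd.DataFrame:
        dm = squareform(hierarchy.cophenet(self.linkage_matrix))
        return pd.DataFrame(dm, index=self.leaf_ids, columns=self.leaf_ids)

    def pairwise_matrix(self) -> pd.DataFrame:
        dm = squareform(self.pairwise)
        return pd.DataFrame(dm, index=self.leaf_ids, columns=self.leaf_ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()


def _profiles(data: pd.DataFrame, config: ClusterConfig) -> np.ndarray:
    x = data.to_numpy(dtype=float).T  # miRNAs x samples
    if config.metric == "correlation_distance":
        flat = x.std(axis=1) == 0
        if flat.any():
            bad = [c for c, f in zip(data.columns, flat) if f]
            raise ValueError(
                f"correlation distance undefined for constant profile(s) {bad}"
            )
    if config.standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0  # constant profile -> centered zeros
        x = (x - mu) / sd
    return x


def hierarchical_cluster(data: pd.DataFrame, config: ClusterConfig | None = None) -> Dendrogram:
    """Agglomerate miRNA profiles under the configured metric and linkage."""
    config = config or ClusterConfig()
    if data.shape[1] < 2:
        raise ValueError("need at least 2 miRNAs to cluster")
    if data.shape[0] < 3:
        raise ValueError(f"need >= 3 samples, got {data.shape[0]}")
    x = _profiles(data, config)
    if config.linkage == "ward":
        d = pdist(x, metric="euclidean")
        z = hierarchy.linkage(d, method="ward")
    else:
        d = pdist(x, metric=_METRICS[config.metric])
        z = hierarchy.linkage(d, method=config.linkage)
    return Dendrogram(leaf_ids=list(data.columns), linkage_matrix=z, pairwise=d)


def cut_to_clusters(tree: Dendrogram, k: int) -> list[set[str]]:
    """Cut the tree into exactly ``k`` clusters (k=1: one cluster; k=n: singletons)."""
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(tree.linkage_matrix, n_clusters=k).ravel()
    clusters: dict[int, set[str]] = {}
    for leaf, lab in zip(tree.leaf_ids, labels):
        clusters.setdefault(int(lab), set()).add(leaf)
    return [clusters[lab] for lab in sorted(clusters)]


def default_bin_edges(distances) -> tuple[float, ...]:
    """Six-quantile cut points of a collection of edge distances."""
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise ValueError("no distances to derive bin edges from")
    qs = np.quantile(arr, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])
    if np.any(np.diff(qs) <= 0):
        # Heavily tied distances: fall back to evenly spaced cuts.
        lo, hi = arr.min(), arr.max()
        if hi <= lo:
            hi = lo + 1.0
        qs = np.linspace(lo, hi, 7)[1:-1]
    return tuple(float(q) for q in qs)


def strength_bin(distance: float, bin_edges: tuple[float, ...]) -> int:
    """1-based bin index; distances above the last edge fall in bin 6."""
    return int(np.searchsorted(np.asarray(bin_edges), distance, side="left")) + 1


def cluster_network(
    tree: Dendrogram,
    partition: list[set[str]],
    config: ClusterConfig | None = None,
):
    """Connect all within-cluster pairs; annotate distance and strength bin."""
    config = config or ClusterConfig()
    dm = (
        tree.cophenetic_matrix()
        if config.distance_source == "cophenetic"
        else tree.pairwise_matrix()
    )
    g = new_network(tree.leaf_ids, "cluster")
    pairs = [
        (min(a, b), max(a, b))
        for cluster in partition
        for a in cluster
        for b in cluster
        if a < b
    ]
    edges = config.bin_edges
    if edges is None:
        if pairs:
            edges = default_bin_edges([dm.loc[a, b] for a, b in pairs])
        else:
            edges = (1.0, 2.0, 3.0, 4.0, 5.0)
            warnings.warn("empty partition edges; using placeholder bin edges", stacklevel=2)
    g.graph["bin_edges"] = list(edges)
    for a, b in sorted(set(pairs)):
        d = float(dm.loc[a, b])
        g.add_edge(a, b, distance=d, strength_bin=strength_bin(d, edges))
    return g


def total_distance(net) -> float:
    """Sum of the edge distance attribute; the connectivity-strength scalar."""
    return float(sum(d["distance"] for _, _, d in net.edges(data=True)))
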