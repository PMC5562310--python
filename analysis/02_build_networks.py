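#!/usr/bin/env python
"""Build the miRNA networks for every group by all three methods.

Reads the synthetic expression tables written by 01_simulate_data.py and
constructs, per patient group, the correlation-threshold network (+0.8 on
log-scale Pearson), the 4-cluster hierarchical network with cophenetic edge
distances, and the Bayesian-network skeleton (quantile discretization, BDe
score, simulated-annealing search).  Writes edge lists (TSV + GraphML) and an
edge-count table under results/networks/.
"""

import sys
from pathlib import Path

import pandas as pd

from spongenet.bayes import BayesConfig, anneal_search, dag_to_network, quantile_discretize
from spongenet.cluster import ClusterConfig, cluster_network, cut_to_clusters, hierarchical_cluster
from spongenet.correlation import CorrelationConfig, correlation_network
from spongenet.network import read_expression, write_network_graphml, write_network_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20170818
GROUPS = ("control", "sepsis", "pre_surgery", "post_surgery")


def main() -> None:
    data_dir = ROOT / "data"
    out = ROOT / "networks"
    out.mkdir(parents=True, exist_ok=True)
    if not data_dir.exists():
        print("run analysis/01_simulate_data.py first", file=sys.stderr)
        return 1

    corr_cfg = CorrelationConfig(scale="log")
    clus_cfg = ClusterConfig()
    rows = []
    for group in GROUPS:
        data = read_expression(data_dir / f"expression_{group}.tsv")
        nets = {}
        nets["correlation"] = correlation_network(data, corr_cfg)
        tree = hierarchical_cluster(data, clus_cfg)
        nets["cluster"] = cluster_network(
            tree, cut_to_clusters(tree, clus_cfg.n_clusters), clus_cfg
        )
        disc = quantile_discretize(data, 3)
        nets["bayes"] = dag_to_network(
            anneal_search(disc, BayesConfig(seed=SEED, max_iterations=20_000))
        )
        for method, g in nets.items():
            write_network_tsv(g, out / f"net_{group}_{method}.tsv")
            write_network_graphml(g, out / f"net_{group}_{method}.graphml")
            isolated = sum(1 for n in g.nodes() if g.degree(n) == 0)
            rows.append(
                {
                    "group": group,
                    "method": method,
                    "edges": g.number_of_edges(),
                    "isolated_nodes": isolated,
                }
            )
            print(
                f"{group:13s} {method:11s} {g.number_of_edges():3d} edges, "
                f"{isolated} isolated nodes"
            )

    pd.DataFrame(rows).to_csv(out / "edge_counts.tsv", sep="\t", index=False)
    print(f"networks and edge_counts.tsv written to {out}")


if __name__ == "__main__":
    sys.exit(main())
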