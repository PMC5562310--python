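"""End-to-end pipeline: datasets -> networks -> comparison reports.

A :class:`RunConfig` names the datasets (either expression-table files or
synthetic-generator specs), the network construction methods to run, and the
condition pairs to compare.  :func:`run_pipeline` materializes every artifact
(expression tables, networks in edge-list TSV and GraphML, comparison JSONs)
plus a manifest from which the run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import BayesConfig, anneal_search, dag_to_network, quantile_discretize
from .cluster import ClusterConfig, cluster_network, cut_to_clusters, hierarchical_cluster
from .compare import compare_networks, diff_graph
from .correlation import CorrelationConfig, correlation_network
from .generate import (
    CorrelationStructure,
    S_GROUP,
    generate_expression,
    inject_sponge,
    study_structure,
)
from .network import (
    read_expression,
    write_expression,
    write_network_graphml,
    write_network_tsv,
)
from .profiles import GROUP_SIZES, table1_profiles

logger = logging.getLogger(__name__)

METHODS = ("correlation", "cluster", "bayes")


class ConfigError(ValueError):
    """Malformed run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class DatasetSpec:
    """One expression dataset: either a file or a generator recipe."""

    name: str
    path: str | None = None
    group: str | None = None
    n_samples: int | None = None
    latent_r: float = 0.95
    structure: str = "study"  # "study" | "identity"
    sponge_ids: tuple[str, ...] = ()
    sponge_residual: float = 0.1

    def __post_init__(self) -> None:
        if (self.path is None) == (self.group is None):
            raise ConfigError(
                f"dataset {self.name!r}: give exactly one of 'path' or 'group'"
            )


@dataclass
class RunConfig:
    datasets: list[DatasetSpec]
    methods: tuple[str, ...] = METHODS
    comparisons: tuple[tuple[str, str], ...] = ()
    out_dir: str = "results/run"
    seed: int = 0
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    s_group_min_degree: int = 4

    def __post_init__(self) -> None:
        if isinstance(self.methods, str):
            self.methods = (self.methods,) if self.methods != "all" else METHODS
        self.methods = tuple(self.methods)
        self.comparisons = tuple(tuple(pair) for pair in self.comparisons)
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}")
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate dataset names")
        for a, b in self.comparisons:
            if a not in names or b not in names:
                raise ConfigError(f"comparison ({a}, {b}) references unknown dataset")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            datasets = [DatasetSpec(**d) for d in raw["datasets"]]
            kwargs: dict = {"datasets": datasets}
            if "methods" in raw:
                kwargs["methods"] = raw["methods"]
            if "comparisons" in raw:
                kwargs["comparisons"] = tuple(tuple(p) for p in raw["comparisons"])
            for key in ("out_dir", "seed", "s_group_min_degree"):
                if key in raw:
                    kwargs[key] = raw[key]
            for key, ctor in (
                ("correlation", CorrelationConfig),
                ("cluster", ClusterConfig),
                ("bayes", BayesConfig),
            ):
                if key in raw:
                    kwargs[key] = ctor(**raw[key])
            return cls(**kwargs)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed config: {exc}") from exc


def _dataset_seed(base_seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{base_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_dataset(spec: DatasetSpec, seed: int) -> pd.DataFrame:
    if spec.path is not None:
        try:
            return read_expression(spec.path)
        except FileNotFoundError as exc:
            raise DataError(f"dataset {spec.name!r}: file not found: {spec.path}") from exc
        except ValueError as exc:
            raise DataError(f"dataset {spec.name!r}: {exc}") from exc
    profiles = table1_profiles()
    if spec.group not in profiles:
        raise ConfigError(f"dataset {spec.name!r}: unknown group {spec.group!r}")
    profile = profiles[spec.group]
    if spec.structure == "identity":
        corr = CorrelationStructure.identity(profile.mirna_ids)
    elif spec.structure == "study":
        corr = study_structure(profile.mirna_ids, r=spec.latent_r)
    else:
        raise ConfigError(f"dataset {spec.name!r}: unknown structure {spec.structure!r}")
    if spec.sponge_ids:
        corr = inject_sponge(corr, set(spec.sponge_ids), spec.sponge_residual)
    n = spec.n_samples or GROUP_SIZES[spec.group]
    return generate_expression(profile, corr, n, seed=_dataset_seed(seed, spec.name))


def build_network(
    data: pd.DataFrame, method: str, config: RunConfig
) -> nx.Graph:
    if method == "correlation":
        return correlation_network(data, config.correlation)
    if method == "cluster":
        tree = hierarchical_cluster(data, config.cluster)
        partition = cut_to_clusters(tree, config.cluster.n_clusters)
        return cluster_network(tree, partition, config.cluster)
    if method == "bayes":
        disc = quantile_discretize(data, config.bayes.levels)
        dag = anneal_search(disc, config.bayes)
        return dag_to_network(dag)
    raise ConfigError(f"unknown method {method!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every dataset x method, compare the requested pairs, write artifacts.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    datasets: dict[str, pd.DataFrame] = {}
    for spec in config.datasets:
        data = load_dataset(spec, config.seed)
        datasets[spec.name] = data
        write_expression(data, out / f"expression_{spec.name}.tsv")

    networks: dict[tuple[str, str], nx.Graph] = {}
    for name, data in datasets.items():
        for method in config.methods:
            logger.info("building %s network for %s", method, name)
            g = build_network(data, method, config)
            networks[(name, method)] = g
            write_network_tsv(g, out / f"net_{name}_{method}.tsv")
            write_network_graphml(g, out / f"net_{name}_{method}.graphml")

    reports = []
    for a, b in config.comparisons:
        for method in config.methods:
            report = compare_networks(
                networks[(a, method)],
                networks[(b, method)],
                label_a=a,
                label_b=b,
                min_degree_a=config.s_group_min_degree,
            )
            path = out / f"compare_{a}_vs_{b}_{method}.json"
            report.to_json(path)
            write_network_graphml(
                diff_graph(networks[(a, method)], networks[(b, method)]),
                out / f"diff_{a}_vs_{b}_{method}.graphml",
            )
            reports.append(
                {"pair": [a, b], "method": method, "report": report.to_dict()}
            )

    config_blob = json.dumps(_config_dict(config), sort_keys=True)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "datasets": {
            name: {"n_samples": int(df.shape[0]), "n_mirnas": int(df.shape[1])}
            for name, df in datasets.items()
        },
        "networks": {
            f"{name}/{method}": g.number_of_edges()
            for (name, method), g in networks.items()
        },
        "comparisons": reports,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    def plain(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, (list, tuple)):
            return [plain(x) for x in obj]
        return obj

    return plain(config)


def sepsis_study_config(
    out_dir: str,
    seed: int,
    methods: tuple[str, ...] = METHODS,
    latent_r: float = 0.95,
    sponge_residual: float = 0.1,
) -> RunConfig:
    """The default four-group synthetic emulation of the study design.

    Control and pre-surgery carry the connected latent structure; sepsis is
    the control structure with the S-group sponged; post-surgery stays
    connected (surgical trauma did not disconnect the published networks).
    """
    datasets = [
        DatasetSpec(name="control", group="control", latent_r=latent_r),
        DatasetSpec(
            name="sepsis",
            group="sepsis",
            latent_r=latent_r,
            sponge_ids=tuple(S_GROUP),
            sponge_residual=sponge_residual,
        ),
        DatasetSpec(name="pre_surgery", group="pre_surgery", latent_r=latent_r),
        DatasetSpec(name="post_surgery", group="post_surgery", latent_r=latent_r),
    ]
    return RunConfig(
        datasets=datasets,
        methods=methods,
        comparisons=(("control", "sepsis"), ("pre_surgery", "post_surgery")),
        out_dir=out_dir,
        seed=seed,
        correlation=CorrelationConfig(scale="log"),
    )
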