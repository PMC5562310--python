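"""Correlation-coefficient network construction.

Pairwise Pearson correlation is computed across subjects for every pair of
miRNAs and an edge is drawn wherever the correlation reaches the threshold
(default +0.8 — deliberately high so the network stays interpretable; typical
co-expression studies use 0.3-0.5).  By default only positive correlations
create edges, matching the "+" in the published threshold; an absolute-value
mode is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import new_network

__all__ = ["CorrelationConfig", "pearson_matrix", "threshold_network", "correlation_network"]


@dataclass(frozen=True)
class CorrelationConfig:
    threshold: float = 0.8
    mode: str = "positive_only"  # or "absolute"
    scale: str = "raw"  # or "log"

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.mode not in ("positive_only", "absolute"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scale not in ("raw", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")


def pearson_matrix(data: pd.DataFrame, scale: str = "raw") -> pd.DataFrame:
    """Symmetric matrix of pairwise Pearson r between miRNA columns.

    ``scale="log"`` correlates natural-log values (all entries must be
    positive).  Constant columns have no defined correlation; their entries
    are forced to 0 with a warning so degenerate inputs still yield a network.
    """
    if data.shape[0] < 3:
        raise ValueError(f"need >= 3 samples, got {data.shape[0]}")
    values = data.to_numpy(dtype=float)
    if scale == "log":
        if (values <= 0).any():
            raise ValueError("log scale requires strictly positive values")
        values = np.log(values)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")

    constant = values.std(axis=0) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    if constant.any():
        names = [c for c, flag in zip(data.columns, constant) if flag]
        warnings.warn(
            f"constant expression for {names}; correlations set to 0", stacklevel=2
        )
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)


def threshold_network(corr: pd.DataFrame, config: CorrelationConfig | None = None):
    """Edge wherever r meets the threshold; all nodes kept even if isolated.

    ``positive_only``: edge iff ``r >= threshold``.
    ``absolute``: edge iff ``|r| >= threshold``.
    Ties at exactly the threshold are included.
    """
    config = config or CorrelationConfig()
    nodes = list(corr.columns)
    g = new_network(nodes, "correlation")
    m = corr.to_numpy(dtype=float)
    for i, u in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            r = m[i, j]
            value = abs(r) if config.mode == "absolute" else r
            if value >= config.threshold:
                g.add_edge(u, nodes[j], r=float(r))
    return g


def correlation_network(data: pd.DataFrame, config: CorrelationConfig | None = None):
    """Convenience: Pearson matrix then thresholding."""
    config = config or CorrelationConfig()
    return threshold_network(pearson_matrix(data, scale=config.scale), config)
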