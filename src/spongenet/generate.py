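"""Synthetic expression-matrix generator.

Per-patient plasma miRNA measurements for the study groups are not publicly
deposited, so analyses are exercised on synthetic sample-level data whose
marginals match the published per-group (mean, sd) profiles and whose
inter-miRNA dependence is controllable.

The generator is a Gaussian copula with log-normal marginals: each miRNA's
published mean and sd are moment-matched to a log-normal (the published SDs
frequently exceed the means several-fold, which rules out a normal marginal on
a positive scale), and dependence is imposed on the latent Gaussian (log)
scale.  Pearson correlation measured on the raw ``2^-ΔCt`` scale is therefore
attenuated relative to the latent correlation; the log view recovers it
exactly.

``inject_sponge`` emulates the sponging hypothesis: a sponge transcript
sequesters a subset of miRNAs, destroying their statistical coupling to every
other miRNA.  It shrinks all latent correlations incident to the sponged set
toward zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import GroupProfile

__all__ = [
    "CorrelationStructure",
    "lognormal_params_from_moments",
    "generate_expression",
    "inject_sponge",
    "block_structure",
    "study_structure",
]

logger = logging.getLogger(__name__)

# Node groups observed in the differential network figure of the study:
# C = completely connected in both conditions, S = "sponged" (isolated in sepsis).
C_GROUP = ("miR-23", "miR-26a", "miR-26b", "miR-93", "miR-223", "miR-21")
S_GROUP = ("miR-182", "miR-146", "miR-155", "miR-16", "miR-29a")


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal ``(mu, sigma)`` whose distribution has the given mean and sd.

    Inverts ``mean = exp(mu + sigma^2/2)`` and
    ``sd^2 = mean^2 (exp(sigma^2) - 1)``:

    ``sigma^2 = ln(1 + sd^2/mean^2)``, ``mu = ln(mean) - sigma^2/2``.
    """
    if not (mean > 0):
        raise ValueError(f"mean must be > 0, got {mean}")
    if not (sd > 0):
        raise ValueError(f"sd must be > 0, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass
class CorrelationStructure:
    """Latent (log-scale) inter-miRNA correlation matrix.

    Symmetric with unit diagonal; repaired to the nearest positive
    semi-definite matrix by eigenvalue clipping when a perturbation (for
    example :func:`inject_sponge`) breaks definiteness.  Repairs are logged.
    """

    mirna_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.mirna_ids = list(self.mirna_ids)
        m = np.asarray(self.matrix, dtype=float)
        p = len(self.mirna_ids)
        if m.shape != (p, p):
            raise ValueError(f"matrix shape {m.shape} does not match {p} ids")
        if len(set(self.mirna_ids)) != p:
            raise ValueError("duplicate miRNA ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("diagonal must be exactly 1")
        if np.any(np.abs(m) > 1 + 1e-12):
            raise ValueError("entries must lie in [-1, 1]")
        self.matrix = m

    @classmethod
    def identity(cls, mirna_ids: list[str]) -> "CorrelationStructure":
        return cls(mirna_ids=list(mirna_ids), matrix=np.eye(len(mirna_ids)))

    def is_psd(self, tol: float = 1e-10) -> bool:
        return bool(np.linalg.eigvalsh(self.matrix).min() >= -tol)

    def psd_repaired(self) -> "CorrelationStructure":
        """Clip negative eigenvalues at 0 and renormalize the diagonal to 1."""
        vals, vecs = np.linalg.eigh(self.matrix)
        if vals.min() >= -1e-10:
            return self
        logger.warning(
            "correlation matrix not PSD (min eigenvalue %.3g); repairing by "
            "eigenvalue clipping",
            vals.min(),
        )
        repaired = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        repaired = (repaired + repaired.T) / 2.0
        np.fill_diagonal(repaired, 1.0)
        return CorrelationStructure(self.mirna_ids, repaired)


def block_structure(
    mirna_ids: list[str], blocks: list[list[str]], r: float
) -> CorrelationStructure:
    """Equicorrelated blocks at latent correlation ``r``; zero elsewhere."""
    corr = CorrelationStructure.identity(mirna_ids)
    idx = {m: i for i, m in enumerate(mirna_ids)}
    for block in blocks:
        unknown = set(block) - set(idx)
        if unknown:
            raise ValueError(f"unknown ids in block: {sorted(unknown)}")
        for i, a in enumerate(block):
            for b in block[i + 1 :]:
                corr.matrix[idx[a], idx[b]] = corr.matrix[idx[b], idx[a]] = r
    return corr.psd_repaired()


def study_structure(mirna_ids: list[str], r: float = 0.95) -> CorrelationStructure:
    """Latent structure emulating the healthy-control network.

    The C-group and S-group miRNAs form one equicorrelated block at ``r``
    (in controls the sponged group is connected both internally and to the
    connected group); the two viral miRNAs and the remaining nodes stay
    independent, matching their isolation in the published networks.
    """
    block = [m for m in mirna_ids if m in set(C_GROUP) | set(S_GROUP)]
    return block_structure(mirna_ids, [block], r)


def inject_sponge(
    corr: CorrelationStructure,
    sponged_ids: set[str] | list[str],
    residual_r: float,
) -> CorrelationStructure:
    """Decorrelate the sponged miRNAs from everything else.

    Every off-diagonal entry with at least one endpoint in ``sponged_ids`` is
    shrunk to ``sign(r) * min(|r|, residual_r)``; entries among non-sponged
    ids are untouched.  Idempotent.  The result is PSD-repaired if the edit
    breaks positive semi-definiteness.
    """
    if not (0 <= residual_r < 1):
        raise ValueError(f"residual_r must be in [0, 1), got {residual_r}")
    sponged = set(sponged_ids)
    unknown = sponged - set(corr.mirna_ids)
    if unknown:
        raise ValueError(f"unknown miRNA ids: {sorted(unknown)}")
    if not sponged:
        return corr
    m = corr.matrix.copy()
    p = len(corr.mirna_ids)
    mask = np.array([mid in sponged for mid in corr.mirna_ids])
    touched = (mask[:, None] | mask[None, :]) & ~np.eye(p, dtype=bool)
    if touched.any():
        affected = np.abs(m[touched])
        nonzero = affected[affected > 0]
        if nonzero.size and residual_r >= nonzero.min():
            warnings.warn(
                "residual_r >= smallest affected |r|; some entries unchanged",
                stacklevel=2,
            )
    m[touched] = np.sign(m[touched]) * np.minimum(np.abs(m[touched]), residual_r)
    return CorrelationStructure(corr.mirna_ids, m).psd_repaired()


def generate_expression(
    profile: GroupProfile,
    corr: CorrelationStructure,
    n_samples: int,
    seed: int,
) -> pd.DataFrame:
    """Draw a samples x miRNAs expression matrix (``2^-ΔCt`` scale).

    Gaussian copula: latent ``z ~ N(0, corr)``, observed value for miRNA *j*
    is ``exp(mu_j + sigma_j z_j)`` with ``(mu_j, sigma_j)`` moment-matched to
    the profile.  Deterministic for fixed arguments and seed.

    Returns a :class:`pandas.DataFrame` with sample ids ``s000, s001, ...`` as
    index and miRNA ids as columns; all values strictly positive.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for downstream correlation")
    if list(corr.mirna_ids) != list(profile.mirna_ids):
        raise ValueError(
            "correlation structure ids do not match profile ids "
            f"({corr.mirna_ids[:3]}... vs {profile.mirna_ids[:3]}...)"
        )
    params = [lognormal_params_from_moments(mu, sd) for _, mu, sd in profile.entries]
    mus = np.array([p[0] for p in params])
    sigmas = np.array([p[1] for p in params])

    repaired = corr.psd_repaired()
    try:
        factor = np.linalg.cholesky(repaired.matrix)
    except np.linalg.LinAlgError:
        # Singular after repair: use an eigen factor instead.
        vals, vecs = np.linalg.eigh(repaired.matrix)
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, len(mus))) @ factor.T
    values = np.exp(mus + sigmas * z)
    width = max(3, len(str(n_samples - 1)))
    sample_ids = [f"s{i:0{width}d}" for i in range(n_samples)]
    return pd.DataFrame(values, index=sample_ids, columns=list(profile.mirna_ids))
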