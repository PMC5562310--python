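"""Per-group miRNA abundance profiles.

A :class:`GroupProfile` holds, for one patient group, the per-miRNA mean and
standard deviation of the normalized plasma abundance (``2^-ΔCt`` scale,
qRT-PCR normalized against a cel-miR-39-3p spike-in).  The packaged fixture
covers the 16 circulating miRNAs (14 cellular + 2 KSHV viral) measured in the
four study groups: septic patients (n=99), healthy controls (n=53),
pre-surgery (n=19) and post-surgery (n=11).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = ["GROUP_LABELS", "GROUP_SIZES", "GroupProfile", "table1_profiles"]

GROUP_LABELS = ("sepsis", "control", "pre_surgery", "post_surgery")

#: Number of subjects sampled per group in the source cohorts.
GROUP_SIZES = {"sepsis": 99, "control": 53, "pre_surgery": 19, "post_surgery": 11}


@dataclass(frozen=True)
class GroupProfile:
    """Marginal (mean, sd) targets for every miRNA of one patient group.

    Parameters
    ----------
    group_label :
        One of ``sepsis``, ``control``, ``pre_surgery``, ``post_surgery``.
    entries :
        ``(mirna_id, mean, sd)`` triples; means and sds are strictly positive
        values on the ``2^-ΔCt`` scale.
    """

    group_label: str
    entries: tuple[tuple[str, float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        ids = [m for m, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in profile")
        for mirna, mean, sd in self.entries:
            if not mean > 0:
                raise ValueError(f"{mirna}: mean must be > 0, got {mean}")
            if not sd > 0:
                raise ValueError(f"{mirna}: sd must be > 0, got {sd}")

    @property
    def mirna_ids(self) -> list[str]:
        return [m for m, _, _ in self.entries]

    def mean(self, mirna_id: str) -> float:
        return dict((m, mu) for m, mu, _ in self.entries)[mirna_id]

    def sd(self, mirna_id: str) -> float:
        return dict((m, s) for m, _, s in self.entries)[mirna_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["mirna", "mean", "sd"]).set_index(
            "mirna"
        )


def table1_profiles() -> dict[str, GroupProfile]:
    """Load the packaged 16-miRNA x 4-group profile table.

    Returns a mapping from group label to :class:`GroupProfile`.  Values are
    the published group means and standard deviations with the source's
    decimal commas normalized to decimal points.
    """
    ref = resources.files("spongenet").joinpath("data/table1_profiles.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    profiles: dict[str, GroupProfile] = {}
    for label, sub in table.groupby("group", sort=False):
        entries = tuple(
            (str(r.mirna), float(r.mean), float(r.sd)) for r in sub.itertuples()
        )
        if len(entries) != 16:
            raise ValueError(f"fixture for {label} has {len(entries)} entries")
        profiles[label] = GroupProfile(group_label=str(label), entries=entries)
    missing = set(GROUP_LABELS) - set(profiles)
    if missing:
        raise ValueError(f"fixture missing groups: {sorted(missing)}")
    return profiles
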