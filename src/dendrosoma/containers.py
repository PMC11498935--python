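"""Shared in-memory containers for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SITE_KEY = ["contig", "pos", "ref", "alt"]


@dataclass
class MutationMatrix:
    """Somatic SNV sites x samples presence/absence with zygosity.

    ``presence`` is a boolean frame indexed by (contig, pos, ref, alt) with
    one column per branch-tip sample; the base sample defines the reference
    genotype and therefore has no column. A homozygous call counts as a
    single mutation event, recorded in ``genotypes`` (``het``/``hom``).
    """

    presence: pd.DataFrame
    genotypes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.presence.index, pd.MultiIndex):
            raise ValueError("presence must be indexed by (contig, pos, ref, alt)")
        self.presence = self.presence.astype(bool).sort_index()
        if self.genotypes is None:
            self.genotypes = pd.Series("het", index=self.presence.index)
        else:
            self.genotypes = self.genotypes.reindex(self.presence.index).fillna("het")

    @property
    def tips(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_sites(self) -> int:
        return len(self.presence)

    def per_tip_counts(self) -> pd.Series:
        """Mutations carried by each tip (distance from the base genotype)."""
        return self.presence.sum(axis=0)

    def equals(self, other: "MutationMatrix") -> bool:
        return self.presence.equals(other.presence.reindex(columns=self.tips))

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        df = self.presence.astype(int).copy()
        df["genotype"] = self.genotypes
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=[0, 1, 2, 3])
        geno = df.pop("genotype") if "genotype" in df.columns else None
        return cls(presence=df.astype(bool), genotypes=geno)

    @classmethod
    def empty(cls, tips: list[str]) -> "MutationMatrix":
        idx = pd.MultiIndex.from_arrays([[], [], [], []], names=SITE_KEY)
        return cls(presence=pd.DataFrame(False, index=idx, columns=tips))
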