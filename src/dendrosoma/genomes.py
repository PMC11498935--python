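"""Annotated genomes: sequence container, CDS bookkeeping, and interval logic.

A genome here is a single contig of A/C/G/T with single-exon protein-coding
genes (one CDS per gene, start codon through stop codon, on either strand).
Intergenic space is defined the way neutral-background analyses of plant
genomes usually define it: everything outside the union of gene bodies
extended 1 kb past the 5' end of the start codon and 500 bp past the 3' end
of the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENE_COLUMNS = ["gene_id", "start", "end", "strand"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase, N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotatedGenome:
    """A contig plus its gene annotation.

    Parameters
    ----------
    name
        Contig identifier used in FASTA/GFF3/VCF output.
    seq
        Uppercase genome sequence.
    genes
        One row per gene: ``gene_id``, ``start``, ``end`` (1-based inclusive
        CDS span on the contig) and ``strand`` (``+``/``-``).
    """

    name: str
    seq: str
    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS)
    )

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        missing = set(GENE_COLUMNS) - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table lacks columns {sorted(missing)}")
        self._coding_index: dict[int, tuple[int, int]] | None = None

    def __len__(self) -> int:
        return len(self.seq)

    # ------------------------------------------------------------------ CDS
    def cds_sequence(self, gene_id: str) -> str:
        """Sense-strand CDS (begins ATG, ends in a stop codon)."""
        row = self.genes.loc[self.genes.gene_id == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        start, end, strand = int(row.start.iloc[0]), int(row.end.iloc[0]), row.strand.iloc[0]
        s = self.seq[start - 1 : end]
        return revcomp(s) if strand == "-" else s

    def coding_index(self) -> dict[int, tuple[int, int]]:
        """Map genomic position (1-based) -> (gene row index, CDS offset).

        Offsets count along the sense strand, 0-based, so ``offset // 3``
        is the codon number and ``offset % 3`` the position within it.
        Later genes win where annotations overlap (they do not, by
        construction, in simulated genomes).
        """
        if self._coding_index is None:
            idx: dict[int, tuple[int, int]] = {}
            for i, row in self.genes.iterrows():
                start, end = int(row.start), int(row.end)
                if row.strand == "+":
                    for pos in range(start, end + 1):
                        idx[pos] = (i, pos - start)
                else:
                    for pos in range(start, end + 1):
                        idx[pos] = (i, end - pos)
            self._coding_index = idx
        return self._coding_index

    # ------------------------------------------------------------ intervals
    def intergenic_intervals(
        self, upstream: int = 1000, downstream: int = 500
    ) -> list[tuple[int, int]]:
        """Complement of gene bodies extended by flanks (strand-aware)."""
        return define_intergenic(
            self.genes, len(self.seq), upstream=upstream, downstream=downstream
        )

    # ----------------------------------------------------------------- I/O
    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.seq), width):
                fh.write(self.seq[i : i + width] + "\n")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.name} 1 {len(self.seq)}\n")
            for _, row in self.genes.iterrows():
                attrs_gene = f"ID={row.gene_id}"
                fh.write(
                    f"{self.name}\tdendrosoma\tgene\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t.\t{attrs_gene}\n"
                )
                fh.write(
                    f"{self.name}\tdendrosoma\tCDS\t{row.start}\t{row.end}\t.\t"
                    f"{row.strand}\t0\tID={row.gene_id}.cds;Parent={row.gene_id}\n"
                )

    @classmethod
    def from_files(cls, fasta: str | Path, gff3: str | Path | None = None) -> "AnnotatedGenome":
        from Bio import SeqIO

        record = next(SeqIO.parse(str(fasta), "fasta"))
        genes: list[dict] = []
        if gff3 is not None:
            with open(gff3) as fh:
                for line in fh:
                    if line.startswith("#"):
                        continue
                    f = line.rstrip("\n").split("\t")
                    if len(f) < 9 or f[2] != "CDS":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                    )
                    gene_id = attrs.get("Parent") or attrs.get("ID", f"gene{len(genes)}")
                    genes.append(
                        {
                            "gene_id": gene_id,
                            "start": int(f[3]),
                            "end": int(f[4]),
                            "strand": f[6],
                        }
                    )
        return cls(
            name=record.id,
            seq=str(record.seq).upper(),
            genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        )


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def define_intergenic(
    genes: pd.DataFrame,
    genome_length: int,
    upstream: int = 1000,
    downstream: int = 500,
) -> list[tuple[int, int]]:
    """Intergenic intervals: complement of flank-extended gene bodies.

    ``upstream`` extends past the start codon (5' of the gene, so to lower
    coordinates for ``+`` genes and higher coordinates for ``-`` genes);
    ``downstream`` extends past the stop codon. Intervals are clipped to
    ``[1, genome_length]`` and overlapping extensions are unioned before
    taking the complement.
    """
    extended = []
    for _, row in genes.iterrows():
        if row.strand == "+":
            lo, hi = row.start - upstream, row.end + downstream
        else:
            lo, hi = row.start - downstream, row.end + upstream
        extended.append((max(1, int(lo)), min(genome_length, int(hi))))
    merged = merge_intervals(extended)
    out: list[tuple[int, int]] = []
    cursor = 1
    for s, e in merged:
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= genome_length:
        out.append((cursor, genome_length))
    return out


def positions_in_intervals(
    positions: np.ndarray, intervals: list[tuple[int, int]]
) -> np.ndarray:
    """Boolean mask of which 1-based positions fall inside the intervals."""
    positions = np.asarray(positions)
    mask = np.zeros(positions.shape, dtype=bool)
    for s, e in intervals:
        mask |= (positions >= s) & (positions <= e)
    return mask


def interval_base_counts(seq: str, intervals: list[tuple[int, int]]) -> dict[str, int]:
    """Counts of A/C/G/T within the given 1-based inclusive intervals."""
    counts = {b: 0 for b in BASES}
    for s, e in intervals:
        chunk = seq[s - 1 : e]
        for b in BASES:
            counts[b] += chunk.count(b)
    return counts
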