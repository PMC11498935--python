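"""96-context mutational spectra, CpG enrichment, and signature comparison.

Substitutions are classified by the mutated base and its immediate 5' and
3' neighbours. Collapsing strands onto the pyrimidine (C or T at the
centre) leaves six substitution classes x 16 flank combinations = 96
classes, ordered as in the COSMIC SBS catalogues. Spectra can be
normalised by the genome's triplet content (opportunity) or reported as
raw class fractions; COSMIC signatures are defined on raw fractions of the
human genome, so the raw mode is the like-for-like one for cosine
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomes import AnnotatedGenome, revcomp

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CLASSES_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
PYRIMIDINE_TRIPLETS = tuple(
    f"{five}{center}{three}" for center in "CT" for five in "ACGT" for three in "ACGT"
)
_PURINES = {"A", "G"}
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class ContextUnavailable(ValueError):
    """Raised when a site lacks a 5' or 3' flanking base."""


def collapse_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-collapsed substitution class, e.g. G>A -> C>T."""
    if ref == alt or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    if ref in _PURINES:
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{ref}>{alt}"


def classify_context(genome: AnnotatedGenome, pos: int, ref: str, alt: str) -> str:
    """96-class label for a substitution at a 1-based genome position.

    If the reference base is a purine, the triplet and the substitution are
    reverse-complemented before labelling, so both strands of a mutation
    map to the same class.
    """
    seq = genome.seq
    if seq[pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at {pos}: genome has {seq[pos - 1]}, record says {ref}"
        )
    if pos < 2 or pos >= len(seq):
        raise ContextUnavailable(f"position {pos} lacks a flanking base")
    five, three = seq[pos - 2], seq[pos]
    if "N" in (five, three):
        raise ContextUnavailable(f"N in flanking context at {pos}")
    if ref in _PURINES:
        five, ref, three = revcomp(three), revcomp(ref), revcomp(five)
        alt = revcomp(alt)
    return f"{five}[{ref}>{alt}]{three}"


def genome_triplet_counts(seq: str) -> dict[str, int]:
    """Pyrimidine-centred triplet content of a sequence.

    Overlapping windows of width three; windows containing N are skipped;
    purine-centred windows are credited to their reverse complement.
    """
    codes = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    valid = (a >= 0) & (b >= 0) & (c >= 0)
    # purine centre -> reverse complement: complement code is 3 - code
    flip = valid & ((b == 0) | (b == 2))
    a2 = np.where(flip, 3 - c, a)
    b2 = np.where(flip, 3 - b, b)
    c2 = np.where(flip, 3 - a, c)
    idx = a2 * 16 + b2 * 4 + c2
    counts = np.bincount(idx[valid], minlength=64)
    out: dict[str, int] = {}
    for t in PYRIMIDINE_TRIPLETS:
        i = _BASE_CODE[t[0]] * 16 + _BASE_CODE[t[1]] * 4 + _BASE_CODE[t[2]]
        if counts[i]:
            out[t] = int(counts[i])
    return out


@dataclass
class SpectrumVector:
    """96-class substitution spectrum (fractions summing to one)."""

    values: pd.Series
    raw_counts: pd.Series
    opportunity: pd.Series
    normalization: str = "opportunity"
    excluded_sites: int = 0

    def __post_init__(self) -> None:
        for name in ("values", "raw_counts"):
            s = getattr(self, name)
            if list(s.index) != list(CLASSES_96):
                raise ValueError(f"{name} must be indexed by the 96 classes in order")
        total = float(self.values.sum())
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"spectrum sums to {total}, expected 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.values,
                "count": self.raw_counts,
                "opportunity": self.opportunity.reindex(self.values.index),
            }
        )


def _class_opportunity() -> pd.Series:
    return pd.Series(
        {c: f"{c[0]}{c[2]}{c[6]}" for c in CLASSES_96}, name="triplet"
    )


def spectrum(
    snvs: pd.DataFrame,
    genome: AnnotatedGenome,
    normalize: str = "opportunity",
) -> SpectrumVector:
    """Build the 96-class spectrum of a set of SNVs.

    ``snvs`` needs columns contig/pos/ref/alt. With
    ``normalize='opportunity'`` each class count is divided by the genome
    count of its reference triplet and the result renormalised to sum to
    one; ``normalize='raw'`` reports plain class fractions. Sites at
    contig edges or flanked by N are excluded and tallied in
    ``excluded_sites``.
    """
    counts = pd.Series(0, index=list(CLASSES_96), dtype=int)
    excluded = 0
    for pos, ref, alt in zip(snvs["pos"], snvs["ref"], snvs["alt"]):
        try:
            counts[classify_context(genome, int(pos), ref, alt)] += 1
        except ContextUnavailable:
            excluded += 1
    if counts.sum() == 0:
        raise ValueError("no classifiable SNVs")
    triplet_counts = genome_triplet_counts(genome.seq)
    opp = _class_opportunity().map(lambda t: triplet_counts.get(t, 0)).astype(float)
    if normalize == "opportunity":
        if ((opp == 0) & (counts > 0)).any():
            raise ValueError("nonzero count in a class with zero genome opportunity")
        weighted = counts / opp.replace(0, np.nan)
        weighted = weighted.fillna(0.0)
        values = weighted / weighted.sum()
    elif normalize == "raw":
        values = counts / counts.sum()
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return SpectrumVector(
        values=values.astype(float),
        raw_counts=counts,
        opportunity=opp,
        normalization=normalize,
        excluded_sites=excluded,
    )


def cpg_enrichment(snvs: pd.DataFrame, genome: AnnotatedGenome) -> float:
    """Fold-excess of mutations at CpG sites over the genomic CpG fraction.

    Numerator: fraction of SNVs whose mutated base is the C of a CpG on
    either strand (ref C followed by G, or ref G preceded by C).
    Denominator: fraction of genome positions in CpG context (both the C
    and the G of each CpG dinucleotide).
    """
    seq = genome.seq
    n = len(snvs)
    if n == 0:
        raise ValueError("no SNVs supplied")
    hits = 0
    for pos, ref in zip(snvs["pos"], snvs["ref"]):
        pos = int(pos)
        if ref == "C" and pos < len(seq) and seq[pos] == "G":
            hits += 1
        elif ref == "G" and pos >= 2 and seq[pos - 2] == "C":
            hits += 1
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    n_cpg_positions = 2 * int(cg.sum())
    if n_cpg_positions == 0:
        raise ValueError("genome contains no CpG dinucleotides")
    genome_fraction = n_cpg_positions / len(seq)
    return (hits / n) / genome_fraction


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two nonnegative spectrum vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def spectrum_difference(a: SpectrumVector, b: SpectrumVector) -> pd.Series:
    """Signed per-class difference a - b (sums to zero for normalised inputs)."""
    if list(a.values.index) != list(b.values.index):
        raise ValueError("class order mismatch between spectra")
    return a.values - b.values


def load_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a 96 x S signature matrix (TSV, row labels in COSMIC order)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CLASSES_96):
        raise ValueError("signature matrix rows must be the 96 classes in COSMIC order")
    if (df.to_numpy() < 0).any():
        raise ValueError("signature matrix must be nonnegative")
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    return df


def signature_similarities(spec: SpectrumVector, signatures: pd.DataFrame) -> pd.Series:
    """Cosine similarity of a spectrum against each signature column."""
    return pd.Series(
        {
            name: cosine_similarity(spec.values.to_numpy(), col.to_numpy())
            for name, col in signatures.items()
        }
    )
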