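"""Codon-opportunity neutrality test for somatic and fixed SNVs.

For a CDS set of total length L_cds there are 3*L_cds possible single-base
mutations. Each is classified by the codon table as synonymous, missense
or nonsense, and binned by its pyrimidine-collapsed substitution class.
Weighting the opportunity counts by per-class background mutation rates
(observed in intergenic space, assumed nearly neutral) gives expected
synonymous and non-synonymous totals (lambda_S, lambda_N) and the expected
non-synonymous fraction

    p_N = lambda_N / (lambda_S + lambda_N)

against which the observed non-synonymous fraction is tested with an exact
two-sided binomial test.

Classification notes: mutations inside the annotated terminal stop codon
are enumerated too; stop-to-stop changes are synonymous and stop-to-sense
(read-through) changes are grouped with missense, so the 3*L_cds identity
holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .genomes import (
    AnnotatedGenome,
    STOP_CODONS,
    define_intergenic,
    interval_base_counts,
    positions_in_intervals,
    revcomp,
)
from .spectrum import SUBSTITUTIONS, collapse_substitution

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
MUTATION_TYPES = ("synonymous", "missense", "nonsense")

# reference-base eligibility per collapsed class: C>* classes can occur at
# C:G base pairs, T>* classes at T:A base pairs
CLASS_REF_BASES = {
    "C>A": "CG", "C>G": "CG", "C>T": "CG",
    "T>A": "TA", "T>C": "TA", "T>G": "TA",
}


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for a stop."""
    return "*" if codon in STOP_CODONS else _STANDARD.forward_table[codon]


def classify_codon_change(codon: str, offset: int, alt_base: str) -> str:
    """synonymous/missense/nonsense for one base change within a codon.

    Stop-gained is nonsense; stop-to-stop synonymous; stop-lost grouped
    with missense (a protein-altering, non-truncating change).
    """
    new = codon[:offset] + alt_base + codon[offset + 1 :]
    old_aa, new_aa = translate_codon(codon), translate_codon(new)
    if old_aa == new_aa:
        return "synonymous"
    if new_aa == "*":
        return "nonsense"
    return "missense"


@dataclass
class OpportunityTable:
    """Possible CDS mutations by substitution class and consequence."""

    counts: pd.DataFrame  # 6 classes x 3 types
    l_cds: int
    n_excluded_cds: int = 0

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(
            index=list(SUBSTITUTIONS), columns=list(MUTATION_TYPES)
        ).fillna(0).astype(int)
        total = int(self.counts.to_numpy().sum())
        if total != 3 * self.l_cds:
            raise ValueError(
                f"opportunity total {total} != 3*L_cds = {3 * self.l_cds}"
            )


@dataclass
class BackgroundRates:
    """Per-class substitution rates per eligible site, with provenance."""

    rates: pd.Series  # indexed by the six collapsed classes
    source: str = "intergenic"
    eligible_bases: pd.Series | None = None

    def __post_init__(self) -> None:
        self.rates = self.rates.reindex(list(SUBSTITUTIONS)).fillna(0.0)
        if (self.rates < 0).any():
            raise ValueError("negative background rate")


@dataclass
class SelectionTestResult:
    lambda_s: float
    lambda_n: float
    p_n: float
    observed_nonsyn: int
    observed_total: int
    p_value: float
    reject_at_5pct: bool


def is_valid_orf(cds: str) -> bool:
    if len(cds) % 3 or len(cds) < 6 or not cds.startswith("ATG"):
        return False
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    return codons[-1] in STOP_CODONS and not any(c in STOP_CODONS for c in codons[:-1])


def enumerate_opportunities(genome: AnnotatedGenome) -> OpportunityTable:
    """Count every possible CDS mutation by class and consequence.

    CDSs that are not clean ORFs (internal stop, length not a multiple of
    three) are excluded and tallied. The substitution class is taken on
    the sense strand and pyrimidine-collapsed, so it matches the class of
    the genomic substitution regardless of gene strand.
    """
    counts = pd.DataFrame(0, index=list(SUBSTITUTIONS), columns=list(MUTATION_TYPES))
    l_cds = 0
    excluded = 0
    for gene_id in genome.genes.gene_id:
        cds = genome.cds_sequence(gene_id)
        if not is_valid_orf(cds):
            excluded += 1
            continue
        l_cds += len(cds)
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            for offset in range(3):
                ref = codon[offset]
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    cls = collapse_substitution(ref, alt)
                    kind = classify_codon_change(codon, offset, alt)
                    counts.loc[cls, kind] += 1
    return OpportunityTable(counts=counts, l_cds=l_cds, n_excluded_cds=excluded)


def background_rates(
    snvs: pd.DataFrame,
    intervals: list[tuple[int, int]],
    genome: AnnotatedGenome,
    source: str = "intergenic",
) -> BackgroundRates:
    """Observed per-class mutation rates inside the given regions.

    rate[class] = (#SNVs of that class in the regions) / (#region bases at
    which the class can occur: C:G bases for C>* classes, T:A bases for
    T>* classes).
    """
    if not intervals:
        raise ValueError("empty region set")
    base_counts = interval_base_counts(genome.seq, intervals)
    eligible = pd.Series(
        {
            cls: sum(base_counts[b] for b in CLASS_REF_BASES[cls])
            for cls in SUBSTITUTIONS
        },
        dtype=float,
    )
    if len(snvs):
        inside = positions_in_intervals(snvs["pos"].to_numpy(), intervals)
        sub = snvs.loc[inside]
        observed = (
            pd.Series(
                [collapse_substitution(r, a) for r, a in zip(sub["ref"], sub["alt"])]
            ).value_counts()
            if len(sub)
            else pd.Series(dtype=int)
        )
    else:
        observed = pd.Series(dtype=int)
    observed = observed.reindex(list(SUBSTITUTIONS)).fillna(0)
    if ((eligible == 0) & (observed > 0)).any():
        raise ValueError("observed SNVs in a class with no eligible bases")
    rates = (observed / eligible.replace(0, np.nan)).fillna(0.0)
    return BackgroundRates(rates=rates, source=source, eligible_bases=eligible)


def expected_rates(
    table: OpportunityTable, rates: BackgroundRates
) -> tuple[float, float, float]:
    """lambda_S, lambda_N and the expected non-synonymous fraction p_N."""
    r = rates.rates
    lam_s = float((r * table.counts["synonymous"]).sum())
    lam_n = float(
        (r * (table.counts["missense"] + table.counts["nonsense"])).sum()
    )
    if lam_s + lam_n == 0:
        raise ValueError("expected mutation counts are zero; cannot form p_N")
    return lam_s, lam_n, lam_n / (lam_s + lam_n)


def binomial_selection_test(
    observed_nonsyn: int, observed_total: int, p_n: float
) -> SelectionTestResult:
    """Exact two-sided binomial test of the observed non-synonymous count.

    Two-sided p-value by the minimum-likelihood convention (sum of outcome
    probabilities no greater than the observed outcome's), the standard
    exact-test behaviour.
    """
    if observed_total <= 0:
        raise ValueError("no observed mutations to test")
    if not 0 <= observed_nonsyn <= observed_total:
        raise ValueError("observed non-synonymous count out of range")
    if not 0 < p_n < 1:
        raise ValueError("p_N must be strictly between 0 and 1")
    res = stats.binomtest(observed_nonsyn, observed_total, p_n, alternative="two-sided")
    lam_placeholder = np.nan
    return SelectionTestResult(
        lambda_s=lam_placeholder,
        lambda_n=lam_placeholder,
        p_n=p_n,
        observed_nonsyn=observed_nonsyn,
        observed_total=observed_total,
        p_value=float(res.pvalue),
        reject_at_5pct=bool(res.pvalue < 0.05),
    )


def classify_site_effect(genome: AnnotatedGenome, pos: int, alt: str) -> str:
    """Coding consequence of a genomic substitution: synonymous, missense,
    nonsense, or noncoding."""
    hit = genome.coding_index().get(pos)
    if hit is None:
        return "noncoding"
    gene_row, offset = hit
    gene = genome.genes.iloc[gene_row]
    cds = genome.cds_sequence(gene.gene_id)
    codon_i, within = divmod(offset, 3)
    codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_sense = alt if gene.strand == "+" else revcomp(alt)
    return classify_codon_change(codon, within, alt_sense)


def observed_coding_counts(
    snvs: pd.DataFrame, genome: AnnotatedGenome
) -> tuple[int, int]:
    """(non-synonymous, total) counts among SNVs falling inside CDSs."""
    nonsyn = total = 0
    for pos, alt in zip(snvs["pos"], snvs["alt"]):
        effect = classify_site_effect(genome, int(pos), alt)
        if effect == "noncoding":
            continue
        total += 1
        if effect in ("missense", "nonsense"):
            nonsyn += 1
    return nonsyn, total


def selection_test(
    snvs: pd.DataFrame,
    genome: AnnotatedGenome,
    background: str = "intergenic",
) -> SelectionTestResult:
    """End-to-end neutrality test of an SNV set against its genome.

    ``background`` chooses where per-class rates come from: ``intergenic``
    (outside gene bodies plus 1 kb upstream / 500 bp downstream flanks) or
    ``whole_genome``.
    """
    table = enumerate_opportunities(genome)
    if background == "intergenic":
        intervals = genome.intergenic_intervals()
    elif background == "whole_genome":
        intervals = [(1, len(genome.seq))]
    else:
        raise ValueError(f"unknown background {background!r}")
    rates = background_rates(snvs, intervals, genome, source=background)
    lam_s, lam_n, p_n = expected_rates(table, rates)
    k, n = observed_coding_counts(snvs, genome)
    result = binomial_selection_test(k, n, p_n)
    result.lambda_s, result.lambda_n = lam_s, lam_n
    return result


# -------------------------------------------------------- calibration helpers
def cds_effect_lookup(genome: AnnotatedGenome) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised consequence lookup for every CDS position and alt base.

    Returns (positions, effects) where ``positions`` are the 1-based CDS
    genome positions of valid ORFs and ``effects[i, j]`` codes the
    consequence of mutating position i to base "ACGT"[j]: 0 same base,
    1 synonymous, 2 missense, 3 nonsense.
    """
    pos_list: list[int] = []
    eff_list: list[list[int]] = []
    code = {"synonymous": 1, "missense": 2, "nonsense": 3}
    for _, gene in genome.genes.iterrows():
        cds = genome.cds_sequence(gene.gene_id)
        if not is_valid_orf(cds):
            continue
        for pos in range(int(gene.start), int(gene.end) + 1):
            offset = (pos - gene.start) if gene.strand == "+" else (gene.end - pos)
            codon_i, within = divmod(offset, 3)
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            row = []
            for alt in "ACGT":
                if alt == genome.seq[pos - 1]:
                    row.append(0)
                else:
                    alt_sense = alt if gene.strand == "+" else revcomp(alt)
                    row.append(code[classify_codon_change(codon, within, alt_sense)])
            pos_list.append(pos)
            eff_list.append(row)
    return np.array(pos_list, dtype=np.int64), np.array(eff_list, dtype=np.int8)


def neutral_rejection_rate(
    genome: AnnotatedGenome,
    n_mutations: int,
    n_reps: int,
    seed: int,
    nonsyn_removal_prob: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Monte-Carlo rejection rate of the neutrality test on CDS mutations.

    Each replicate draws ``n_mutations`` substitutions uniformly over CDS
    positions and alternative bases (candidate non-synonymous draws are
    rejected and redrawn with ``nonsyn_removal_prob``, emulating purifying
    selection) and tests the observed non-synonymous count against the
    neutral expectation p_N from the genome's opportunity table with
    uniform per-class rates. Returns (rejection rate, p-values).
    """
    rng = np.random.default_rng(seed)
    table = enumerate_opportunities(genome)
    flat = pd.Series(
        {
            "synonymous": int(table.counts["synonymous"].sum()),
            "missense": int(table.counts["missense"].sum()),
            "nonsense": int(table.counts["nonsense"].sum()),
        }
    )
    p_n = (flat["missense"] + flat["nonsense"]) / flat.sum()
    positions, effects = cds_effect_lookup(genome)
    # flatten the (position, alt) opportunity space: the 3 real alts per site
    site_idx, alt_idx = np.nonzero(effects)
    eff_flat = effects[site_idx, alt_idx]
    pvals = np.empty(n_reps)
    for rep in range(n_reps):
        need = n_mutations
        kept_effects: list[np.ndarray] = []
        while need > 0:
            draw = rng.integers(0, eff_flat.size, size=2 * need + 8)
            eff = eff_flat[draw]
            if nonsyn_removal_prob > 0:
                nonsyn = eff >= 2
                rejected = nonsyn & (rng.random(eff.size) < nonsyn_removal_prob)
                eff = eff[~rejected]
            eff = eff[:need]
            kept_effects.append(eff)
            need -= eff.size
        eff_all = np.concatenate(kept_effects)
        k = int((eff_all >= 2).sum())
        pvals[rep] = stats.binomtest(k, n_mutations, p_n).pvalue
    return float((pvals < 0.05).mean()), pvals
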