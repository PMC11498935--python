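"""Opportunity enumeration, background rates, and the neutrality test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dendrosoma import (
    SimConfig,
    background_rates,
    binomial_selection_test,
    enumerate_opportunities,
    expected_rates,
    generate_genome,
    selection_test,
    simulate_interindividual_snvs,
)
from dendrosoma.genomes import AnnotatedGenome, revcomp
from dendrosoma.selection import (
    BackgroundRates,
    classify_codon_change,
    classify_site_effect,
    translate_codon,
)
from dendrosoma.spectrum import SUBSTITUTIONS


def _single_gene_genome(cds: str, pad: int = 30, strand: str = "+") -> AnnotatedGenome:
    seq = "A" * pad + (cds if strand == "+" else revcomp(cds)) + "A" * pad
    genes = pd.DataFrame(
        [{"gene_id": "g1", "start": pad + 1, "end": pad + len(cds), "strand": strand}]
    )
    return AnnotatedGenome(name="chr1", seq=seq, genes=genes)


def brute_force_codon_neighbors(codon: str) -> dict[str, int]:
    """Independent oracle: translate every neighbor with Bio.Seq."""
    from Bio.Seq import Seq

    out = {"synonymous": 0, "missense": 0, "nonsense": 0}
    old = str(Seq(codon).translate())
    for i in range(3):
        for alt in "ACGT":
            if alt == codon[i]:
                continue
            new = str(Seq(codon[:i] + alt + codon[i + 1 :]).translate())
            if new == old:
                out["synonymous"] += 1
            elif new == "*":
                out["nonsense"] += 1
            else:
                out["missense"] += 1
    return out


def test_classifier_agrees_with_translation_oracle_on_all_codons():
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                mine = {"synonymous": 0, "missense": 0, "nonsense": 0}
                for i in range(3):
                    for alt in "ACGT":
                        if alt == codon[i]:
                            continue
                        mine[classify_codon_change(codon, i, alt)] += 1
                assert mine == brute_force_codon_neighbors(codon)


def test_atg_codon_has_nine_missense_neighbors():
    assert brute_force_codon_neighbors("ATG") == {
        "synonymous": 0, "missense": 9, "nonsense": 0,
    }


def test_tgg_codon_has_exactly_two_nonsense_neighbors():
    res = brute_force_codon_neighbors("TGG")  # TAG and TGA are stops
    assert res["nonsense"] == 2


def test_whole_codon_table_partition_matches_oracle():
    """Enumerating all 64 codons x 9 neighbors gives ~24% synonymous."""
    totals = {"synonymous": 0, "missense": 0, "nonsense": 0}
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if translate_codon(codon) == "*":
                    continue
                for k, v in brute_force_codon_neighbors(codon).items():
                    totals[k] += v
    frac_syn = totals["synonymous"] / sum(totals.values())
    assert 0.2 < frac_syn < 0.28


def test_opportunity_table_for_a_minimal_orf():
    cds = "ATGTGGTAA"  # Met-Trp-stop
    g = _single_gene_genome(cds)
    table = enumerate_opportunities(g)
    assert table.l_cds == 9
    assert int(table.counts.to_numpy().sum()) == 27
    expected = {"synonymous": 0, "missense": 0, "nonsense": 0}
    for codon in ("ATG", "TGG", "TAA"):
        for k, v in brute_force_codon_neighbors(codon).items():
            expected[k] += v
    # stop codon neighbors: stop-to-stop is synonymous, stop-lost missense
    assert table.counts["synonymous"].sum() == expected["synonymous"]
    assert table.counts["nonsense"].sum() == expected["nonsense"]


def test_opportunity_is_strand_symmetric():
    cds = "ATGGCTTGCAGATAA"
    plus = enumerate_opportunities(_single_gene_genome(cds, strand="+"))
    minus = enumerate_opportunities(_single_gene_genome(cds, strand="-"))
    pd.testing.assert_frame_equal(plus.counts, minus.counts)


@given(st.integers(1, 6), st.integers(2, 12), st.integers(0, 500))
def test_opportunity_totals_equal_three_l_cds(n_genes, codons, seed):
    cfg = SimConfig(
        seed=seed,
        genome_length=n_genes * (codons * 3 + 3100),
        n_genes=n_genes,
        mean_cds_length=3 * codons,
    )
    g = generate_genome(cfg)
    table = enumerate_opportunities(g)
    l_cds = sum(len(g.cds_sequence(gid)) for gid in g.genes.gene_id)
    assert table.l_cds == l_cds
    assert int(table.counts.to_numpy().sum()) == 3 * l_cds


def test_invalid_orfs_are_excluded_from_opportunity():
    g = _single_gene_genome("ATGTAATAA")  # internal stop
    table = enumerate_opportunities(g)
    assert table.l_cds == 0 or table.n_excluded_cds == 1
    assert table.n_excluded_cds == 1


def test_background_rates_toy_arithmetic():
    # 100 C bases and 100 A bases; two C>T mutations inside the region
    g = AnnotatedGenome(name="chr1", seq="C" * 100 + "A" * 100)
    snvs = pd.DataFrame(
        [("chr1", 10, "C", "T"), ("chr1", 20, "C", "T"), ("chr1", 150, "A", "G")],
        columns=["contig", "pos", "ref", "alt"],
    )
    rates = background_rates(snvs, [(1, 200)], g)
    assert rates.rates["C>T"] == pytest.approx(2 / 100)
    assert rates.rates["T>C"] == pytest.approx(1 / 100)  # A>G collapses to T>C
    assert rates.rates["C>A"] == 0.0
    none = background_rates(snvs.iloc[0:0], [(1, 200)], g)
    assert (none.rates == 0).all()
    with pytest.raises(ValueError, match="empty region"):
        background_rates(snvs, [], g)


def test_uniform_rates_cancel_in_expected_fraction(small_genome):
    table = enumerate_opportunities(small_genome)
    uniform = BackgroundRates(rates=pd.Series(0.01, index=list(SUBSTITUTIONS)))
    lam_s, lam_n, p_n = expected_rates(table, uniform)
    flat = table.counts.sum(axis=0)
    assert p_n == pytest.approx((flat["missense"] + flat["nonsense"]) / flat.sum())


def test_concentrated_rates_pick_one_class(small_genome):
    table = enumerate_opportunities(small_genome)
    rates = pd.Series(0.0, index=list(SUBSTITUTIONS))
    rates["C>T"] = 1.0
    lam_s, lam_n, p_n = expected_rates(table, BackgroundRates(rates=rates))
    row = table.counts.loc["C>T"]
    assert p_n == pytest.approx((row["missense"] + row["nonsense"]) / row.sum())


def test_expected_rates_match_weighted_sum_oracle(small_genome):
    rng = np.random.default_rng(5)
    table = enumerate_opportunities(small_genome)
    r = pd.Series(rng.random(6), index=list(SUBSTITUTIONS))
    lam_s, lam_n, p_n = expected_rates(table, BackgroundRates(rates=r))
    oracle_s = sum(r[c] * table.counts.loc[c, "synonymous"] for c in SUBSTITUTIONS)
    oracle_n = sum(
        r[c] * (table.counts.loc[c, "missense"] + table.counts.loc[c, "nonsense"])
        for c in SUBSTITUTIONS
    )
    assert lam_s == pytest.approx(oracle_s)
    assert lam_n == pytest.approx(oracle_n)
    assert p_n == pytest.approx(oracle_n / (oracle_s + oracle_n))


def test_binomial_test_at_the_mode_gives_p_one():
    res = binomial_selection_test(1, 2, 0.5)
    assert res.p_value == pytest.approx(1.0)
    assert not res.reject_at_5pct


def test_binomial_test_tail_sum():
    res = binomial_selection_test(0, 10, 0.5)
    assert res.p_value == pytest.approx(2 * 0.5**10)
    assert res.reject_at_5pct


def test_binomial_test_input_validation():
    with pytest.raises(ValueError):
        binomial_selection_test(1, 0, 0.5)
    with pytest.raises(ValueError):
        binomial_selection_test(3, 2, 0.5)
    with pytest.raises(ValueError):
        binomial_selection_test(1, 2, 1.0)


def test_site_effect_classification_respects_strand():
    cds = "ATGTGGTAA"
    g = _single_gene_genome(cds, strand="-")
    # genomic layout: pad + revcomp(cds); the last CDS base genomically is
    # the first sense base (A of ATG)
    start = int(g.genes.start.iloc[0])
    end = int(g.genes.end.iloc[0])
    # mutate genomic 'end' position: sense offset 0, ATG -> anything = missense
    ref = g.seq[end - 1]
    alt = "G" if ref != "G" else "C"
    assert classify_site_effect(g, end, alt) == "missense"
    assert classify_site_effect(g, 1, "C") == "noncoding"


def test_neutral_somatic_snvs_pass_the_selection_test(small_genome):
    """Uniformly placed mutations should not be flagged as selected."""
    snvs = simulate_interindividual_snvs(small_genome, 400, 0.0, seed=12)
    res = selection_test(snvs, small_genome, background="intergenic")
    assert 0 < res.p_n < 1
    assert res.observed_total > 0
    assert res.p_value > 0.05
    whole = selection_test(snvs, small_genome, background="whole_genome")
    assert whole.p_value > 0.05


def test_purged_snvs_are_flagged_by_the_selection_test(small_genome):
    snvs = simulate_interindividual_snvs(small_genome, 1500, 0.8, seed=13)
    res = selection_test(snvs, small_genome)
    assert res.reject_at_5pct
    assert res.observed_nonsyn / max(res.observed_total, 1) < res.p_n
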