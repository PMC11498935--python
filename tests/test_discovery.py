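"""Replicate/caller concordance filtering and the hard/support filters."""

import numpy as np
import pandas as pd
import pytest

from dendrosoma import (
    FilterThresholds,
    apply_hard_filters,
    apply_support_filters,
    collapse_homozygous,
    filter_interindividual,
    intersect_callers,
    intersect_replicates,
    pool_thresholds,
)
from dendrosoma.discovery import ANNOTATIONS, KEY

PASS_ANNOTS = {
    "QD": 20.0, "QUAL": 500.0, "SOR": 1.0, "FS": 5.0,
    "MQ": 55.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0,
}
BOUNDARY_ANNOTS = {
    "QD": 2.0, "QUAL": 30.0, "SOR": 4.0, "FS": 60.0,
    "MQ": 40.0, "MQRankSum": -12.5, "ReadPosRankSum": -8.0,
}


def make_record(pos=100, sample="b1", replicate=1, caller="A", threshold="T40",
                genotype="het", support=10, **annots):
    rec = {
        "contig": "chr1", "pos": pos, "ref": "C", "alt": "T",
        "sample": sample, "replicate": replicate, "caller": caller,
        "threshold": threshold, "genotype": genotype,
        "depth": 40, "hq_reads": 38, "supporting_reads": support,
        **PASS_ANNOTS,
    }
    rec.update(annots)
    return rec


def frame(*records):
    return pd.DataFrame(list(records))


def test_hard_filter_removes_below_qd_boundary():
    df = frame(make_record(QD=1.9))
    assert apply_hard_filters(df).empty


def test_hard_filter_retains_records_exactly_at_every_threshold():
    df = frame(make_record(**BOUNDARY_ANNOTS))
    assert len(apply_hard_filters(df)) == 1


def test_hard_filter_fails_missing_annotations():
    df = frame(make_record(MQRankSum=np.nan))
    assert apply_hard_filters(df).empty


def test_hard_filter_matches_rowwise_predicate_oracle():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(400):
        annots = {
            "QD": rng.uniform(0, 5), "QUAL": rng.uniform(0, 100),
            "SOR": rng.uniform(0, 8), "FS": rng.uniform(0, 120),
            "MQ": rng.uniform(20, 60), "MQRankSum": rng.uniform(-20, 5),
            "ReadPosRankSum": rng.uniform(-15, 5),
        }
        rows.append(make_record(pos=i + 1, **annots))
    df = frame(*rows)
    got = set(apply_hard_filters(df)["pos"])
    t = FilterThresholds()
    expected = set()
    for _, r in df.iterrows():
        ok = (
            r.QD >= t.qd_min and r.QUAL >= t.qual_min and r.SOR <= t.sor_max
            and r.FS <= t.fs_max and r.MQ >= t.mq_min
            and r.MQRankSum >= t.mqranksum_min and r.ReadPosRankSum >= t.readpos_min
        )
        if ok:
            expected.add(r.pos)
    assert got == expected


def _random_callset(rng, sample="b1", replicate=1, caller="A", n=60, pos_max=80):
    positions = rng.choice(np.arange(1, pos_max + 1), size=n, replace=False)
    return frame(*[
        make_record(pos=int(p), sample=sample, replicate=replicate,
                    caller=caller,
                    genotype="hom" if rng.random() < 0.1 else "het")
        for p in positions
    ])


def test_intersections_match_set_oracle_and_algebra():
    rng = np.random.default_rng(1)
    r1 = _random_callset(rng, replicate=1)
    r2 = _random_callset(rng, replicate=2)
    got = intersect_replicates(r1, r2)
    oracle = set(map(tuple, r1[KEY].values)) & set(map(tuple, r2[KEY].values))
    assert set(map(tuple, got[KEY].values)) == oracle
    # idempotence and annihilation
    same = intersect_replicates(r1, r1.assign(replicate=2))
    assert set(map(tuple, same[KEY].values)) == set(map(tuple, r1[KEY].values))
    assert intersect_replicates(r1, r2.iloc[0:0]).empty
    # caller intersection keyed identically, commutative in keys
    a, b = r1.assign(caller="A"), r2.assign(caller="B", replicate=1)
    ab = set(map(tuple, intersect_callers(a, b)[KEY].values))
    ba = set(map(tuple, intersect_callers(b, a)[KEY].values))
    assert ab == ba == oracle


def test_replicate_intersection_rejects_mismatched_samples():
    r1 = frame(make_record(sample="b1"))
    r2 = frame(make_record(sample="b2", replicate=2))
    with pytest.raises(ValueError, match="different samples"):
        intersect_replicates(r1, r2)


def test_genotype_is_part_of_the_intersection_key():
    r1 = frame(make_record(genotype="het"))
    r2 = frame(make_record(genotype="hom", replicate=2))
    assert intersect_replicates(r1, r2).empty


def test_pool_thresholds_is_a_keyed_union_with_provenance():
    rng = np.random.default_rng(2)
    sets = {t: _random_callset(rng, n=40) for t in ("T40", "T30", "T20")}
    pooled = pool_thresholds(sets)
    oracle = set()
    for df in sets.values():
        oracle |= set(map(tuple, df[KEY].values))
    assert set(map(tuple, pooled[KEY].values)) == oracle
    assert len(pooled) == len(oracle)  # each key once
    assert pooled["thresholds_detected"].str.contains("T").all()
    # three identical sets pool to the same keys; disjoint sets add up
    same = pool_thresholds({t: sets["T40"] for t in ("T40", "T30", "T20")})
    assert len(same) == len(sets["T40"])


def _hq_rows(pos, samples, hq=30):
    rows = []
    for s in samples:
        for rep in (1, 2):
            rows.append({"contig": "chr1", "pos": pos, "sample": s,
                         "replicate": rep, "hq_reads": hq})
    return rows


def test_support_filter_drops_sites_with_low_coverage_anywhere():
    samples = ["b1", "b2", "base"]
    cand = frame(make_record(pos=10)).assign(support_rep1=5, support_rep2=5)
    hq = pd.DataFrame(_hq_rows(10, samples))
    hq.loc[(hq["sample"] == "b2") & (hq["replicate"] == 2), "hq_reads"] = 4
    assert apply_support_filters(cand, hq).empty
    hq["hq_reads"] = 5  # boundary: exactly five high-quality reads passes
    assert len(apply_support_filters(cand, hq)) == 1


def test_support_filter_requires_two_reads_in_both_replicates():
    samples = ["b1", "b2", "base"]
    hq = pd.DataFrame(_hq_rows(10, samples))
    weak = frame(make_record(pos=10)).assign(support_rep1=2, support_rep2=1)
    assert apply_support_filters(weak, hq).empty
    ok = frame(make_record(pos=10)).assign(support_rep1=2, support_rep2=2)
    assert len(apply_support_filters(ok, hq)) == 1


def test_support_filter_rejects_sites_with_missing_coverage():
    cand = frame(make_record(pos=10)).assign(support_rep1=5, support_rep2=5)
    hq = pd.DataFrame(_hq_rows(10, ["b1", "b2"]) + _hq_rows(11, ["b1", "b2", "base"]))
    assert apply_support_filters(cand, hq).empty


def test_collapse_homozygous_counts_single_events():
    tips = ["b1", "b2", "b3"]
    calls = frame(
        make_record(pos=5, sample="b1", genotype="hom"),
        make_record(pos=5, sample="b2", genotype="hom"),
        make_record(pos=9, sample="b1", genotype="het"),
    )
    matrix = collapse_homozygous(calls, tips)
    assert matrix.n_sites == 2  # hom site is one event, not two
    assert matrix.genotypes.loc[("chr1", 5, "C", "T")] == "hom"
    assert matrix.presence.loc[("chr1", 5, "C", "T"), "b2"]
    assert not matrix.presence.loc[("chr1", 9, "C", "T"), "b3"]


def test_collapse_resolves_genotype_conflicts_to_het(caplog):
    calls = frame(
        make_record(pos=5, sample="b1", genotype="hom"),
        make_record(pos=5, sample="b2", genotype="het"),
    )
    matrix = collapse_homozygous(calls, ["b1", "b2"])
    assert matrix.genotypes.loc[("chr1", 5, "C", "T")] == "het"


def test_collapse_event_count_equals_distinct_sites():
    rng = np.random.default_rng(3)
    rows = []
    for _ in range(200):
        pos = int(rng.integers(1, 60))
        rows.append(make_record(pos=pos, sample=f"b{rng.integers(1, 4)}",
                                genotype="hom" if rng.random() < 0.3 else "het"))
    calls = frame(*rows)
    # genotype conflicts collapse to het, so events = distinct sites
    matrix = collapse_homozygous(calls, ["b1", "b2", "b3"])
    assert matrix.n_sites == calls[["contig", "pos", "ref", "alt"]].drop_duplicates().shape[0]


# ------------------------------------------------- inter-individual filters
def _candidates(positions):
    return frame(*[make_record(pos=int(p)) for p in positions])


def test_indel_window_boundary_is_151_inclusive():
    depth = np.full(2000, 30.0)
    cands = _candidates([848, 849, 850, 1151, 1152])
    kept, _ = filter_interindividual(cands, np.array([1000]), depth)
    assert set(kept["pos"]) == {848, 1152}  # 150 and 151 bp away removed


def test_zero_depth_runs_excise_flanks_only_when_longer_than_ten():
    depth = np.full(3000, 30.0)
    depth[1000:1011] = 0  # run of 11 sites: 1001..1011 (1-based)
    cands = _candidates([860, 840, 1160, 1164, 2000])
    kept, _ = filter_interindividual(cands, np.array([]), depth)
    # exclusion zone is [1001-151, 1011+151] = [850, 1162]
    assert set(kept["pos"]) == {840, 1164, 2000}
    depth10 = np.full(3000, 30.0)
    depth10[1000:1010] = 0  # run of exactly ten: no exclusion
    kept10, _ = filter_interindividual(cands, np.array([]), depth10)
    assert set(kept10["pos"]) == {860, 840, 1160, 1164, 2000}


def test_depth_bounds_use_mean_of_full_track():
    depth = np.full(1000, 30.0)
    depth[499] = 4      # below 5
    depth[500] = 47     # above 30 + 3*sqrt(30) ~ 46.4
    depth[501] = 46     # inside
    cands = _candidates([500, 501, 502, 600])
    kept, log = filter_interindividual(cands, np.array([]), depth)
    assert set(kept["pos"]) == {502, 600}
    kept_lin, _ = filter_interindividual(
        cands, np.array([]), depth, FilterThresholds(depth_upper="linear")
    )
    assert set(kept_lin["pos"]) == {501, 502, 600}  # 47 < 4*mean


def test_interindividual_filters_match_interval_mask_oracle():
    rng = np.random.default_rng(4)
    n = 5000
    depth = rng.poisson(30, n).astype(float)
    depth[1200:1215] = 0
    indels = np.sort(rng.choice(np.arange(1, n + 1), size=5, replace=False))
    positions = rng.choice(np.arange(1, n + 1), size=300, replace=False)
    cands = _candidates(positions)
    kept, _ = filter_interindividual(cands, indels, depth)
    t = FilterThresholds()
    d = depth.mean()
    upper = d + 3 * np.sqrt(d)
    runs = []
    run_start = None
    for i, v in enumerate(depth, start=1):
        if v == 0 and run_start is None:
            run_start = i
        if v != 0 and run_start is not None:
            if i - run_start > t.zero_depth_run:
                runs.append((run_start, i - 1))
            run_start = None
    expected = set()
    for p in positions:
        if any(abs(int(p) - int(i)) <= t.indel_window for i in indels):
            continue
        if any(s - t.indel_window <= p <= e + t.indel_window for s, e in runs):
            continue
        if not (t.depth_min <= depth[p - 1] <= upper):
            continue
        expected.add(int(p))
    assert set(kept["pos"]) == expected


def test_filters_only_remove_records():
    """The pipeline is monotone: every stage's output is a subset of input."""
    rng = np.random.default_rng(5)
    df = _random_callset(rng, n=50)
    filtered = apply_hard_filters(df)
    assert set(map(tuple, filtered[KEY].values)) <= set(map(tuple, df[KEY].values))
    kept, _ = filter_interindividual(df, np.array([10]), np.full(200, 30.0))
    assert set(kept["pos"]) <= set(df["pos"])
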