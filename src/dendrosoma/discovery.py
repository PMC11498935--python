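"""Concordance-based somatic SNV discovery and inter-individual filters.

The discovery strategy trades caller internals for concordance: a putative
somatic SNV must survive GATK-style hard filters, be called identically in
two biological replicates of the same sample, by two independent callers,
under at least one of three mapping/base-quality threshold sets (T40, T30,
T20), and then pass read-support filters evaluated across every sample of
the individual. Homozygous calls are collapsed to a single mutation event.

All call sets are pandas DataFrames with one row per call record; records
are keyed by (contig, pos, ref, alt, genotype) so a heterozygous call in
one replicate does not match a homozygous call in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SITE_KEY, MutationMatrix

logger = logging.getLogger(__name__)

KEY = SITE_KEY + ["genotype"]
ANNOTATIONS = ["QD", "QUAL", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum"]
THRESHOLD_SETS = ("T40", "T30", "T20")
CALLERS = ("A", "B")


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter and support-filter cutoffs.

    Removal conditions are strict inequalities (a record exactly at a
    threshold is retained), matching the usual semantics of GATK
    VariantFiltration expressions like ``QD < 2.0``.
    """

    qd_min: float = 2.0
    qual_min: float = 30.0
    sor_max: float = 4.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readpos_min: float = -8.0
    min_hq_reads: int = 5
    min_replicate_support: int = 2
    indel_window: int = 151
    zero_depth_run: int = 10
    depth_min: int = 5
    depth_upper: str = "sqrt"  # mean + 3*sqrt(mean); "linear" gives 4*mean


# ------------------------------------------------------------ hard filters
def apply_hard_filters(
    records: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Retain records passing every annotation cutoff.

    A record is kept iff QD >= qd_min, QUAL >= qual_min, SOR <= sor_max,
    FS <= fs_max, MQ >= mq_min, MQRankSum >= mqranksum_min and
    ReadPosRankSum >= readpos_min. A missing (NaN) annotation fails its
    filter — conservative, matching typical hard-filter semantics.
    """
    t = thresholds
    keep = (
        (records["QD"] >= t.qd_min)
        & (records["QUAL"] >= t.qual_min)
        & (records["SOR"] <= t.sor_max)
        & (records["FS"] <= t.fs_max)
        & (records["MQ"] >= t.mq_min)
        & (records["MQRankSum"] >= t.mqranksum_min)
        & (records["ReadPosRankSum"] >= t.readpos_min)
    )
    dropped = len(records) - int(keep.sum())
    if dropped:
        logger.debug("hard filters removed %d/%d records", dropped, len(records))
    return records.loc[keep].copy()


# ------------------------------------------------------------ intersections
def _single_value(df: pd.DataFrame, col: str) -> object:
    vals = df[col].unique()
    if len(vals) > 1:
        raise ValueError(f"call set mixes {col} values {list(vals)}")
    return vals[0] if len(vals) else None


def intersect_replicates(rep1: pd.DataFrame, rep2: pd.DataFrame) -> pd.DataFrame:
    """Keep calls identical (by site key and genotype) in both replicates.

    Returns replicate-1 records annotated with ``support_rep1`` and
    ``support_rep2`` (alt-supporting read counts in each replicate).
    """
    s1, s2 = _single_value(rep1, "sample"), _single_value(rep2, "sample")
    if s1 is not None and s2 is not None and s1 != s2:
        raise ValueError(f"replicate call sets are from different samples: {s1} vs {s2}")
    if rep1.empty or rep2.empty:
        return rep1.iloc[0:0].copy()
    r2 = rep2[KEY + ["supporting_reads"]].rename(
        columns={"supporting_reads": "support_rep2"}
    )
    out = rep1.merge(r2.drop_duplicates(KEY), on=KEY, how="inner")
    out = out.rename(columns={"supporting_reads": "support_rep1"})
    return out


def intersect_callers(caller_a: pd.DataFrame, caller_b: pd.DataFrame) -> pd.DataFrame:
    """Keep calls made identically by both callers (records from caller A)."""
    s1, s2 = _single_value(caller_a, "sample"), _single_value(caller_b, "sample")
    if s1 is not None and s2 is not None and s1 != s2:
        raise ValueError(f"caller call sets are from different samples: {s1} vs {s2}")
    if caller_a.empty or caller_b.empty:
        return caller_a.iloc[0:0].copy()
    keys_b = caller_b[KEY].drop_duplicates()
    return caller_a.merge(keys_b, on=KEY, how="inner")


def pool_thresholds(sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Key-level union over threshold sets, with detection provenance.

    Each site/genotype key appears once; the record retained is the one
    from the strictest threshold that detected it (dict order), and the
    ``thresholds_detected`` column lists every detecting set.
    """
    frames = []
    for name, df in sets.items():
        if df.empty:
            continue
        f = df.copy()
        f["_threshold_name"] = name
        frames.append(f)
    if not frames:
        for df in sets.values():
            out = df.iloc[0:0].copy()
            out["thresholds_detected"] = pd.Series(dtype=str)
            return out
        raise ValueError("no threshold sets supplied")
    allrec = pd.concat(frames, ignore_index=True)
    prov = (
        allrec.groupby(KEY, sort=False)["_threshold_name"]
        .agg(lambda s: ";".join(dict.fromkeys(s)))
        .rename("thresholds_detected")
    )
    first = allrec.drop_duplicates(KEY, keep="first").drop(columns=["_threshold_name"])
    out = first.merge(prov.reset_index(), on=KEY, how="left")
    return out


# ----------------------------------------------------------- support filters
def apply_support_filters(
    candidates: pd.DataFrame,
    hq_table: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Cross-sample read-support filters on pooled candidates.

    ``hq_table`` holds high-quality read counts (mapping quality > 20) for
    every sample-replicate at every candidate site, columns
    ``contig, pos, sample, replicate, hq_reads``. A site is removed when
    any sample-replicate shows fewer than ``min_hq_reads`` high-quality
    reads, or when its coverage data are incomplete; a variant-carrying
    record is removed unless supported by at least
    ``min_replicate_support`` reads in *both* replicates.
    """
    if candidates.empty:
        return candidates.copy()
    n_tracks = hq_table.groupby(["contig", "pos"]).size()
    expected = hq_table.groupby(["sample", "replicate"]).ngroups
    site_min = hq_table.groupby(["contig", "pos"])["hq_reads"].min()
    ok_sites = set(
        site_min[(site_min >= thresholds.min_hq_reads) & (n_tracks == expected)].index
    )
    incomplete = set(n_tracks[n_tracks != expected].index)
    if incomplete:
        logger.warning("rejecting %d sites with incomplete coverage data", len(incomplete))
    keys = list(zip(candidates["contig"], candidates["pos"]))
    keep_site = pd.Series([k in ok_sites for k in keys], index=candidates.index)
    m = thresholds.min_replicate_support
    keep_support = (candidates["support_rep1"] >= m) & (candidates["support_rep2"] >= m)
    return candidates.loc[keep_site & keep_support].copy()


# -------------------------------------------------------------- collapsing
def collapse_homozygous(callset: pd.DataFrame, tips: list[str]) -> MutationMatrix:
    """Collapse per-sample calls into a sites x tips presence matrix.

    A homozygous site contributes one mutation event, not two. Conflicting
    genotypes among carriers of one site are resolved to heterozygous with
    a warning.
    """
    if callset.empty:
        return MutationMatrix.empty(tips)
    geno = callset.groupby(SITE_KEY, sort=True)["genotype"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else "conflict"
    )
    n_conflict = int((geno == "conflict").sum())
    if n_conflict:
        logger.warning(
            "%d sites with conflicting genotypes across carriers; treated as het",
            n_conflict,
        )
        geno = geno.replace("conflict", "het")
    presence = (
        callset.assign(_one=True)
        .pivot_table(index=SITE_KEY, columns="sample", values="_one", aggfunc="any", fill_value=False)
        .reindex(columns=tips, fill_value=False)
    )
    presence.columns.name = None
    return MutationMatrix(presence=presence.astype(bool), genotypes=geno)


# ------------------------------------------------------- somatic pipeline
def discover_somatic(
    records: pd.DataFrame,
    hq_table: pd.DataFrame,
    tips: list[str],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[MutationMatrix, dict[str, int]]:
    """Full intra-individual discovery: filters, intersections, collapsing.

    ``records`` holds every call of every (sample, replicate, caller,
    threshold_set); the base sample contributes coverage (via ``hq_table``)
    but its calls, if any, are processed like any tip's. Returns the
    somatic mutation matrix over ``tips`` and per-stage record counts.
    """
    stage_counts = {"input": len(records)}
    filtered = apply_hard_filters(records, thresholds)
    stage_counts["hard_filtered"] = len(filtered)

    per_sample: list[pd.DataFrame] = []
    for sample, sdf in filtered.groupby("sample", sort=True):
        by_threshold: dict[str, pd.DataFrame] = {}
        for tset in THRESHOLD_SETS:
            tdf = sdf[sdf["threshold"] == tset]
            per_caller = []
            for caller in CALLERS:
                cdf = tdf[tdf["caller"] == caller]
                merged = intersect_replicates(
                    cdf[cdf["replicate"] == 1], cdf[cdf["replicate"] == 2]
                )
                per_caller.append(merged)
            by_threshold[tset] = intersect_callers(per_caller[0], per_caller[1])
        per_sample.append(pool_thresholds(by_threshold))
    candidates = (
        pd.concat(per_sample, ignore_index=True) if per_sample else filtered.iloc[0:0]
    )
    stage_counts["concordant"] = len(candidates)

    supported = apply_support_filters(candidates, hq_table, thresholds)
    stage_counts["supported"] = len(supported)

    matrix = collapse_homozygous(
        supported[supported["sample"].isin(tips)], tips
    )
    stage_counts["sites"] = matrix.n_sites
    return matrix, stage_counts


# -------------------------------------------------- inter-individual filters
def zero_depth_runs(depth_track: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """1-based [start, end] intervals of zero-depth runs longer than min_run."""
    zero = np.asarray(depth_track) == 0
    if not zero.any():
        return []
    padded = np.concatenate([[False], zero, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s + 1 > min_run]


def filter_interindividual(
    candidates: pd.DataFrame,
    indel_positions: np.ndarray,
    depth_track: np.ndarray,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Ambiguity filters for fixed inter-individual SNVs.

    In order: remove SNVs within ``indel_window`` bp of an indel; remove
    SNVs within ``indel_window`` bp of a zero-depth run longer than
    ``zero_depth_run`` consecutive sites; remove SNVs whose depth is below
    ``depth_min`` or above the upper bound (mean depth d plus 3*sqrt(d) by
    default, 4d in ``linear`` mode). The mean d is taken over the whole
    depth track before any removal.
    """
    depth_track = np.asarray(depth_track, dtype=float)
    if depth_track.size == 0:
        raise ValueError("empty depth track")
    d_mean = float(depth_track.mean())
    if thresholds.depth_upper == "sqrt":
        upper = d_mean + 3.0 * np.sqrt(d_mean)
    elif thresholds.depth_upper == "linear":
        upper = 4.0 * d_mean
    else:
        raise ValueError(f"unknown depth_upper mode {thresholds.depth_upper!r}")

    pos = candidates["pos"].to_numpy()
    log: dict[str, int] = {"input": len(candidates)}
    w = thresholds.indel_window

    indels = np.sort(np.asarray(indel_positions))
    if indels.size:
        idx = np.searchsorted(indels, pos)
        left = np.where(idx > 0, pos - indels[np.maximum(idx - 1, 0)], np.inf)
        right = np.where(idx < indels.size, indels[np.minimum(idx, indels.size - 1)] - pos, np.inf)
        near_indel = np.minimum(left, right) <= w
    else:
        near_indel = np.zeros(pos.shape, dtype=bool)
    keep = ~near_indel
    log["after_indel_window"] = int(keep.sum())

    near_run = np.zeros(pos.shape, dtype=bool)
    for s, e in zero_depth_runs(depth_track, thresholds.zero_depth_run):
        near_run |= (pos >= s - w) & (pos <= e + w)
    keep &= ~near_run
    log["after_zero_depth"] = int(keep.sum())

    depths = depth_track[pos - 1]
    keep &= (depths >= thresholds.depth_min) & (depths <= upper)
    log["after_depth_bounds"] = int(keep.sum())
    return candidates.loc[keep].copy(), log
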