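"""Readers and writers for the pipeline's on-disk artifacts.

Call tables travel as uncompressed VCF v4.2, one file per
sample/replicate/caller/threshold, with the seven hard-filter annotations
in INFO and GT:DP:HQ:AD in FORMAT. Everything else is plain text: FASTA,
GFF3, Newick, TSV, JSON.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import ANNOTATIONS

_VCF_NAME = re.compile(
    r"calls_(?P<sample>[^_]+)_rep(?P<rep>[12])_(?P<caller>[AB])_(?P<threshold>T\d+)\.vcf$"
)


def write_vcf(records: pd.DataFrame, path: str | Path, contig_length: int) -> None:
    """Write one sample-replicate-caller-threshold call set as VCF v4.2."""
    sample = records["sample"].iloc[0] if len(records) else "sample"
    contig = records["contig"].iloc[0] if len(records) else "chr1"
    lines = [
        "##fileformat=VCFv4.2",
        "##source=dendrosoma",
        f"##contig=<ID={contig},length={contig_length}>",
    ]
    for ann in ANNOTATIONS:
        if ann == "QUAL":
            continue
        lines.append(
            f'##INFO=<ID={ann},Number=1,Type=Float,Description="{ann} filter annotation">'
        )
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=HQ,Number=1,Type=Integer,Description="Reads with mapping quality > 20">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for _, r in records.sort_values("pos").iterrows():
        info = ";".join(
            f"{ann}={r[ann]:.4f}" for ann in ANNOTATIONS if ann != "QUAL"
        )
        gt = "0/1" if r["genotype"] == "het" else "1/1"
        ad_ref = max(int(r["depth"]) - int(r["supporting_reads"]), 0)
        sample_field = f"{gt}:{int(r['depth'])}:{int(r['hq_reads'])}:{ad_ref},{int(r['supporting_reads'])}"
        lines.append(
            f"{r['contig']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t"
            f"{r['QUAL']:.2f}\t.\t{info}\tGT:DP:HQ:AD\t{sample_field}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read one call-set VCF back into the record-table representation.

    Sample, replicate, caller and threshold are recovered from the file
    name pattern ``calls_<sample>_rep<r>_<caller>_<threshold>.vcf``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    m = _VCF_NAME.search(path.name)
    meta = m.groupdict() if m else {}
    vcf = VCF(str(path))
    sample = vcf.samples[0] if vcf.samples else meta.get("sample", "sample")
    rows = []
    for var in vcf:
        gts = var.genotypes[0] if var.genotypes else [0, 1, False]
        genotype = "hom" if gts[0] == 1 and gts[1] == 1 else "het"
        depth = int(var.format("DP")[0][0]) if var.format("DP") is not None else 0
        hq = int(var.format("HQ")[0][0]) if var.format("HQ") is not None else 0
        ad = var.format("AD")
        support = int(ad[0][-1]) if ad is not None else 0
        row = {
            "contig": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0],
            "sample": meta.get("sample", sample),
            "replicate": int(meta.get("rep", 1)),
            "caller": meta.get("caller", "A"),
            "threshold": meta.get("threshold", "T40"),
            "genotype": genotype,
            "depth": depth,
            "hq_reads": hq,
            "supporting_reads": support,
            "QUAL": float(var.QUAL) if var.QUAL is not None else np.nan,
        }
        for ann in ANNOTATIONS:
            if ann == "QUAL":
                continue
            val = var.INFO.get(ann)
            row[ann] = float(val) if val is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_call_tables(call_tables, outdir: str | Path, contig_length: int) -> list[Path]:
    """One VCF per (sample, replicate, caller, threshold)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    df = call_tables.records
    for (sample, rep, caller, tset), grp in df.groupby(
        ["sample", "replicate", "caller", "threshold"], sort=True
    ):
        p = outdir / f"calls_{sample}_rep{rep}_{caller}_{tset}.vcf"
        write_vcf(grp, p, contig_length)
        written.append(p)
    return written


def read_call_tables_dir(calls_dir: str | Path) -> pd.DataFrame:
    frames = [read_vcf(p) for p in sorted(Path(calls_dir).glob("calls_*.vcf"))]
    if not frames:
        raise FileNotFoundError(f"no calls_*.vcf files under {calls_dir}")
    return pd.concat(frames, ignore_index=True)


def write_somatic_vcf(matrix, path: str | Path, contig_length: int) -> None:
    """Final somatic SNV set with carrier samples in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=dendrosoma",
        '##INFO=<ID=CARRIERS,Number=.,Type=String,Description="Tip samples carrying the mutation">',
        '##INFO=<ID=GENO,Number=1,Type=String,Description="het or hom (collapsed to one event)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for (contig, pos, ref, alt), row in matrix.presence.iterrows():
        carriers = ",".join(c for c in matrix.tips if row[c])
        geno = matrix.genotypes.loc[(contig, pos, ref, alt)]
        lines.append(
            f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\tCARRIERS={carriers};GENO={geno}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_snv_table(path: str | Path) -> pd.DataFrame:
    """Read a site list (VCF or TSV with contig/pos/ref/alt columns)."""
    path = Path(path)
    if path.suffix == ".vcf":
        from cyvcf2 import VCF

        rows = [
            {"contig": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]}
            for v in VCF(str(path))
        ]
        return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    return pd.read_csv(path, sep="\t")
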