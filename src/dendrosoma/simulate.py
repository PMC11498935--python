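"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design the pipeline is built for: a
diploid genome with annotated CDSs and intergenic space; a physical tree
architecture with seven branch tips plus a base (cambium) sample whose
genotype defines the reference; somatic mutations accumulating as a
Poisson process along branches (optionally CpG-biased toward C>T),
inherited by distal branches and stochastically lost at branch points; and
two biological replicates of noisy variant calls per sample, from two
emulated callers at three quality-threshold sets, with per-site depths and
GATK-style filter annotations.

Mutations are modelled at the site level under an infinite-sites
approximation (colliding sites are resampled); read alignment and caller
internals are out of scope and replaced by per-site error rates and
annotation mixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SITE_KEY, MutationMatrix
from .discovery import ANNOTATIONS, CALLERS, THRESHOLD_SETS
from .genomes import AnnotatedGenome, STOP_CODONS, revcomp
from .trees import PhysicalTree

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimConfig:
    """Study-scale parameters of the synthetic landscape.

    The genome is a scaled-down stand-in for a ~350 Mb dipterocarp genome:
    shorter, but with the per-tree expected mutation counts of the real
    study (hundreds of SNVs) obtained by a correspondingly larger
    per-meter rate. Exactly one of ``mu_per_meter``/``mu_per_year`` may be
    set; the per-year form is converted through ``growth_rate`` (meters of
    growth per year).
    """

    seed: int = 0
    genome_length: int = 200_000
    n_genes: int = 40
    mean_cds_length: int = 900
    gc_content: float = 0.38
    mu_per_meter: float | None = 1.25e-5
    mu_per_year: float | None = None
    growth_rate: float = 0.5  # m/yr, used only with mu_per_year
    cpg_ct_multiplier: float = 4.0
    loss_prob: float = 0.05
    hom_fraction: float = 0.04
    fp_rate: float = 1e-5
    fn_rate: float = 0.05
    mean_depth: float = 60.0
    hq_fraction: float = 0.97
    annot_fail_rate: float = 0.02
    fp_annot_fail_rate: float = 0.5
    ploidy: int = 2

    def __post_init__(self) -> None:
        if (self.mu_per_meter is None) == (self.mu_per_year is None):
            raise ValueError("set exactly one of mu_per_meter / mu_per_year")
        for name in ("gc_content", "loss_prob", "hom_fraction", "fp_rate",
                     "fn_rate", "annot_fail_rate", "fp_annot_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fp_rate >= 1 or self.fn_rate >= 1:
            raise ValueError("fp_rate and fn_rate must be < 1")
        if self.mean_cds_length % 3:
            raise ValueError("mean_cds_length must be a multiple of 3")
        if self.ploidy != 2:
            raise ValueError("only diploid bookkeeping is supported")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")

    @property
    def effective_mu_per_meter(self) -> float:
        mu = (
            self.mu_per_meter
            if self.mu_per_meter is not None
            else self.mu_per_year / self.growth_rate
        )
        if mu <= 0:
            raise ValueError("mutation rate must be positive")
        return mu

    def noiseless(self) -> "SimConfig":
        """Copy with all call noise switched off (loss still applies)."""
        d = asdict(self)
        d.update(fp_rate=0.0, fn_rate=0.0, annot_fail_rate=0.0, fp_annot_fail_rate=0.0)
        return SimConfig(**d)


@dataclass
class TruthSet:
    """Ground truth of one simulation run."""

    mutations: pd.DataFrame  # contig,pos,ref,alt,genotype,origin,carrying tips
    matrix: MutationMatrix
    mu_per_meter: float
    tree: PhysicalTree

    def to_json(self, path: str | Path) -> None:
        recs = self.mutations.copy()
        recs["tips"] = recs["tips"].map(list)
        payload = {
            "mu_per_meter": self.mu_per_meter,
            "tree_newick": self.tree.newick(),
            "mutations": recs.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------- genome
def generate_genome(config: SimConfig) -> AnnotatedGenome:
    """Random annotated genome: background sequence plus packed ORFs.

    Genes are placed one per slot of ``genome_length // n_genes`` bases
    with jitter, leaving at least 1 kb upstream and 500 bp downstream of
    every CDS outside any other gene's flanks, so intergenic space is
    never empty. Each CDS starts with ATG, ends with a random stop codon
    and has no internal stop. Deterministic under the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=config.genome_length, p=p)

    genes: list[dict] = []
    if config.n_genes > 0:
        cds_len = config.mean_cds_length
        slot = config.genome_length // config.n_genes
        if slot < cds_len + 3000 or config.genome_length < config.n_genes * (cds_len + 3000):
            raise ValueError(
                "genome too small to pack genes: need genome_length >= "
                "n_genes * (mean_cds_length + 3000)"
            )
        n_internal = cds_len // 3 - 2
        for i in range(config.n_genes):
            jitter = int(rng.integers(0, slot - cds_len - 1500))
            start = i * slot + 1001 + jitter  # 1-based
            codons: list[str] = []
            while len(codons) < n_internal:
                cod = "".join(rng.choice(bases, size=3, p=p))
                if cod not in STOP_CODONS:
                    codons.append(cod)
            stop = str(rng.choice(list(STOP_CODONS)))
            cds = "ATG" + "".join(codons) + stop
            strand = str(rng.choice(["+", "-"]))
            placed = cds if strand == "+" else revcomp(cds)
            seq[start - 1 : start - 1 + cds_len] = list(placed)
            genes.append(
                {
                    "gene_id": f"g{i + 1:04d}",
                    "start": start,
                    "end": start + cds_len - 1,
                    "strand": strand,
                }
            )
    return AnnotatedGenome(
        name="chr1",
        seq="".join(seq),
        genes=pd.DataFrame(genes, columns=["gene_id", "start", "end", "strand"]),
    )


# ---------------------------------------------------------- architecture
def generate_architecture(
    n_tips: int = 7,
    branch_lengths: dict[str, float] | None = None,
    seed: int = 0,
    trunk_length: float = 25.0,
    internal_range: tuple[float, float] = (1.0, 6.0),
    pendant_range: tuple[float, float] = (2.0, 10.0),
    age: float | None = None,
) -> PhysicalTree:
    """Random rooted architecture: a trunk and a bifurcating crown.

    Defaults emulate a mature emergent tropical tree: base sample at the
    stem base, a tall trunk, and seven branch-tip samples in the crown.
    ``branch_lengths`` can pin specific edge lengths by child-node name
    after generation (used by tests for hand-built geometries).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    tips = [f"b{i + 1}" for i in range(n_tips)]
    edges: list[tuple[str, str, float]] = []
    counter = 0

    def new_internal() -> str:
        nonlocal counter
        counter += 1
        return f"n{counter}"

    def build(leaves: list[str], parent: str, length: float) -> None:
        if len(leaves) == 1:
            edges.append((parent, leaves[0], length))
            return
        node = new_internal()
        edges.append((parent, node, length))
        k = int(rng.integers(1, len(leaves)))
        lengths = rng.uniform(*internal_range, size=2)
        l_left = lengths[0] if k > 1 else rng.uniform(*pendant_range)
        l_right = lengths[1] if len(leaves) - k > 1 else rng.uniform(*pendant_range)
        build(leaves[:k], node, float(l_left))
        build(leaves[k:], node, float(l_right))

    build(tips, "base", float(trunk_length))
    if branch_lengths:
        for bad in set(branch_lengths) - {c for _, c, _ in edges}:
            raise ValueError(f"unknown edge child {bad!r}")
        if any(l <= 0 for l in branch_lengths.values()):
            raise ValueError("branch lengths must be positive")
        edges = [(p, c, branch_lengths.get(c, l)) for p, c, l in edges]
    return PhysicalTree(edges=edges, tips=tips, base="base", age=age)


def star_architecture(n_tips: int, length: float = 1.0) -> PhysicalTree:
    """Star tree: every tip hangs directly off the base (test geometry)."""
    tips = [f"b{i + 1}" for i in range(n_tips)]
    return PhysicalTree(
        edges=[("base", t, length) for t in tips], tips=tips, base="base"
    )


# ------------------------------------------------------------- mutations
def _site_alt_weights(genome: AnnotatedGenome, multiplier: float):
    """Per-site sampling weights and the CpG mask.

    Non-CpG sites get weight 1. CpG sites (the C, and the G on the
    opposite strand) get a common weight chosen so the realised
    fold-enrichment of mutations at CpG sites equals ``multiplier``; the
    excess weight rides entirely on the C>T (G>A) channel.
    """
    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    cpg = np.zeros(arr.size, dtype=bool)
    cpg[:-1] |= is_c[:-1] & is_g[1:]
    cpg[1:] |= is_g[1:] & is_c[:-1]
    f = cpg.mean()
    if multiplier < 1:
        raise ValueError("cpg_ct_multiplier must be >= 1")
    if multiplier * f >= 1:
        raise ValueError(
            f"cpg_ct_multiplier {multiplier} infeasible: genome CpG fraction {f:.3f}"
        )
    w = multiplier * (1 - f) / (1 - multiplier * f) if multiplier > 1 else 1.0
    weights = np.ones(arr.size)
    weights[cpg] = w
    return weights / weights.sum(), cpg, w


def _draw_alt(rng, ref: str, at_cpg: bool, w: float) -> str:
    others = [b for b in "ACGT" if b != ref]
    if at_cpg and ref in ("C", "G") and w > 1:
        special = "T" if ref == "C" else "A"
        probs = np.array(
            [w - 2 / 3 if b == special else 1 / 3 for b in others]
        )
        probs /= probs.sum()
        return str(rng.choice(others, p=probs))
    return str(rng.choice(others))


def simulate_somatic_mutations(
    genome: AnnotatedGenome,
    tree: PhysicalTree,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[MutationMatrix, TruthSet]:
    """Poisson mutation accumulation along the architecture.

    Each branch of length L accrues Poisson(2 * G * mu * L) mutations
    (diploid, G = genome length). A mutation is carried by the subtree
    below its originating branch, except that transmission to each
    daughter branch fails independently with ``loss_prob``. Colliding
    sites are resampled (infinite-sites). Mutations surviving to no tip
    stay in the truth records with an empty carrier set but do not appear
    in the matrix.
    """
    mu = config.effective_mu_per_meter
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 3])
    )
    weights, cpg, w = _site_alt_weights(genome, config.cpg_ct_multiplier)
    g_len = len(genome.seq)
    used: set[int] = set()
    records: list[dict] = []
    for parent, child, length in tree.preorder_edges():
        n_mut = rng.poisson(2.0 * g_len * mu * length)
        if n_mut > 0.5 * g_len:
            raise ValueError("mutation rate too high for the infinite-sites model")
        sites = rng.choice(g_len, size=n_mut, p=weights)
        for s in sites:
            tries = 0
            while int(s) in used:
                s = rng.choice(g_len, p=weights)
                tries += 1
                if tries > 1000:
                    raise RuntimeError("site space exhausted; lower the rate")
            s = int(s)
            used.add(s)
            pos = s + 1
            ref = genome.seq[s]
            alt = _draw_alt(rng, ref, bool(cpg[s]), w)
            carried = _transmit(tree, child, config.loss_prob, rng)
            genotype = "hom" if rng.random() < config.hom_fraction else "het"
            records.append(
                {
                    "contig": genome.name,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "genotype": genotype,
                    "origin": child,
                    "tips": tuple(carried),
                }
            )
    mutations = pd.DataFrame(
        records, columns=["contig", "pos", "ref", "alt", "genotype", "origin", "tips"]
    ).sort_values("pos", kind="stable").reset_index(drop=True)
    carried_mask = mutations["tips"].map(len) > 0
    visible = mutations.loc[carried_mask]
    if len(visible):
        idx = pd.MultiIndex.from_frame(visible[SITE_KEY])
        presence = pd.DataFrame(
            [[t in tips_ for t in tree.tips] for tips_ in visible["tips"]],
            index=idx,
            columns=tree.tips,
        )
        genotypes = pd.Series(visible["genotype"].to_numpy(), index=idx)
        matrix = MutationMatrix(presence=presence, genotypes=genotypes)
    else:
        matrix = MutationMatrix.empty(tree.tips)
    truth = TruthSet(mutations=mutations, matrix=matrix, mu_per_meter=mu, tree=tree)
    return matrix, truth


def _transmit(tree: PhysicalTree, origin: str, loss_prob: float, rng) -> list[str]:
    """Tips carrying a mutation that arose on the branch above ``origin``."""
    carried: list[str] = []
    stack = [origin]
    while stack:
        node = stack.pop()
        kids = tree.children.get(node)
        if not kids:
            if node in tree.tips:
                carried.append(node)
            continue
        for k in kids:
            if loss_prob == 0 or rng.random() >= loss_prob:
                stack.append(k)
    return sorted(carried)


# ------------------------------------------------------------ call tables
class DepthModel:
    """Deterministic per-(sample, replicate, site) coverage model.

    Depth is Poisson around the configured mean and high-quality reads are
    binomial on depth; draws are keyed by a stable hash of the query so
    any site can be interrogated reproducibly, including sites no caller
    emitted.
    """

    def __init__(self, seed: int, mean_depth: float, hq_fraction: float):
        self.seed = int(seed)
        self.mean_depth = mean_depth
        self.hq_fraction = hq_fraction

    def _rng(self, sample: str, replicate: int, pos: int) -> np.random.Generator:
        key = zlib.crc32(sample.encode())
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, key, int(replicate), int(pos)])
        )

    def depth_hq(self, sample: str, replicate: int, pos: int) -> tuple[int, int]:
        rng = self._rng(sample, replicate, pos)
        depth = int(rng.poisson(self.mean_depth))
        hq = int(rng.binomial(depth, self.hq_fraction)) if depth else 0
        return depth, hq

    def hq_table(
        self, contig: str, positions, samples: list[str], replicates=(1, 2)
    ) -> pd.DataFrame:
        rows = []
        for pos in positions:
            for sample in samples:
                for rep in replicates:
                    depth, hq = self.depth_hq(sample, rep, int(pos))
                    rows.append(
                        {
                            "contig": contig,
                            "pos": int(pos),
                            "sample": sample,
                            "replicate": rep,
                            "depth": depth,
                            "hq_reads": hq,
                        }
                    )
        return pd.DataFrame(
            rows, columns=["contig", "pos", "sample", "replicate", "depth", "hq_reads"]
        )


@dataclass
class CallTables:
    """Per-sample, per-replicate, per-caller, per-threshold call records."""

    records: pd.DataFrame
    depth_model: DepthModel
    samples: list[str] = field(default_factory=list)

    def subset(self, sample=None, replicate=None, caller=None, threshold=None):
        df = self.records
        for col, val in (
            ("sample", sample),
            ("replicate", replicate),
            ("caller", caller),
            ("threshold", threshold),
        ):
            if val is not None:
                df = df[df[col] == val]
        return df.copy()

    def hq_table_for(self, positions) -> pd.DataFrame:
        contig = (
            self.records["contig"].iloc[0] if len(self.records) else "chr1"
        )
        return self.depth_model.hq_table(contig, positions, self.samples)


def _pass_annotations(rng, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "QD": rng.uniform(10, 35, n),
            "QUAL": rng.uniform(200, 2000, n),
            "SOR": rng.uniform(0.3, 2.5, n),
            "FS": rng.uniform(0, 15, n),
            "MQ": rng.uniform(50, 60, n),
            "MQRankSum": rng.normal(0, 1, n),
            "ReadPosRankSum": rng.normal(0, 1, n),
        }
    )


_FAIL_DRAWS = {
    "QD": lambda rng: rng.uniform(0.0, 1.99),
    "QUAL": lambda rng: rng.uniform(0.0, 29.9),
    "SOR": lambda rng: rng.uniform(4.01, 9.0),
    "FS": lambda rng: rng.uniform(60.1, 120.0),
    "MQ": lambda rng: rng.uniform(20.0, 39.9),
    "MQRankSum": lambda rng: rng.uniform(-20.0, -12.6),
    "ReadPosRankSum": lambda rng: rng.uniform(-15.0, -8.1),
}


def simulate_call_tables(
    matrix: MutationMatrix,
    genome: AnnotatedGenome,
    tree: PhysicalTree,
    config: SimConfig,
    seed: int | None = None,
) -> CallTables:
    """Emulated caller output for every sample and biological replicate.

    True sites are dropped per replicate with ``fn_rate`` (the dropout is
    shared by both callers and all threshold sets, which see the same
    library); spurious sites are injected per replicate at ``fp_rate`` per
    genome site, always with the transition alternative allele so a false
    positive recurring in the other replicate is self-consistent. Filter
    annotations are drawn per (caller, threshold) copy from a pass
    distribution, corrupted to a failing value with ``annot_fail_rate``
    (true sites) or ``fp_annot_fail_rate`` (spurious sites).
    """
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 4]))
    depth_model = DepthModel(
        seed=base_seed, mean_depth=config.mean_depth, hq_fraction=config.hq_fraction
    )
    samples = list(tree.tips) + [tree.base]
    g_len = len(genome.seq)
    rows: list[dict] = []
    presence = matrix.presence
    for sample in samples:
        if sample in presence.columns:
            carried = presence.index[presence[sample]]
        else:
            carried = presence.index[0:0]
        for rep in (1, 2):
            keep = rng.random(len(carried)) >= config.fn_rate
            for (contig, pos, ref, alt), ok in zip(carried, keep):
                if not ok:
                    continue
                genotype = matrix.genotypes.loc[(contig, pos, ref, alt)]
                depth, hq = depth_model.depth_hq(sample, rep, pos)
                p_alt = 0.5 if genotype == "het" else config.hq_fraction
                support = int(rng.binomial(depth, p_alt)) if depth else 0
                rows.append(
                    {
                        "contig": contig,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "sample": sample,
                        "replicate": rep,
                        "genotype": genotype,
                        "depth": depth,
                        "hq_reads": hq,
                        "supporting_reads": support,
                        "is_spurious": False,
                    }
                )
            n_fp = rng.poisson(config.fp_rate * g_len)
            fp_positions = set()
            true_pos = {p for _, p, _, _ in carried}
            while len(fp_positions) < n_fp:
                cand = int(rng.integers(1, g_len + 1))
                if cand not in true_pos:
                    fp_positions.add(cand)
            for pos in sorted(fp_positions):
                ref = genome.seq[pos - 1]
                depth, hq = depth_model.depth_hq(sample, rep, pos)
                support = int(rng.binomial(depth, 0.25)) if depth else 0
                rows.append(
                    {
                        "contig": genome.name,
                        "pos": pos,
                        "ref": ref,
                        "alt": _TRANSITION[ref],
                        "sample": sample,
                        "replicate": rep,
                        "genotype": "het",
                        "depth": depth,
                        "hq_reads": hq,
                        "supporting_reads": support,
                        "is_spurious": True,
                    }
                )
    base = pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt", "sample", "replicate", "genotype",
            "depth", "hq_reads", "supporting_reads", "is_spurious",
        ],
    )
    copies = []
    for caller in CALLERS:
        for tset in THRESHOLD_SETS:
            c = base.copy()
            c["caller"] = caller
            c["threshold"] = tset
            copies.append(c)
    records = pd.concat(copies, ignore_index=True) if copies else base
    n = len(records)
    annots = _pass_annotations(rng, n)
    fail_rate = np.where(
        records["is_spurious"].to_numpy() if n else False,
        config.fp_annot_fail_rate,
        config.annot_fail_rate,
    )
    if n:
        fails = np.flatnonzero(rng.random(n) < fail_rate)
        for i in fails:
            which = str(rng.choice(ANNOTATIONS))
            annots.loc[i, which] = _FAIL_DRAWS[which](rng)
    records = pd.concat([records, annots], axis=1)
    return CallTables(records=records, depth_model=depth_model, samples=samples)


# ---------------------------------------------------- inter-individual SNVs
def simulate_interindividual_snvs(
    genome: AnnotatedGenome,
    n_sites: int,
    nonsyn_removal_prob: float = 0.0,
    seed: int = 0,
    region: str = "genome",
) -> pd.DataFrame:
    """Fixed SNVs between individuals under tunable purifying selection.

    Sites are placed uniformly (over the whole genome, or over CDS
    positions with ``region='cds'``) with a uniform alternative allele;
    candidate non-synonymous draws are rejected and redrawn with
    ``nonsyn_removal_prob``. ``nonsyn_removal_prob=1`` purges every
    non-synonymous site.
    """
    from .selection import classify_site_effect

    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 0 <= nonsyn_removal_prob <= 1:
        raise ValueError("nonsyn_removal_prob must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    if region == "cds":
        pool = np.array(sorted(genome.coding_index()), dtype=np.int64)
        if pool.size == 0:
            raise ValueError("no CDS positions available")
    elif region == "genome":
        pool = None
    else:
        raise ValueError(f"unknown region {region!r}")
    if nonsyn_removal_prob == 1.0 and region == "cds":
        # complete purging still needs synonymous capacity; probed lazily below
        pass
    out: list[dict] = []
    guard = 0
    while len(out) < n_sites:
        guard += 1
        if guard > 200 * n_sites + 10_000:
            raise RuntimeError(
                "rejection sampling stalled: no acceptable sites remain"
            )
        pos = (
            int(pool[rng.integers(0, pool.size)])
            if pool is not None
            else int(rng.integers(1, len(genome.seq) + 1))
        )
        ref = genome.seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        effect = classify_site_effect(genome, pos, alt)
        if effect in ("missense", "nonsense") and rng.random() < nonsyn_removal_prob:
            continue
        out.append(
            {"contig": genome.name, "pos": pos, "ref": ref, "alt": alt, "effect": effect}
        )
    return pd.DataFrame(out).sort_values("pos", kind="stable").reset_index(drop=True)
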