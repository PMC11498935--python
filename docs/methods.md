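# Methods

## The design being modelled

A single tree is sampled at the apices of seven branches plus a cambium
sample at the stem base; DNA is extracted twice per sample (two biological
replicates) and each extraction is genotyped independently. The base
sample defines the reference genotype, so a somatic mutation is an SNV at
which one or more branch tips differ from the base. Because branches
inherit the mutations of the meristem they grew from, the set of tips
carrying each mutation should be a clade of the physical architecture, up
to stochastic loss of mutant cell lineages at branch points.

## Synthetic-data generator

The generator produces every input the analysis consumes, with ground
truth:

- **Genome.** A single contig with configurable length and GC content,
  carrying single-exon genes (ATG…stop, no internal stop, random strand)
  packed one per slot so that every gene keeps ≥ 1 kb upstream and
  ≥ 500 bp downstream of flank, guaranteeing nonempty intergenic space.
  Defaults (100–200 kb, 20–40 genes of 900 bp, GC 0.38) are a scaled-down
  stand-in for a ~350 Mb dipterocarp assembly; per-meter rates are scaled
  up correspondingly (~10⁻⁵–10⁻⁴ /nt/m) so each simulated tree carries the
  few hundred somatic SNVs the real study design yields. All statistical
  properties exercised here (Poisson accumulation, concordance filtering,
  regression, spectra, opportunity counting) are invariant to this joint
  rescaling; what does *not* scale down is the absolute number of callable
  sites, so absolute rate magnitudes in simulations are not comparable to
  published per-nucleotide rates.
- **Architecture.** A rooted tree with branch lengths in meters: a trunk
  (default 25 m) and a random bifurcating crown with internal edges of
  1–6 m and pendant edges of 2–10 m, giving ~40 m tall trees with seven
  tips — the study's geometry. Age enters as height / growth-rate when a
  per-year clock is simulated.
- **Mutations.** Each branch of length L accrues Poisson(2·G·μ·L)
  mutations (G genome length; the 2 is diploidy). Sites are drawn from a
  weighted distribution: `cpg_ct_multiplier` m sets the *realised*
  fold-enrichment of mutations at CpG sites (both the C and the G
  position), implemented as a per-site weight m(1−f)/(1−mf) with f the
  genomic CpG fraction, the excess riding entirely on the C>T (G>A)
  channel. This makes the parameter directly the quantity the CpG
  enrichment statistic estimates; it requires m·f < 1. Colliding sites
  are resampled (infinite-sites approximation). A configurable fraction
  (default 4%, matching the observed share of homozygous calls) of
  mutations is emitted homozygous to exercise collapsing. Inheritance:
  a mutation is carried by the subtree below its originating branch, with
  independent loss probability `loss_prob` (default 0.05) at each daughter
  branch — enough to produce the topology-violating sharing patterns seen
  in real trees without dominating the signal.
- **Call tables.** Two replicates per sample; true sites drop out per
  replicate with `fn_rate`, spurious sites appear per replicate at
  `fp_rate` per genome site (always with the transition alternative
  allele, so a false positive recurring in both replicates is
  self-consistent — the mechanism by which replicate intersection passes
  ≈ fp² of noise). Depth is Poisson around `mean_depth` (default 60×,
  matching the study's coverage) via a keyed deterministic depth model, so
  the same (sample, replicate, site) always yields the same coverage —
  including sites interrogated only by the support filters. The seven
  hard-filter annotations are drawn from a passing mixture and corrupted
  to failing values at configurable rates. Reads themselves are not
  simulated; caller internals, mapping artifacts, and base-quality error
  models are out of scope, so the generator cannot express
  alignment-induced error correlations between replicates — the main
  real-data failure mode the manual-curation step of an actual study
  addresses. Passing tests therefore validate the pipeline's logic, not
  the error structure of any particular sequencing experiment.

## Discovery conventions

- Removal conditions are strict inequalities (a record exactly at a
  threshold is retained), matching GATK `VariantFiltration` expressions;
  a missing annotation fails its filter.
- Records are keyed by (contig, pos, ref, alt, genotype): a heterozygous
  call in one replicate does not match a homozygous call in the other.
- Homozygous sites collapse to one mutation event; genotype conflicts
  across carriers resolve to heterozygous with a warning.
- Inter-individual filters run in order: ±151 bp of an indel; ±151 bp of
  a zero-depth run longer than ten consecutive sites; depth < 5 or above
  the upper bound. The upper bound defaults to d + 3√d (mean plus three
  standard deviations under Poisson-like depth), with a `linear` (4d)
  alternative; the mean d is taken over the whole track before removals.

## Rate estimation

The per-meter rate uses all 21 unordered tip pairs: b = Σxy/Σx², CI from
the t distribution with n−1 degrees of freedom and
SE = √(Σ(y−bx)²/(n−1)/Σx²); μ_g = b/(2R) with CI endpoints transformed
identically. The pairs share path segments and are therefore not
independent observations; the interval deliberately reproduces the
conventional zero-intercept `lm` output rather than correcting for this.
The coverage experiment in `dendrosoma.experiments` measures the
consequence directly: the point estimate is unbiased (relative bias well
under 1% at 200 replicates) but the naive interval covers the generating
rate in far fewer than 95% of replicates, because shared pendant edges
inflate the slope's true sampling variance several-fold over the
residual-based estimate. Users wanting calibrated uncertainty should
bootstrap over mutations or simulate; the reported CI is the field's
conventional one.

Stochastic loss biases the pairwise estimator upward: a mutation arising
above two tips' ancestor and then lost on one side adds a pairwise
difference without any path length. Ratio-based contrasts (slow/fast
species) are unaffected because the bias factor is common; absolute-rate
experiments use `loss_prob = 0`.

The per-year rate divides each tip's mutation count from the base by
2·R·A and summarises across the seven tips with a t-interval. Tip counts
share ancestral branches, so the same caveat applies.

## Neighbor joining and congruence

Standard Saitou–Nei agglomeration; exact Q-ties break toward the
lexicographically smallest pair of cluster labels (a cluster is labelled
by its smallest leaf), making output deterministic. Negative limb lengths
are clamped to zero with the deficit moved to the sister limb, preserving
the joined distance. Newick output quotes labels and prints lengths to
six significant figures. The base sample carries no variants by
construction and is excluded from NJ; congruence is computed over the
seven tips as the Robinson–Foulds distance between non-trivial
bipartition sets, normalised by 2(n−3).

## Spectra

The 96 classes follow COSMIC ordering (C>A, C>G, C>T, T>A, T>C, T>G
blocks; flanks A/C/G/T by 5' then 3'). Purine-centred contexts are
reverse-complemented, an exact 2:1 collapse of the 192 strand-specific
contexts. Genome triplet counts use overlapping windows, skipping windows
containing N. Two normalisations are provided, because "fraction of each
mutated triplet" is ambiguous: the default divides class counts by genome
triplet opportunity and renormalises; the `raw` mode reports plain class
fractions, which is the like-for-like scale for cosine comparison against
COSMIC signatures (themselves defined on raw human-genome fractions).
Both record their mode in the output. Sites lacking a flank are excluded
and tallied.

CpG enrichment is (fraction of SNVs whose mutated base is the C of a CpG
on either strand) / (fraction of genome positions in CpG context).

## Selection test

All 3·L_cds possible CDS mutations are enumerated and classified by the
standard nuclear codon table. The annotated terminal stop codon is
enumerated too: stop-to-stop changes are synonymous and stop-to-sense
(stop-lost) changes are grouped with missense — a deliberate convention
that keeps the opportunity total exactly 3·L_cds while treating
read-through as the protein-altering event it is. CDSs that are not clean
ORFs are excluded and counted. Background rates divide observed SNVs per
collapsed class by the number of region bases at which the class can
occur (C:G bases for C>* classes, T:A bases for T>*), from intergenic
space by default (outside gene bodies extended 1 kb past the start codon
and 500 bp past the stop codon, strand-aware) or the whole genome.
Despite its historical label, p_N is the expected **non**-synonymous
fraction λ_N/(λ_S+λ_N); the observed non-synonymous count is tested
against it with the exact two-sided binomial test (minimum-likelihood
convention, so an observation at the mode gives p = 1). The calibration
experiment draws CDS mutations uniformly over (position, alternative)
pairs and evaluates p_N from the same genome's opportunity table with
uniform class rates — a null under which the observed count is exactly
binomial; the exact test is slightly conservative by discreteness (the
analytic rejection rate at n = 200, p_N ≈ 0.78 is 0.041).

## Growth model

μ = α + βτ with τ the cell-cycle duration in years; rμ = α/τ + β per
year; m(t) = (α/τ + β)t. The slow/fast per-meter ratio
(α+βτ_S)/(α+βτ_F) is monotone in β/α between 1 and τ_S/τ_F, so
`assess_consistency` inverts it where possible: an observed ratio in
(1, τ_S/τ_F) yields x = βτ_F/α exactly; a ratio at or above τ_S/τ_F has
no finite nonnegative solution and is reported as the clock-dominated
(β ≫ α) limit together with the gap to the supremum, rather than being
silently clipped; a ratio ≤ 1 is consistent with replication-dominated
mutagenesis. α and β default to being shared between the species being
compared; the cell-cycle ratio may be derived from growth-increment
ratios when not supplied directly.

## Numerical and interface choices

- Every stochastic stage takes one integer seed; sub-streams derive from
  `numpy` `SeedSequence`s, so all outputs are byte-reproducible and
  pipeline reruns with the same configuration produce identical manifest
  hashes.
- Degenerate inputs raise: single-pair regressions flag an undefined CI;
  NJ requires three taxa and a symmetric matrix; empty depth tracks,
  zero callable sites, non-positive ages, zero vectors in cosines, and
  all-zero presence rows are errors.
- Reporting precision follows field convention: three significant figures
  for rates, two for fold-ratios.
- Reference experiment sizes (100 kb genome, 100–200 simulation
  replicates, 1000-replicate calibration) were chosen so each experiment
  completes in seconds while keeping Monte-Carlo error well inside the
  bands being checked.

## Known limitations

- No read-level simulation: alignment artifacts, index hopping, and
  replicate-correlated errors are outside the generator's vocabulary.
- Isoforms: simulated genes are single-isoform; the all-isoform vs
  primary-isoform distinction of real annotations reduces to the same
  table here.
- The naive rate CI is anticonservative under the pairwise design (see
  above); point estimates and ratio contrasts are the reliable outputs.
- The growth model treats the meristem as a single fixed stem-cell
  lineage; asymmetric stem-cell division and multi-lineage drift are not
  modelled.
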