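"""Reference simulation experiments exercising the whole pipeline.

Each function runs one self-contained computational experiment at the
package's reference conditions — a 100 kb, 20-gene genome standing in for
a ~350 Mb dipterocarp assembly, with per-meter rates scaled up so each
tree carries hundreds of somatic SNVs — and returns plain numbers. They
are the basis of both the acceptance checks and the worked examples in
the documentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .discovery import discover_somatic
from .rates import estimate_rates
from .selection import neutral_rejection_rate
from .simulate import (
    SimConfig,
    generate_architecture,
    generate_genome,
    simulate_call_tables,
    simulate_somatic_mutations,
)
from .spectrum import cpg_enrichment
from .trees import nj_from_matrix, topology_congruence

REFERENCE_GENOME = dict(genome_length=100_000, n_genes=20)


def _seed(master: int, k: int) -> int:
    return (int(master) * 1000 + k) % (2**31 - 1)


def truth_recovery(seed: int = 1) -> dict:
    """Noiseless end-to-end discovery: calls with fp=fn=0 must reproduce
    the simulated mutation matrix exactly."""
    cfg = SimConfig(
        seed=_seed(seed, 1), mu_per_meter=1.25e-5, loss_prob=0.0,
        **REFERENCE_GENOME,
    ).noiseless()
    genome = generate_genome(cfg)
    tree = generate_architecture(seed=_seed(seed, 2))
    matrix, truth = simulate_somatic_mutations(genome, tree, cfg)
    calls = simulate_call_tables(matrix, genome, tree, cfg)
    hq = calls.hq_table_for(sorted(calls.records["pos"].unique()))
    recovered, counts = discover_somatic(calls.records, hq, tree.tips)
    identical = recovered.presence.equals(matrix.presence)
    n = max(matrix.n_sites, recovered.n_sites, 1)
    shared = len(matrix.presence.index.intersection(recovered.presence.index))
    agree = (
        recovered.presence.reindex(matrix.presence.index).fillna(False)
        == matrix.presence
    ).all(axis=1)
    return {
        "identical": bool(identical),
        "fraction_recovered": float(agree.sum() / n) if not identical else 1.0,
        "n_sites": int(matrix.n_sites),
        "shared_sites": shared,
        "stage_counts": counts,
    }


def rate_ci_coverage(
    seed: int = 1, n_reps: int = 200, mu: float = 1e-4
) -> dict:
    """How often the naive zero-intercept 95% CI covers the true rate.

    Loss-free accumulation at a known per-meter rate on a fixed seven-tip
    architecture; the CI is the uncorrected t-interval over the 21
    dependent tip pairs, exactly as the estimator reports it.
    """
    cfg = SimConfig(seed=_seed(seed, 3), mu_per_meter=mu, loss_prob=0.0,
                    **REFERENCE_GENOME)
    genome = generate_genome(cfg)
    tree = generate_architecture(seed=_seed(seed, 4))
    covered = 0
    estimates = []
    for rep in range(n_reps):
        m, _ = simulate_somatic_mutations(genome, tree, cfg, seed=_seed(seed, 10 + rep))
        est = estimate_rates(m, tree, len(genome.seq))
        lo, hi = est.mu_g_ci95
        covered += lo <= mu <= hi
        estimates.append(est.mu_g)
    return {
        "coverage": covered / n_reps,
        "n_reps": n_reps,
        "mean_estimate": float(np.mean(estimates)),
        "true_mu": mu,
    }


def clock_contrast(
    seed: int = 1,
    n_reps: int = 200,
    mu_per_year: float = 1e-5,
    growth_slow: float = 0.25,
    growth_fast: float = 0.8,
) -> dict:
    """Two species, equal per-year rate, 3.2-fold different growth rates.

    Per-meter rate estimates should differ by the growth-rate ratio while
    per-year estimates coincide — the clock signature.
    """
    genome_cfg = SimConfig(seed=_seed(seed, 5), mu_per_meter=1e-5, **REFERENCE_GENOME)
    genome = generate_genome(genome_cfg)
    tree = generate_architecture(seed=_seed(seed, 6))
    out: dict[str, list[float]] = {"mg_slow": [], "mg_fast": [], "my_slow": [], "my_fast": []}
    for rep in range(n_reps):
        for label, g in (("slow", growth_slow), ("fast", growth_fast)):
            cfg = SimConfig(
                seed=_seed(seed, 7), mu_per_meter=None, mu_per_year=mu_per_year,
                growth_rate=g, **REFERENCE_GENOME,
            )
            tree.age = tree.height / g
            m, _ = simulate_somatic_mutations(
                genome, tree, cfg, seed=_seed(seed, 1000 + 2 * rep + (label == "fast"))
            )
            est = estimate_rates(m, tree, len(genome.seq), tree.age)
            out[f"mg_{label}"].append(est.mu_g)
            out[f"my_{label}"].append(est.mu_y_mean)
    return {
        "per_meter_ratio": float(np.mean(out["mg_slow"]) / np.mean(out["mg_fast"])),
        "per_year_ratio": float(np.mean(out["my_slow"]) / np.mean(out["my_fast"])),
        "growth_ratio": growth_fast / growth_slow,
        "n_reps": n_reps,
    }


def nj_congruence(seed: int = 1, n_reps: int = 100) -> dict:
    """Fraction of loss-free simulations whose NJ tree matches the
    generating architecture exactly (RF = 0), at >=20 mutations per tip."""
    cfg = SimConfig(seed=_seed(seed, 8), mu_per_meter=1e-4, loss_prob=0.0,
                    **REFERENCE_GENOME)
    genome = generate_genome(cfg)
    congruent = 0
    used = 0
    for rep in range(n_reps):
        tree = generate_architecture(seed=_seed(seed, 5000 + rep))
        m, _ = simulate_somatic_mutations(genome, tree, cfg, seed=_seed(seed, 9000 + rep))
        if m.per_tip_counts().min() < 20:
            continue
        used += 1
        rf, _ = topology_congruence(nj_from_matrix(m), tree.newick())
        congruent += rf == 0
    return {"fraction_congruent": congruent / max(used, 1), "n_reps": used}


def selection_calibration(
    seed: int = 1, n_null: int = 1000, n_power: int = 200
) -> dict:
    """Type-I error at n=200 neutral mutations and power at 50% purging,
    n=500, of the codon-opportunity binomial test."""
    cfg = SimConfig(seed=_seed(seed, 9), mu_per_meter=1e-5, **REFERENCE_GENOME)
    genome = generate_genome(cfg)
    type1, _ = neutral_rejection_rate(
        genome, n_mutations=200, n_reps=n_null, seed=_seed(seed, 11)
    )
    power, _ = neutral_rejection_rate(
        genome, n_mutations=500, n_reps=n_power, seed=_seed(seed, 12),
        nonsyn_removal_prob=0.5,
    )
    return {"type1_rate": type1, "power": power, "n_null": n_null, "n_power": n_power}


def cpg_recovery(seed: int = 1, n_min: int = 2000, multiplier: float = 4.0) -> dict:
    """Recover the CpG fold-enrichment from simulated spectra."""
    cfg = SimConfig(seed=_seed(seed, 13), mu_per_meter=1e-4,
                    cpg_ct_multiplier=multiplier, **REFERENCE_GENOME)
    genome = generate_genome(cfg)
    tree = generate_architecture(seed=_seed(seed, 14))
    frames = []
    total = 0
    rep = 0
    while total < n_min:
        m, _ = simulate_somatic_mutations(genome, tree, cfg, seed=_seed(seed, 20_000 + rep))
        frames.append(m.presence.index.to_frame(index=False))
        total += len(frames[-1])
        rep += 1
    snvs = pd.concat(frames, ignore_index=True)
    return {
        "fold": float(cpg_enrichment(snvs, genome)),
        "n_snvs": int(len(snvs)),
        "multiplier": multiplier,
    }
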