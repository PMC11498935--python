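"""Somatic mutation-rate estimation per meter of growth and per year.

The per-meter rate mu_g divides the slope b of a zero-intercept regression
of pairwise SNV counts on pairwise physical distance by twice the number of
callable sites R (the factor two reflects diploidy):

    mu_g = b / (2 R)

The per-year rate uses, for each branch tip, the number of mutations M
accumulated from the base and the tree age A:

    mu_y = M / (2 R A)

summarised as the mean and t-based 95% CI over the tips. Pairwise points
share path segments and are therefore not independent; confidence
intervals ignore this, matching the conventional zero-intercept lm fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MutationMatrix
from .trees import PhysicalTree, pairwise_physical_distance, pairwise_snv_distance


@dataclass
class RateEstimate:
    """Per-tree rate estimates and their inputs."""

    slope: float
    slope_ci95: tuple[float, float]
    callable_sites: float
    mu_g: float
    mu_g_ci95: tuple[float, float]
    tip_counts: pd.Series | None = None
    age: float | None = None
    mu_y_per_tip: pd.Series | None = None
    mu_y_mean: float | None = None
    mu_y_ci95: tuple[float, float] | None = None
    n_pairs: int = 0
    extras: dict = field(default_factory=dict)


def regress_through_origin(x, y) -> tuple[float, tuple[float, float]]:
    """Zero-intercept least squares: b = sum(xy)/sum(x^2), t-based 95% CI.

    With n points the slope has n-1 residual degrees of freedom and
    SE = sqrt( sum((y - b x)^2)/(n-1) / sum(x^2) ). A single pair gives a
    slope but an undefined CI, flagged as (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or x.size != y.size:
        raise ValueError("need matching non-empty x and y")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all distances are zero; slope undefined")
    b = float(np.sum(x * y) / sxx)
    n = x.size
    if n < 2:
        return b, (np.nan, np.nan)
    resid = y - b * x
    se = float(np.sqrt(np.sum(resid**2) / (n - 1) / sxx))
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return b, (b - tcrit * se, b + tcrit * se)


def rate_per_meter(
    b: float, callable_sites: float, ci95: tuple[float, float] | None = None
) -> tuple[float, tuple[float, float]]:
    """mu_g = b / (2 R); CI endpoints transformed identically."""
    if callable_sites <= 0:
        raise ValueError("callable sites must be positive")
    mu = b / (2.0 * callable_sites)
    if ci95 is None:
        return mu, (np.nan, np.nan)
    return mu, (ci95[0] / (2.0 * callable_sites), ci95[1] / (2.0 * callable_sites))


def rate_per_year(
    tip_counts, callable_sites: float, age: float
) -> tuple[pd.Series, float, tuple[float, float]]:
    """Per-tip mu_y = M/(2 R A); mean and t-based 95% CI across tips."""
    if age <= 0:
        raise ValueError("tree age must be positive")
    if callable_sites <= 0:
        raise ValueError("callable sites must be positive")
    m = pd.Series(tip_counts, dtype=float)
    if m.empty:
        raise ValueError("no tip counts supplied")
    per_tip = m / (2.0 * callable_sites * age)
    mean = float(per_tip.mean())
    n = len(per_tip)
    if n < 2:
        return per_tip, mean, (np.nan, np.nan)
    se = float(per_tip.std(ddof=1) / np.sqrt(n))
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return per_tip, mean, (mean - tcrit * se, mean + tcrit * se)


def estimate_rates(
    matrix: MutationMatrix,
    tree: PhysicalTree,
    callable_sites: float,
    age: float | None = None,
) -> RateEstimate:
    """Full per-tree estimation from a mutation matrix and architecture.

    Uses all unordered tip pairs for the regression (21 for seven tips) and
    per-tip mutation counts from the base for the per-year rate.
    """
    tips = [t for t in tree.tips if t in matrix.tips]
    dphys = pairwise_physical_distance(tree).loc[tips, tips]
    dsnv = pairwise_snv_distance(matrix).loc[tips, tips]
    iu = np.triu_indices(len(tips), k=1)
    x = dphys.to_numpy()[iu]
    y = dsnv.to_numpy()[iu]
    b, b_ci = regress_through_origin(x, y)
    mu_g, mu_g_ci = rate_per_meter(b, callable_sites, b_ci)
    est = RateEstimate(
        slope=b,
        slope_ci95=b_ci,
        callable_sites=callable_sites,
        mu_g=mu_g,
        mu_g_ci95=mu_g_ci,
        tip_counts=matrix.per_tip_counts().loc[tips],
        age=age,
        n_pairs=len(x),
    )
    if age is not None:
        per_tip, mean, ci = rate_per_year(est.tip_counts, callable_sites, age)
        est.mu_y_per_tip = per_tip
        est.mu_y_mean = mean
        est.mu_y_ci95 = ci
    return est


def species_summary(
    rates_by_tree: dict[str, float], species_by_tree: dict[str, str]
) -> dict:
    """Unweighted per-species mean rates and the slow/fast fold-ratio.

    The ratio reported is the larger species mean over the smaller, with
    the species named, so it reads as "slow is x-fold higher than fast"
    when the slow grower mutates faster per meter.
    """
    trees = set(rates_by_tree)
    if trees - set(species_by_tree):
        raise ValueError("species missing for some trees")
    by_species: dict[str, list[float]] = {}
    for tree_id, mu in rates_by_tree.items():
        by_species.setdefault(species_by_tree[tree_id], []).append(mu)
    means = {sp: float(np.mean(v)) for sp, v in by_species.items()}
    if any(len(v) == 0 for v in by_species.values()) or not means:
        raise ValueError("empty species group")
    out: dict = {"means": means}
    if len(means) == 2:
        (sp_hi, hi), (sp_lo, lo) = sorted(means.items(), key=lambda kv: -kv[1])
        out["ratio"] = hi / lo
        out["ratio_species"] = (sp_hi, sp_lo)
    return out


def estimate_age(dbh: float, mai: float) -> float:
    """Approximate tree age (years) as DBH divided by mean annual increment."""
    if mai <= 0:
        raise ValueError("mean annual increment must be positive")
    return dbh / mai


def growth_ratio(mai_fast: float, mai_slow: float) -> float:
    """Fold-difference in growth rate between fast and slow growers."""
    if mai_fast <= 0 or mai_slow <= 0:
        raise ValueError("MAI values must be positive")
    return mai_fast / mai_slow
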