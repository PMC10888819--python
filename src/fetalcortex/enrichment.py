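"""Expression-scaling association and gene-set enrichment statistics.

Regional gene expression (averaged over specimens at a timepoint, within a
tissue zone) is correlated against parcel-mean allometric scaling with
Kendall's tau-b; BH FDR runs across the whole gene x zone x timepoint batch
of a screen.  Significant genes split by the sign of tau into
hyperallometric (tau > 0) and hypoallometric (tau < 0) sets.  Gene-set
over-representation uses the hypergeometric upper tail P(X >= x) with the
enrichment ratio (x/N)/(K/M); class comparisons use odds ratios with
Fisher's exact test; score-shift tests use a permutation null of medians of
random same-size gene draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .zrt import benjamini_hochberg

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression-scaling association

def expression_scaling_association(region_expression: pd.DataFrame,
                                   parcel_beta: pd.Series,
                                   zone: str = "", timepoint: str = "",
                                   region_subset: list[str] | None = None,
                                   min_regions: int = 5) -> pd.DataFrame:
    """Kendall tau-b per gene between regional expression and scaling.

    ``region_expression``: genes x regions (already averaged over specimens
    at the timepoint and within the zone); ``parcel_beta``: region -> mean
    beta.  ``region_subset`` restricts both to a subset (e.g. neocortex
    only).  Genes with constant expression have undefined tau and are
    excluded from the FDR batch (q left NaN by the caller's batch).
    """
    regions = [r for r in region_expression.columns if r in parcel_beta.index]
    if region_subset is not None:
        regions = [r for r in regions if r in set(region_subset)]
    if len(regions) < min_regions:
        raise ValueError(f"only {len(regions)} regions in common; "
                         f"need >= {min_regions}")
    beta_vec = parcel_beta.loc[regions].to_numpy(dtype=float)
    rows = []
    for gene, row in region_expression[regions].iterrows():
        expr = row.to_numpy(dtype=float)
        ok = np.isfinite(expr) & np.isfinite(beta_vec)
        if ok.sum() < min_regions or np.ptp(expr[ok]) == 0:
            tau, p = np.nan, np.nan
        else:
            tau, p = stats.kendalltau(expr[ok], beta_vec[ok])
        rows.append({"gene": gene, "zone": zone, "timepoint": timepoint,
                     "tau": tau, "p": p, "n_regions": int(ok.sum())})
    return pd.DataFrame(rows)


def associate_batch(records: list[pd.DataFrame], alpha: float = 0.01
                    ) -> pd.DataFrame:
    """Pool association tables into one FDR batch and mark significance."""
    df = pd.concat(records, ignore_index=True)
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    df["direction"] = np.where(df["tau"] > 0, "hyper",
                               np.where(df["tau"] < 0, "hypo", "none"))
    return df


def split_allometric_sets(records: pd.DataFrame, alpha: float = 0.01) -> dict:
    """Partition significant associations into hyper/hypo gene sets."""
    records = records.copy()
    if "direction" not in records.columns:
        records["direction"] = np.where(
            records["tau"] > 0, "hyper",
            np.where(records["tau"] < 0, "hypo", "none"))
    sig = records[(records["q"] < alpha) & records["tau"].notna()]
    hyper = sig[sig["tau"] > 0]
    hypo = sig[sig["tau"] < 0]
    per_zone = (sig.groupby(["zone", "timepoint", "direction"])["gene"]
                .apply(lambda s: sorted(set(s))).to_dict())
    return {
        "hyper": sorted(set(hyper["gene"])),
        "hypo": sorted(set(hypo["gene"])),
        "pooled": sorted(set(sig["gene"])),
        "n_significant_records": int(len(sig)),
        "per_zone": per_zone,
    }


# ---------------------------------------------------------------------------
# enrichment statistics

@dataclass
class EnrichmentResult:
    name: str
    M: int              # background size
    N: int              # set-of-interest size
    K: int              # gene-set size (within background)
    x: int              # overlap
    enrichment_ratio: float
    p: float
    q: float | None = None


def hypergeometric_enrichment(set_of_interest, geneset, background,
                              name: str = "",
                              strict_printed_formula: bool = False
                              ) -> EnrichmentResult:
    """Over-representation of ``geneset`` within ``set_of_interest``.

    All sets are deduplicated and intersected with the background before
    counting.  p = P(X >= x) under Hypergeometric(M, K, N), evaluated with
    log-gamma arithmetic (``hypergeom.sf``).  ``strict_printed_formula``
    switches to the exclusive tail P(X > x).
    """
    bg = set(background)
    interest = set(set_of_interest) & bg
    gs = set(geneset) & bg
    M, N, K = len(bg), len(interest), len(gs)
    x = len(interest & gs)
    if N == 0 or K == 0:
        return EnrichmentResult(name, M, N, K, x, np.nan, 1.0)
    ratio = (x / N) / (K / M)
    if strict_printed_formula:
        p = float(stats.hypergeom.sf(x, M, K, N))       # P(X > x)
    else:
        p = float(stats.hypergeom.sf(x - 1, M, K, N))   # P(X >= x)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return EnrichmentResult(name, M, N, K, x, ratio, p)


def enrichment_batch(set_of_interest, genesets: dict, background
                     ) -> pd.DataFrame:
    """Hypergeometric screen over a dict of gene sets, BH-corrected."""
    results = [hypergeometric_enrichment(set_of_interest, gs, background,
                                         name=nm)
               for nm, gs in genesets.items()]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    return df


def proportion_odds_ratio(p1: float | None = None, p2: float | None = None,
                          counts: tuple[int, int, int, int] | None = None
                          ) -> dict:
    """Odds ratio between two proportions or a 2x2 count table.

    With ``counts = (x1, n1, x2, n2)`` (successes and totals per group) a
    two-sided Fisher exact p accompanies the OR; with proportions only the
    p value is omitted.  Degenerate proportions report the OR symbolically
    ('inf' / '0').
    """
    if counts is not None:
        x1, n1, x2, n2 = counts
        p1, p2 = x1 / n1, x2 / n2
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    else:
        fisher_p = None
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        sym = "inf" if (p1 == 1.0 or p2 == 0.0) else "0"
        return {"odds_ratio": np.inf if sym == "inf" else 0.0,
                "symbolic": sym, "p": fisher_p}
    orat = (p1 / (1 - p1)) / (p2 / (1 - p2))
    return {"odds_ratio": float(orat), "symbolic": None, "p": fisher_p}


@dataclass
class PermutationTestResult:
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    seed: int
    side: str
    p: float
    null_quantiles: dict = field(default_factory=dict)


def permutation_median_test(geneset, score_table: pd.DataFrame,
                            n_perm: int = 10000, seed: int = 0,
                            side: str = "low") -> PermutationTestResult:
    """Median score of a gene set against random same-size draws.

    ``score_table``: columns ``gene``, ``score``.  One-sided
    p = (1 + #{null <= observed}) / (n_perm + 1) for ``side='low'``
    (``>=`` for 'high').
    """
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    scores = score_table.set_index("gene")["score"]
    genes = [g for g in set(geneset) if g in scores.index]
    if len(genes) < 2:
        raise ValueError("gene set must contain >= 2 scored genes")
    observed = float(scores.loc[genes].median())
    universe = scores.to_numpy(dtype=float)
    k = len(genes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.median(rng.choice(universe, size=k, replace=False))
    if side == "low":
        extreme = int((null <= observed).sum())
    elif side == "high":
        extreme = int((null >= observed).sum())
    else:
        raise ValueError("side must be 'low' or 'high'")
    p = (1 + extreme) / (n_perm + 1)
    return PermutationTestResult(
        observed, float(null.mean()), float(null.std(ddof=1)), n_perm, seed,
        side, p, {q: float(np.quantile(null, q)) for q in (0.05, 0.5, 0.95)})
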