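"""Per-gene linear model of expression over zone, region and timepoint.

Each gene's expression across all (specimen, region, zone) samples is fit
with a main-effects-only ordinary least squares model (zone + region +
timepoint, dummy coded).  Each factor is tested with a partial (type II) F
test comparing the full model against the model with that factor removed;
Benjamini-Hochberg FDR is applied across genes separately within each
factor and the ZRT set is the triple intersection of significant genes at
q < alpha (default 0.01).  Zone-wise fold changes between the early and mid
timepoints use log2 ratios of timepoint means with a |log2FC| > 0.3 flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionTensor

FACTORS = ("zone", "region", "time")


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    out = np.zeros((len(codes), n_levels - 1))
    for lev in range(1, n_levels):
        out[codes == lev, lev - 1] = 1.0
    return out


@dataclass
class _Design:
    X_full: np.ndarray
    X_reduced: dict[str, np.ndarray]
    df_factor: dict[str, int]
    n: int

    @property
    def df_resid(self) -> int:
        return self.n - self.X_full.shape[1]


def _build_design(tensor: ExpressionTensor) -> tuple[_Design, np.ndarray]:
    """Flatten the tensor's sample axes into a shared design matrix."""
    S, R, Z = (len(tensor.specimens), len(tensor.regions), len(tensor.zones))
    s_idx, r_idx, z_idx = np.meshgrid(np.arange(S), np.arange(R),
                                      np.arange(Z), indexing="ij")
    s_idx, r_idx, z_idx = s_idx.ravel(), r_idx.ravel(), z_idx.ravel()
    tps = tensor.timepoints()
    tp_levels = sorted(set(tps))
    t_idx = np.array([tp_levels.index(tps[s]) for s in s_idx])

    blocks = {"zone": _dummies(z_idx, Z), "region": _dummies(r_idx, R),
              "time": _dummies(t_idx, len(tp_levels))}
    ones = np.ones((len(s_idx), 1))
    X_full = np.hstack([ones, blocks["zone"], blocks["region"],
                        blocks["time"]])
    X_reduced = {f: np.hstack([ones] + [blocks[g] for g in FACTORS if g != f])
                 for f in FACTORS}
    df_factor = {f: blocks[f].shape[1] for f in FACTORS}
    y = tensor.values.reshape(tensor.values.shape[0], -1)  # (G, n_samples)
    return _Design(X_full, X_reduced, df_factor, len(s_idx)), y


def _rss_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS fits of each row of Y on X."""
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ coef
    return (resid ** 2).sum(axis=0)


def _partial_f(rss_red, rss_full, df_f: int, df_resid: int, tss):
    """Type II F with degenerate cases resolved against the data scale.

    A perfect full fit with remaining factor signal gives F = inf (p -> 0);
    both residuals at numerical zero (factor irrelevant in a perfect fit)
    gives F = 0.
    """
    rss_red = np.asarray(rss_red, dtype=float)
    rss_full = np.asarray(rss_full, dtype=float)
    eps = 1e-10 * np.maximum(np.asarray(tss, dtype=float), 1.0)
    num = np.maximum(rss_red - rss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (num / df_f) / (rss_full / df_resid)
    F = np.where(num <= eps, 0.0, F)
    F = np.where((rss_full <= eps) & (num > eps), np.inf, F)
    p = stats.f.sf(np.where(np.isfinite(F), F, 0.0), df_f, df_resid)
    p = np.where(np.isinf(F), 0.0, p)
    p = np.where(F == 0.0, 1.0, p)
    return F, p


def fit_gene_glms(tensor: ExpressionTensor) -> pd.DataFrame:
    """Type II F statistics and p values per gene and factor.

    Complete genes share one design and are solved in a single vectorised
    pass; genes with missing cells are refit individually with listwise
    deletion.  A factor collapsing to one level after deletion yields NaN
    for that gene-factor (gene flagged unevaluable).
    """
    design, Y = _build_design(tensor)
    G = Y.shape[0]
    complete = np.isfinite(Y).all(axis=1)
    out = {f: {"F": np.full(G, np.nan), "p": np.full(G, np.nan)}
           for f in FACTORS}

    if complete.any():
        Yc = Y[complete]
        tss = ((Yc - Yc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        rss_full = _rss_matrix(design.X_full, Yc)
        df_resid = design.df_resid
        for f in FACTORS:
            rss_red = _rss_matrix(design.X_reduced[f], Yc)
            F, p = _partial_f(rss_red, rss_full, design.df_factor[f],
                              df_resid, tss)
            out[f]["F"][complete] = F
            out[f]["p"][complete] = p

    for g in np.nonzero(~complete)[0]:
        ok = np.isfinite(Y[g])
        yg = Y[g, ok]
        Xf = design.X_full[ok]
        used = Xf[:, 1:].any(axis=0)        # columns with any observation
        Xf = np.hstack([Xf[:, :1], Xf[:, 1:][:, used]])
        df_resid = len(yg) - Xf.shape[1]
        if df_resid < 1:
            continue
        rss_full = _rss_matrix(Xf, yg[None]).item()
        tss_g = ((yg - yg.mean()) ** 2).sum()
        col_offsets = {"zone": (0, design.df_factor["zone"]),
                       "region": (design.df_factor["zone"],
                                  design.df_factor["zone"]
                                  + design.df_factor["region"]),
                       "time": (design.df_factor["zone"]
                                + design.df_factor["region"],
                                design.df_factor["zone"]
                                + design.df_factor["region"]
                                + design.df_factor["time"])}
        for f in FACTORS:
            lo, hi = col_offsets[f]
            keep = np.ones(design.X_full.shape[1] - 1, dtype=bool)
            keep[lo:hi] = False
            keep &= used
            df_f = int(used[lo:hi].sum())
            if df_f < 1:
                continue                    # factor collapsed: unevaluable
            Xr = np.hstack([design.X_full[ok][:, :1],
                            design.X_full[ok][:, 1:][:, keep]])
            rss_red = _rss_matrix(Xr, yg[None]).item()
            F, p = _partial_f(rss_red, rss_full, df_f, df_resid, tss_g)
            out[f]["F"][g] = F
            out[f]["p"][g] = p

    return pd.DataFrame({
        "gene": tensor.genes,
        **{f"F_{f}": out[f]["F"] for f in FACTORS},
        **{f"p_{f}": out[f]["p"] for f in FACTORS},
    })


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q values; NaN p values propagate to NaN q."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_zrt(stats_df: pd.DataFrame, alpha: float = 0.01
                 ) -> tuple[pd.DataFrame, dict]:
    """FDR per factor across genes; ZRT = triple intersection at q < alpha."""
    df = stats_df.copy()
    for f in FACTORS:
        df[f"q_{f}"] = benjamini_hochberg(df[f"p_{f}"].to_numpy())
        df[f"sig_{f}"] = df[f"q_{f}"] < alpha
    df["zrt"] = df["sig_zone"] & df["sig_region"] & df["sig_time"]

    z, r, t = df["sig_zone"], df["sig_region"], df["sig_time"]
    venn = {
        "zone": int(z.sum()), "region": int(r.sum()), "time": int(t.sum()),
        "zone_region": int((z & r).sum()), "zone_time": int((z & t).sum()),
        "region_time": int((r & t).sum()), "zrt": int(df["zrt"].sum()),
        "n_genes": int(len(df)),
    }
    return df, venn


def zone_fold_change(tensor: ExpressionTensor, zone: str,
                     threshold: float = 0.3) -> pd.DataFrame:
    """log2 fold change of each gene between early and mid timepoints.

    Means are taken over specimens x regions within the zone at each
    timepoint; non-positive means leave the fold change undefined (NaN).
    """
    zi = tensor.zones.index(zone)
    tps = tensor.timepoints()
    for needed in ("early", "mid"):
        if needed not in tps:
            raise ValueError(f"timepoint {needed!r} absent for zone {zone}")
    sub = tensor.values[:, :, :, zi]                  # (G, S, R)
    with np.errstate(invalid="ignore"):
        mean_early = np.nanmean(sub[:, tps == "early", :], axis=(1, 2))
        mean_mid = np.nanmean(sub[:, tps == "mid", :], axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.where((mean_early > 0) & (mean_mid > 0),
                          np.log2(mean_mid) - np.log2(mean_early), np.nan)
    return pd.DataFrame({
        "gene": tensor.genes, "zone": zone,
        "mean_early": mean_early, "mean_mid": mean_mid, "log2fc": log2fc,
        "flagged": np.abs(log2fc) > threshold,
    })
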