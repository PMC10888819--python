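"""Probe-level microarray tables to a gene x specimen x region x zone tensor.

The processing chain mirrors standard practice for laser-microdissection
(LMD) microarray data from the prenatal brain: drop unassigned, multi-gene
and absent-flagged probes; score each remaining probe's cross-specimen
reproducibility with differential stability (DS) — the average pairwise
Pearson correlation of its (region, zone) expression profile across
specimens; keep the highest-DS probe per gene and drop genes whose best
probe falls below a DS threshold (default 0.2); average replicate samples
within (specimen, region, zone) cells and drop genes missing in more than a
ceiling fraction of tensor cells (default 10%).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIMEPOINT_CUT_PCW = 16.0     # age <= 16 PCW -> "early", else "mid"


def timepoint_of_age(age_pcw: float) -> str:
    return "early" if age_pcw <= TIMEPOINT_CUT_PCW else "mid"


@dataclass
class ExpressionTensor:
    values: np.ndarray        # (G, S, R, Z), NaN where missing
    genes: list[str]
    specimens: list[str]
    regions: list[str]
    zones: list[str]
    specimen_ages: dict[str, float] = field(default_factory=dict)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def timepoints(self) -> np.ndarray:
        return np.array([timepoint_of_age(self.specimen_ages[s])
                         for s in self.specimens])

    def to_long(self) -> pd.DataFrame:
        g, s, r, z = np.meshgrid(
            np.arange(len(self.genes)), np.arange(len(self.specimens)),
            np.arange(len(self.regions)), np.arange(len(self.zones)),
            indexing="ij")
        df = pd.DataFrame({
            "gene": np.array(self.genes)[g.ravel()],
            "specimen": np.array(self.specimens)[s.ravel()],
            "region": np.array(self.regions)[r.ravel()],
            "zone": np.array(self.zones)[z.ravel()],
            "value": self.values.ravel(),
        })
        return df[np.isfinite(df["value"])].reset_index(drop=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame,
                  specimen_ages: dict[str, float] | None = None
                  ) -> "ExpressionTensor":
        genes = sorted(df["gene"].unique())
        specimens = sorted(df["specimen"].unique())
        regions = sorted(df["region"].unique())
        zones = sorted(df["zone"].unique())
        gi = {g: i for i, g in enumerate(genes)}
        si = {s: i for i, s in enumerate(specimens)}
        ri = {r: i for i, r in enumerate(regions)}
        zi = {z: i for i, z in enumerate(zones)}
        values = np.full((len(genes), len(specimens), len(regions),
                          len(zones)), np.nan)
        values[df["gene"].map(gi), df["specimen"].map(si),
               df["region"].map(ri), df["zone"].map(zi)] = df["value"]
        return cls(values, genes, specimens, regions, zones,
                   specimen_ages or {})


def filter_probes(probes: pd.DataFrame, expression: pd.DataFrame
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop multi-gene, gene-less and absent-flagged probes.

    ``probes``: columns ``probe_id``, ``gene`` (NaN/empty if unassigned),
    ``present_flag``; a probe assigned to several genes appears on several
    rows.  ``expression`` rows are indexed by ``probe_id``.  Returns the
    filtered tables and an audit dict of drop counts.
    """
    probes = probes.copy()
    missing_records = set(expression.index) - set(probes["probe_id"])
    if missing_records:
        raise ValueError(
            f"expression rows without probe record: {sorted(missing_records)[:5]}")

    gene_counts = probes.groupby("probe_id")["gene"].nunique()
    multi = set(gene_counts[gene_counts > 1].index)
    no_gene = set(probes.loc[probes["gene"].isna()
                             | (probes["gene"] == ""), "probe_id"])
    absent = set(probes.loc[~probes["present_flag"].astype(bool), "probe_id"])

    drop = multi | no_gene | absent
    kept = probes[~probes["probe_id"].isin(drop)].drop_duplicates("probe_id")
    audit = {"n_input": int(probes["probe_id"].nunique()),
             "n_multi_gene": len(multi), "n_unassigned": len(no_gene),
             "n_absent": len(absent), "n_retained": int(len(kept))}
    if len(kept) == 0:
        logger.warning("probe filtering removed every probe")
    expr = expression.loc[expression.index.isin(kept["probe_id"])]
    return kept.reset_index(drop=True), expr, audit


def differential_stability(expression: pd.DataFrame, meta: pd.DataFrame,
                           min_overlap: int = 4) -> pd.Series:
    """Average pairwise cross-specimen correlation of each probe's profile.

    ``expression``: probes x samples; ``meta``: per sample ``sample_id``,
    ``specimen_id``, ``region``, ``zone``.  For every specimen pair, the
    Pearson correlation of a probe's expression over (region, zone) cells
    present in both specimens is computed; DS is the mean over pairs with at
    least ``min_overlap`` shared cells.  Probes with no valid pair get NaN.
    """
    specimens = sorted(meta["specimen_id"].unique())
    if len(specimens) < 2:
        raise ValueError("differential stability needs >= 2 specimens")
    # per-specimen (region, zone)-cell matrix, replicates averaged
    cell_tables = {}
    for spec in specimens:
        sel = meta[meta["specimen_id"] == spec]
        cols = [c for c in sel["sample_id"] if c in expression.columns]
        sub = expression[cols]
        key = sel.set_index("sample_id").loc[cols]
        cells = pd.MultiIndex.from_frame(key[["region", "zone"]])
        tab = sub.T.groupby(cells).mean().T   # probes x cells
        cell_tables[spec] = tab

    n_probes = len(expression)
    sums = np.zeros(n_probes)
    counts = np.zeros(n_probes, dtype=int)
    for a, b in itertools.combinations(specimens, 2):
        ta, tb = cell_tables[a], cell_tables[b]
        common = ta.columns.intersection(tb.columns)
        xa = ta[common].to_numpy()
        xb = tb[common].to_numpy()
        both = np.isfinite(xa) & np.isfinite(xb)
        n_common = both.sum(axis=1)
        ok = n_common >= min_overlap
        if not ok.any():
            continue
        xa = np.where(both, xa, np.nan)
        xb = np.where(both, xb, np.nan)
        ma = np.nanmean(xa, axis=1, keepdims=True)
        mb = np.nanmean(xb, axis=1, keepdims=True)
        da = np.nan_to_num(xa - ma)
        db = np.nan_to_num(xb - mb)
        num = (da * db).sum(axis=1)
        den = np.sqrt((da ** 2).sum(axis=1) * (db ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        valid = ok & np.isfinite(r)
        sums[valid] += r[valid]
        counts[valid] += 1
    ds = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(ds, index=expression.index, name="ds")


def select_probe_per_gene(probes: pd.DataFrame, ds: pd.Series,
                          expression: pd.DataFrame,
                          threshold: float = 0.2
                          ) -> tuple[pd.DataFrame, dict]:
    """Keep the max-DS probe per gene; drop genes whose best DS < threshold.

    Ties are broken toward the lexicographically smaller probe_id.  Probes
    with undefined DS are treated as below threshold.  Returns gene-level
    expression (genes x samples) and an audit dict.
    """
    tab = probes[["probe_id", "gene"]].copy()
    tab["ds"] = tab["probe_id"].map(ds)
    tab = tab.sort_values(["gene", "ds", "probe_id"],
                          ascending=[True, False, True],
                          na_position="last")
    best = tab.groupby("gene", sort=True).first().reset_index()
    kept = best[best["ds"].notna() & (best["ds"] >= threshold)]
    dropped = best[~best.index.isin(kept.index)]
    gene_expr = expression.loc[kept["probe_id"]]
    gene_expr.index = pd.Index(kept["gene"], name="gene")
    audit = {"n_genes_in": int(best.shape[0]),
             "n_genes_dropped_low_ds": int(dropped.shape[0]),
             "n_genes_out": int(kept.shape[0])}
    return gene_expr, audit


def aggregate_samples(gene_expr: pd.DataFrame, meta: pd.DataFrame,
                      missing_ceiling: float = 0.10
                      ) -> tuple[ExpressionTensor, dict]:
    """Average replicate samples per (specimen, region, zone) cell.

    Samples whose region or zone is unmapped (NaN) are excluded with a
    warning.  Genes missing in more than ``missing_ceiling`` of tensor cells
    are removed.
    """
    meta = meta.copy()
    bad = meta["region"].isna() | meta["zone"].isna()
    if bad.any():
        logger.warning("excluding %d samples with unmappable region/zone",
                       int(bad.sum()))
        meta = meta[~bad]
    meta = meta[meta["sample_id"].isin(gene_expr.columns)]

    long = gene_expr[meta["sample_id"]].T
    key = pd.MultiIndex.from_frame(
        meta.set_index("sample_id").loc[long.index,
                                        ["specimen_id", "region", "zone"]])
    cells = long.groupby(key).mean().T      # genes x (spec, region, zone)
    cells = cells.sort_index()              # row-order invariance

    specimens = sorted({k[0] for k in cells.columns})
    regions = sorted({k[1] for k in cells.columns})
    zones = sorted({k[2] for k in cells.columns})
    si = {s: i for i, s in enumerate(specimens)}
    ri = {r: i for i, r in enumerate(regions)}
    zi = {z: i for i, z in enumerate(zones)}
    genes = list(cells.index)
    values = np.full((len(genes), len(specimens), len(regions), len(zones)),
                     np.nan)
    for col_idx, (s, r, z) in enumerate(cells.columns):
        values[:, si[s], ri[r], zi[z]] = cells.iloc[:, col_idx]

    frac_missing = (~np.isfinite(values)).reshape(len(genes), -1).mean(axis=1)
    keep = frac_missing <= missing_ceiling
    dropped_genes = [g for g, k in zip(genes, keep) if not k]
    values = values[keep]
    genes = [g for g, k in zip(genes, keep) if k]

    ages = (meta.drop_duplicates("specimen_id")
            .set_index("specimen_id")["age_pcw"].to_dict()
            if "age_pcw" in meta.columns else {})
    tensor = ExpressionTensor(values, genes, specimens, regions, zones, ages)
    audit = {"n_genes_in": len(keep), "n_genes_dropped_missing":
             len(dropped_genes), "n_genes_out": len(genes),
             "dropped_genes": dropped_genes[:50]}
    return tensor, audit


def process_expression(expression: pd.DataFrame, probes: pd.DataFrame,
                       meta: pd.DataFrame, ds_threshold: float = 0.2,
                       missing_ceiling: float = 0.10,
                       min_overlap: int = 4) -> tuple[ExpressionTensor, dict]:
    """Full probe-to-tensor chain with a combined audit."""
    kept_probes, expr, audit_filter = filter_probes(probes, expression)
    ds = differential_stability(expr, meta, min_overlap=min_overlap)
    gene_expr, audit_select = select_probe_per_gene(kept_probes, ds, expr,
                                                    threshold=ds_threshold)
    tensor, audit_agg = aggregate_samples(gene_expr, meta,
                                          missing_ceiling=missing_ceiling)
    return tensor, {"filter": audit_filter, "select": audit_select,
                    "aggregate": audit_agg}
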