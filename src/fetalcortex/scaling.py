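"""Vertexwise allometric scaling of cortical surface area.

For a cohort of subjects sharing one mesh topology, each vertex v is fit
with the log-log model

    log10(a_v) = b0_v + beta_v * log10(A) + eps

where a_v is the vertex's surface area and A the subject's total cortical
area (sum over non-medial-wall vertices).  beta_v reads directly against 1:
beta > 1 is hyperallometric (the vertex expands faster than the cortex as a
whole), beta < 1 hypoallometric.  Before fitting, vertex areas are corrected
for folding bias by regressing out curvature across subjects, smoothed on
the mesh with a kernel calibrated to a target FWHM, and screened for
outliers with an age-sorted sliding window (leave-one-out robust z); scans
aberrant at more than a small fraction of vertices are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic.histology import ConfigurationError
from .synthetic.surfaces import SurfaceCohortData

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))   # approx 2.355


@dataclass
class ScalingConfig:
    fwhm_mm: float = 10.0
    window_size: int = 25
    outlier_z: float = 2.5
    scan_drop_fraction: float = 0.05
    min_scans_per_vertex: int = 10
    curvature_mode: str = "per_vertex"   # or "off"

    def validate(self) -> None:
        if self.fwhm_mm <= 0:
            raise ConfigurationError("FWHM must be positive")
        if self.window_size < 3:
            raise ConfigurationError("window must be >= 3 scans")


@dataclass
class ScalingResult:
    beta: np.ndarray               # (V,), NaN where undefined
    intercept: np.ndarray
    residual_sd: np.ndarray
    n_used: np.ndarray
    parcel_means: pd.DataFrame     # parcel, mean_beta, n_vertices
    excluded_pairs: np.ndarray     # (N, V) bool exclusion mask used
    dropped_scans: list[int] = field(default_factory=list)


def vertex_adjacency(faces: np.ndarray, n_vertices: int) -> list[np.ndarray]:
    neigh = [set() for _ in range(n_vertices)]
    for a, b, c in faces:
        neigh[a].update((b, c)); neigh[b].update((a, c)); neigh[c].update((a, b))
    return [np.fromiter(s, dtype=int) for s in neigh]


def _averaging_operator(faces: np.ndarray, n_vertices: int):
    import scipy.sparse as sp
    adj = vertex_adjacency(faces, n_vertices)
    rows = np.concatenate([np.full(len(a), v) for v, a in enumerate(adj)])
    cols = np.concatenate(adj)
    deg = np.array([len(a) for a in adj], dtype=float)
    vals = 1.0 / deg[rows]
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(n_vertices, n_vertices))


def smooth_metric(values: np.ndarray, faces: np.ndarray,
                  vertices: np.ndarray, fwhm_mm: float,
                  mix: float = 0.5, max_iter: int = 500) -> np.ndarray:
    """Iterated neighbour averaging calibrated to a target kernel FWHM.

    Each step mixes a vertex with the mean of its neighbours
    (``x <- (1-mix) x + mix * nbr_mean``).  The iteration count is
    calibrated on the mesh itself: a delta function is smoothed until the
    width of its kernel at half maximum reaches ``fwhm_mm`` (distances by
    chord length, adequate for kernels much smaller than the surface).
    """
    V = np.asarray(values).shape[-1]
    A = _averaging_operator(faces, V)

    probe = np.zeros(V)
    probe[0] = 1.0
    d = np.linalg.norm(vertices - vertices[0], axis=1)
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        probe = (1 - mix) * probe + mix * (A @ probe)
        reached = d[probe >= probe.max() / 2.0].max()
        if 2.0 * reached >= fwhm_mm:
            n_iter = it
            break

    out = np.atleast_2d(np.asarray(values, dtype=float)).copy()
    for _ in range(n_iter):
        out = (1 - mix) * out + mix * (out @ A.T)
    return out if np.asarray(values).ndim > 1 else out[0]


def correct_vertex_area(cohort: SurfaceCohortData,
                        cfg: ScalingConfig | None = None,
                        smooth: bool = True) -> np.ndarray:
    """Regress curvature out of vertex area and smooth on the mesh.

    At each vertex, across subjects, area is regressed on curvature (OLS)
    and replaced by residual + cross-subject mean; vertices whose curvature
    has zero variance are left untouched.  Smoothing then applies the
    calibrated mesh kernel per subject.
    """
    cfg = cfg or ScalingConfig()
    cfg.validate()
    areas = cohort.areas.astype(float).copy()
    if cfg.curvature_mode != "off":
        curv = cohort.curvature
        cmean = curv.mean(axis=0, keepdims=True)
        dc = curv - cmean
        # partial the curvature slope for overall size (log total area) so
        # cohort-wide growth cannot masquerade as a folding effect, then
        # remove the full curvature deviation with that slope
        logT = np.log10(np.maximum(cohort.total_areas(), 1e-300))
        dT = (logT - logT.mean())[:, None]
        tvar = (dT ** 2).sum()
        bc = (dc * dT).sum(axis=0) / tvar if tvar > 1e-18 else 0.0
        curv_r = dc - bc * dT
        amean = areas.mean(axis=0, keepdims=True)
        rvar = (curv_r ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = (curv_r * (areas - amean)).sum(axis=0) / rvar
        slope = np.where(rvar > 1e-18, slope, 0.0)
        areas = areas - slope[None, :] * dc
    if smooth:
        areas = smooth_metric(areas, cohort.faces, cohort.vertices,
                              cfg.fwhm_mm)
    return areas


def total_area_model(cohort: SurfaceCohortData,
                     areas: np.ndarray | None = None,
                     include_sex: bool = False) -> dict:
    """OLS of log10(total area) on age (weeks), optionally sex and age:sex."""
    ages = cohort.subjects["age"].to_numpy(dtype=float)
    if len(ages) < 10 or np.ptp(ages) < 5.0:
        raise ValueError("need >= 10 subjects spanning >= 5 weeks of age")
    A = cohort.total_areas(areas)
    y = np.log10(A)
    X = {"age": ages}
    if include_sex:
        male = (cohort.subjects["sex"] == "M").to_numpy(dtype=float)
        X["male"] = male
        X["age_x_male"] = ages * male
    Xd = sm.add_constant(pd.DataFrame(X))
    fit = sm.OLS(y, Xd).fit()
    return {"coef": fit.params.to_dict(), "p": fit.pvalues.to_dict(),
            "r2": float(fit.rsquared), "n": int(len(y)), "model": fit}


def window_outlier_mask(cohort: SurfaceCohortData,
                        areas: np.ndarray | None = None,
                        cfg: ScalingConfig | None = None
                        ) -> tuple[np.ndarray, list[int]]:
    """Sliding-window (over age) leave-one-out outlier flags per (scan, vertex).

    Scans are sorted by age; each scan's window holds the up-to
    ``window_size`` nearest scans in sorted order (centred, truncated at the
    ends).  A (scan, vertex) pair is flagged when the area deviates from the
    window mean (computed without the tested scan) by more than
    ``outlier_z`` window SDs.  Scans flagged at more than
    ``scan_drop_fraction`` of vertices are dropped entirely.
    """
    cfg = cfg or ScalingConfig()
    cfg.validate()
    a = cohort.areas if areas is None else areas
    N, V = a.shape
    if N < 3:
        raise ValueError("cohort must contain at least 3 scans")
    order = np.argsort(cohort.subjects["age"].to_numpy(), kind="stable")
    flags = np.zeros((N, V), dtype=bool)
    half = cfg.window_size // 2
    for pos, scan in enumerate(order):
        lo = max(0, min(pos - half, N - cfg.window_size))
        hi = min(N, lo + cfg.window_size)
        member = [order[i] for i in range(lo, hi) if order[i] != scan]
        if len(member) < 2:
            continue
        win = a[member]
        mu = win.mean(axis=0)
        sd = win.std(axis=0, ddof=1)
        dev = np.abs(a[scan] - mu)
        with np.errstate(invalid="ignore"):
            flags[scan] = (sd > 0) & (dev > cfg.outlier_z * sd)
    vertex_frac = flags[:, ~cohort.medial_wall].mean(axis=1)
    dropped = [int(s) for s in np.nonzero(vertex_frac > cfg.scan_drop_fraction)[0]]
    return flags, dropped


def fit_vertex_scaling(cohort: SurfaceCohortData,
                       areas: np.ndarray | None = None,
                       cfg: ScalingConfig | None = None,
                       exclusions: np.ndarray | None = None,
                       dropped_scans: list[int] | None = None,
                       total_areas: np.ndarray | None = None
                       ) -> ScalingResult:
    """Per-vertex OLS of log10(vertex area) on log10(total area).

    ``total_areas`` overrides the predictor (by default the per-scan sum of
    non-medial vertex areas), e.g. to use an externally modelled total.
    """
    cfg = cfg or ScalingConfig()
    cfg.validate()
    a = (cohort.areas if areas is None else areas).astype(float)
    N, V = a.shape
    excl = np.zeros((N, V), dtype=bool) if exclusions is None \
        else exclusions.copy()
    dropped = list(dropped_scans or [])
    excl[dropped, :] = True
    excl[:, cohort.medial_wall] = True
    valid = (~excl) & (a > 0)

    scan_ok = np.ones(N, dtype=bool)
    scan_ok[dropped] = False
    A = cohort.total_areas(a) if total_areas is None \
        else np.asarray(total_areas, dtype=float)
    x = np.where(A > 0, np.log10(np.maximum(A, 1e-300)), np.nan)
    y = np.where(a > 0, np.log10(np.maximum(a, 1e-300)), np.nan)
    valid &= np.isfinite(x)[:, None] & scan_ok[:, None]

    w = valid.astype(float)
    n_used = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xw = np.where(valid, x[:, None], 0.0)
        yw = np.where(valid, y, 0.0)
        xbar = xw.sum(axis=0) / n_used
        ybar = yw.sum(axis=0) / n_used
        dx = np.where(valid, x[:, None] - xbar[None, :], 0.0)
        dy = np.where(valid, y - ybar[None, :], 0.0)
        sxx = (dx * dx).sum(axis=0)
        beta = (dx * dy).sum(axis=0) / sxx
        intercept = ybar - beta * xbar
        resid = np.where(valid, dy - beta[None, :] * dx, 0.0)
        dof = np.maximum(n_used - 2, 1)
        residual_sd = np.sqrt((resid ** 2).sum(axis=0) / dof)

    undef = (n_used < cfg.min_scans_per_vertex) | (sxx <= 0)
    beta[undef] = np.nan
    intercept[undef] = np.nan
    residual_sd[undef] = np.nan

    parcel_means = parcellate_scaling(beta, cohort.parcels,
                                      cohort.medial_wall)
    return ScalingResult(beta, intercept, residual_sd, n_used.astype(int),
                         parcel_means, excl, dropped)


def parcellate_scaling(beta: np.ndarray, parcels: np.ndarray,
                       medial_wall: np.ndarray) -> pd.DataFrame:
    """Unweighted mean of defined vertex betas within each parcel."""
    rows = []
    for p in sorted(set(parcels[parcels >= 0].tolist())):
        sel = (parcels == p) & ~medial_wall
        vals = beta[sel]
        vals = vals[np.isfinite(vals)]
        rows.append({"parcel": int(p),
                     "mean_beta": float(vals.mean()) if len(vals) else np.nan,
                     "n_vertices": int(len(vals))})
    return pd.DataFrame(rows)


def run_scaling(cohort: SurfaceCohortData, cfg: ScalingConfig | None = None
                ) -> ScalingResult:
    """Curvature correction, smoothing, outlier screen, then the vertex fit."""
    cfg = cfg or ScalingConfig()
    corrected = correct_vertex_area(cohort, cfg)
    flags, dropped = window_outlier_mask(cohort, corrected, cfg)
    return fit_vertex_scaling(cohort, corrected, cfg, exclusions=flags,
                              dropped_scans=dropped)
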