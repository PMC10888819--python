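"""Synthetic cortical surface cohorts with a known allometric ground truth.

All subjects share one icosphere topology.  Total surface area grows
log-linearly with gestational age; vertex areas are drawn from the log-log
allometric model

    log10(a_v) = b0_v + beta_v * log10(A) + N(0, noise_sd)

with a per-vertex ``beta_field`` spanning both sides of 1 (isometry).  A
configurable linear leak of curvature into log-area exercises the curvature
correction step, and optional (scan, vertex) outlier injections exercise the
sliding-window outlier screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .histology import ConfigurationError


@dataclass
class SurfaceConfig:
    n_subjects: int = 60
    icosphere_subdivisions: int = 3     # 3 -> 642 vertices, 4 -> 2562
    age_min: float = 21.0               # gestational weeks
    age_max: float = 38.0
    beta_min: float = 0.7
    beta_max: float = 1.3
    noise_sd: float = 0.02              # on log10(vertex area)
    growth_slope: float = 0.054         # log10(total area) per week
    log_area_at_age0: float = 1.8       # log10 mm^2 extrapolated intercept
    curvature_leak: float = 0.0         # added to log10(a_v) per curvature unit
    n_outliers: int = 0                 # (scan, vertex) aberrant injections
    outlier_factor: float = 10.0
    n_parcels: int = 12
    medial_wall_fraction: float = 0.05
    male_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if self.beta_max <= 0:
            raise ConfigurationError("beta range must contain positive values")
        if self.age_max <= self.age_min:
            raise ConfigurationError("degenerate age range")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class SurfaceCohortData:
    vertices: np.ndarray               # (V, 3) template coordinates, mm
    faces: np.ndarray                  # (F, 3)
    areas: np.ndarray                  # (N, V) per-scan vertex area, mm^2
    curvature: np.ndarray              # (N, V) 1/mm
    medial_wall: np.ndarray            # (V,) bool
    parcels: np.ndarray                # (V,) int parcel labels, -1 on medial wall
    subjects: pd.DataFrame             # scan_id, subject_id, age, sex

    @property
    def n_scans(self) -> int:
        return self.areas.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.areas.shape[1]

    def total_areas(self, areas: np.ndarray | None = None) -> np.ndarray:
        a = self.areas if areas is None else areas
        return a[:, ~self.medial_wall].sum(axis=1)


@dataclass
class SurfaceSimTruth:
    cohort: SurfaceCohortData
    beta_field: np.ndarray             # (V,)
    b0_field: np.ndarray               # (V,)
    total_area_curve: pd.DataFrame     # scan_id, age, total_area
    outlier_injections: list[tuple[int, int]] = field(default_factory=list)
    growth_slope: float = 0.0
    noise_sd: float = 0.0
    gen_log_total: np.ndarray | None = None   # (N,) generative log10 A


def _parcellate_sphere(vertices: np.ndarray, n_parcels: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Nearest-seed partition of the sphere (contiguous Voronoi parcels)."""
    seeds = rng.choice(len(vertices), size=n_parcels, replace=False)
    d = vertices @ vertices[seeds].T       # cosine similarity on the sphere
    return d.argmax(axis=1)


def gen_surface_cohort(cfg: SurfaceConfig, seed: int) -> SurfaceSimTruth:
    cfg.validate()
    rng = np.random.default_rng(seed)
    mesh = trimesh.creation.icosphere(subdivisions=cfg.icosphere_subdivisions,
                                      radius=30.0)
    verts = np.asarray(mesh.vertices)
    faces = np.asarray(mesh.faces)
    V = len(verts)
    N = cfg.n_subjects

    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    medial = unit[:, 2] > np.quantile(unit[:, 2], 1.0 - cfg.medial_wall_fraction)
    parcels = _parcellate_sphere(unit, cfg.n_parcels, rng)
    parcels[medial] = -1

    # smooth beta field: low-order spherical harmonics mapped into range
    raw = (np.sin(2.0 * unit[:, 0]) + np.cos(3.0 * unit[:, 1]) * unit[:, 2])
    raw = (raw - raw.min()) / (raw.max() - raw.min())
    beta = cfg.beta_min + raw * (cfg.beta_max - cfg.beta_min)

    ages = np.sort(rng.uniform(cfg.age_min, cfg.age_max, N))
    sexes = np.where(rng.random(N) < cfg.male_fraction, "M", "F")
    logA = cfg.log_area_at_age0 + cfg.growth_slope * ages

    # intercepts chosen so expected vertex areas tile the target total at the
    # cohort's mid age; the fitted slope is unaffected by this choice
    mid_logA = logA.mean()
    weights = rng.dirichlet(np.full(V, 50.0))
    b0 = np.log10(weights) + mid_logA - beta * mid_logA

    log_av = b0[None, :] + beta[None, :] * logA[:, None]
    if cfg.noise_sd > 0:
        log_av = log_av + rng.normal(0.0, cfg.noise_sd, log_av.shape)

    base_curv = rng.normal(0.0, 0.1, V)
    if cfg.curvature_leak != 0.0:
        # subject-varying curvature carries the leak into log-area
        curvature = base_curv[None, :] + rng.normal(0.0, 0.05, (N, V))
        log_av = log_av + cfg.curvature_leak * curvature
    else:
        # identical across subjects: the correction step is then a no-op
        curvature = np.tile(base_curv, (N, 1))

    areas = 10.0 ** log_av

    injections: list[tuple[int, int]] = []
    for _ in range(cfg.n_outliers):
        s = int(rng.integers(0, N))
        v = int(rng.integers(0, V))
        areas[s, v] *= cfg.outlier_factor
        injections.append((s, v))

    subjects = pd.DataFrame({
        "scan_id": [f"scan_{i:03d}" for i in range(N)],
        "subject_id": [f"sub_{i:03d}" for i in range(N)],
        "age": ages, "sex": sexes,
    })
    cohort = SurfaceCohortData(verts, faces, areas, curvature, medial,
                               parcels, subjects)
    curve = pd.DataFrame({"scan_id": subjects.scan_id, "age": ages,
                          "total_area": cohort.total_areas()})
    return SurfaceSimTruth(cohort, beta, b0, curve, injections,
                           cfg.growth_slope, cfg.noise_sd, gen_log_total=logA)
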