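"""Synthetic LMD microarray expression with planted zone/region/time effects.

Each gene follows an additive model on the gene x specimen x region x zone
grid:

    value = baseline + zone_shift[z] + region_shift[r] + time_shift[t(specimen)]
            + N(0, noise_sd)

A gene carries an effect for a factor with the configured probability;
shifts for an active factor are a fixed-spread pattern (an evenly spaced
ramp of half-width ``effect_size`` over the factor's levels, permuted per
gene) so the planted signal strength is the declared one rather than a
random draw.  Genes in the optional ``monotone_region_fraction`` keep the
ramp unpermuted over a supplied region ordering — these seed downstream
expression-vs-scaling association tests.  Missing entries are injected
completely at random at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histology import ConfigurationError

ZONES = ("CP", "SP", "IZ", "SVZ", "VZ")


@dataclass
class ExpressionDesign:
    n_genes: int = 2000
    zones: tuple[str, ...] = ZONES
    n_regions: int = 10
    n_timepoints: int = 2
    specimens_per_timepoint: int = 2
    zone_fraction: float = 0.1
    region_fraction: float = 0.1
    time_fraction: float = 0.1
    monotone_region_fraction: float = 0.0  # of all genes; forces ordered ramp
    effect_size: float = 0.5               # half-width of the level ramp
    noise_sd: float = 0.25
    missing_rate: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    region_order: tuple[int, ...] | None = None  # ordering for monotone genes

    def validate(self) -> None:
        for name in ("zone_fraction", "region_fraction", "time_fraction",
                     "monotone_region_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_genes < 1 or self.n_regions < 2 or self.n_timepoints < 1:
            raise ConfigurationError("degenerate design")


@dataclass
class ExpressionSimTruth:
    values: np.ndarray                 # (G, S, R, Z)
    missing: np.ndarray                # (G, S, R, Z) bool
    genes: list[str]
    specimens: list[str]
    regions: list[str]
    zones: list[str]
    specimen_ages: list[float]         # PCW per specimen
    zrt_flags: pd.DataFrame            # gene, zone_effect, region_effect, time_effect
    effect_sizes: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    monotone_genes: list[str] = field(default_factory=list)

    @property
    def planted_zrt(self) -> list[str]:
        f = self.zrt_flags
        sel = f.zone_effect & f.region_effect & f.time_effect
        return f.loc[sel, "gene"].tolist()

    def to_long(self) -> pd.DataFrame:
        """Long-format table (gene, specimen, region, zone, value)."""
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
        return df[~self.missing.ravel()].reset_index(drop=True)


def _ramp(n_levels: int, half_width: float) -> np.ndarray:
    if n_levels == 1:
        return np.zeros(1)
    return np.linspace(-half_width, half_width, n_levels)


def gen_expression_dataset(design: ExpressionDesign, seed: int) -> ExpressionSimTruth:
    design.validate()
    rng = np.random.default_rng(seed)
    G = design.n_genes
    Z = len(design.zones)
    R = design.n_regions
    n_spec = design.n_timepoints * design.specimens_per_timepoint

    genes = [f"G{i:05d}" for i in range(G)]
    regions = [f"region_{i:02d}" for i in range(R)]
    specimens = [f"spec_{i}" for i in range(n_spec)]
    # early specimens at 15/16 PCW, mid at 21 PCW (two-timepoint default)
    tp_ages = np.linspace(15.0, 21.0, design.n_timepoints)
    spec_tp = np.repeat(np.arange(design.n_timepoints),
                        design.specimens_per_timepoint)
    ages = [float(tp_ages[t]) for t in spec_tp]

    zone_flag = rng.random(G) < design.zone_fraction
    region_flag = rng.random(G) < design.region_fraction
    time_flag = rng.random(G) < design.time_fraction
    n_mono = int(round(design.monotone_region_fraction * G))
    mono_idx = rng.choice(G, size=n_mono, replace=False) if n_mono else np.array([], int)
    region_flag[mono_idx] = True
    mono_set = set(mono_idx.tolist())

    order = (np.asarray(design.region_order, int) if design.region_order is not None
             else np.arange(R))

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, G)
    values = np.empty((G, n_spec, R, Z), dtype=float)
    zone_shifts = np.zeros((G, Z))
    region_shifts = np.zeros((G, R))
    time_shifts = np.zeros((G, design.n_timepoints))

    for g in range(G):
        if zone_flag[g]:
            zone_shifts[g] = rng.permutation(_ramp(Z, design.effect_size))
        if region_flag[g]:
            ramp = _ramp(R, design.effect_size)
            if g in mono_set:
                sh = np.empty(R)
                sh[order] = ramp          # monotone increasing along `order`
                region_shifts[g] = sh
            else:
                region_shifts[g] = rng.permutation(ramp)
        if time_flag[g]:
            time_shifts[g] = rng.permutation(_ramp(design.n_timepoints,
                                                   design.effect_size))

    spec_shift = time_shifts[:, spec_tp]                    # (G, S)
    values = (baseline[:, None, None, None]
              + spec_shift[:, :, None, None]
              + region_shifts[:, None, :, None]
              + zone_shifts[:, None, None, :])
    if design.noise_sd > 0:
        values = values + rng.normal(0.0, design.noise_sd, values.shape)

    missing = rng.random(values.shape) < design.missing_rate

    flags = pd.DataFrame({"gene": genes, "zone_effect": zone_flag,
                          "region_effect": region_flag, "time_effect": time_flag})
    return ExpressionSimTruth(
        values=values, missing=missing, genes=genes, specimens=specimens,
        regions=regions, zones=list(design.zones), specimen_ages=ages,
        zrt_flags=flags,
        effect_sizes={"zone": zone_shifts, "region": region_shifts,
                      "time": time_shifts},
        noise_sd=design.noise_sd,
        monotone_genes=[genes[i] for i in sorted(mono_set)])
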