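"""Synthetic gene sets, probe tables and per-gene score tables.

Emulates the annotation resources used by the enrichment stage: GMT-style
marker lists with a planted enrichment ratio relative to a declared
set-of-interest, a probe table with multi-probe genes and present/absent
flags, and a per-gene score table (e.g. a constraint score) with a planted
low-median subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histology import ConfigurationError


@dataclass
class GeneSetSpec:
    name: str
    size: int
    enrichment_ratio: float = 1.0   # planted (x/N)/(K/M) vs the interest set


@dataclass
class AnnotationConfig:
    n_background: int = 1000
    interest_size: int = 100        # declared set-of-interest drawn uniformly
    genesets: list[GeneSetSpec] = field(default_factory=list)
    probes_per_gene_max: int = 3
    absent_fraction: float = 0.2
    score_mean: float = 0.6
    score_sd: float = 0.0           # 0 -> noiseless planted shift
    shifted_size: int = 50
    score_shift: float = -0.3

    def validate(self) -> None:
        if self.interest_size > self.n_background:
            raise ConfigurationError("interest set larger than background")
        for gs in self.genesets:
            if gs.size > self.n_background:
                raise ConfigurationError(f"gene set {gs.name} exceeds background")
            overlap = gs.enrichment_ratio * self.interest_size * gs.size / self.n_background
            if overlap > min(gs.size, self.interest_size) + 1e-9:
                raise ConfigurationError(
                    f"planted overlap for {gs.name} exceeds set sizes")


@dataclass
class AnnotationSimTruth:
    background: list[str]
    interest: list[str]
    genesets: dict[str, list[str]]
    planted_overlaps: dict[str, int]
    probe_table: pd.DataFrame          # probe_id, gene, present_flag
    score_table: pd.DataFrame          # gene, score
    shifted_genes: list[str]


def write_gmt(genesets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out


def gen_annotation_resources(cfg: AnnotationConfig, seed: int) -> AnnotationSimTruth:
    cfg.validate()
    rng = np.random.default_rng(seed)
    background = [f"G{i:05d}" for i in range(cfg.n_background)]
    bg = np.array(background)
    interest = sorted(rng.choice(bg, cfg.interest_size, replace=False).tolist())
    interest_set = set(interest)
    non_interest = np.array([g for g in background if g not in interest_set])

    genesets: dict[str, list[str]] = {}
    overlaps: dict[str, int] = {}
    for spec in cfg.genesets:
        # expected overlap under the planted ratio r: x = r * N*K/M
        x = int(round(spec.enrichment_ratio * cfg.interest_size * spec.size
                      / cfg.n_background))
        x = min(x, spec.size, cfg.interest_size)
        inside = rng.choice(np.array(interest), x, replace=False).tolist()
        outside = rng.choice(non_interest, spec.size - x, replace=False).tolist()
        genesets[spec.name] = sorted(inside + outside)
        overlaps[spec.name] = x

    # probe table: 1..max probes per gene; distinct cross-specimen noise per
    # probe gives downstream differential-stability structure
    rows = []
    for g in background:
        n_probes = int(rng.integers(1, cfg.probes_per_gene_max + 1))
        for p in range(n_probes):
            rows.append({
                "probe_id": f"{g}_p{p}",
                "gene": g,
                "present_flag": bool(rng.random() >= cfg.absent_fraction),
                "probe_noise_sd": float(rng.uniform(0.05, 0.8)),
            })
    probe_table = pd.DataFrame(rows)

    shifted = sorted(rng.choice(bg, cfg.shifted_size, replace=False).tolist())
    shifted_set = set(shifted)
    scores = np.full(cfg.n_background, cfg.score_mean)
    if cfg.score_sd > 0:
        scores = scores + rng.normal(0.0, cfg.score_sd, cfg.n_background)
    scores = scores + np.array([cfg.score_shift if g in shifted_set else 0.0
                                for g in background])
    score_table = pd.DataFrame({"gene": background, "score": scores})

    return AnnotationSimTruth(background, interest, genesets, overlaps,
                              probe_table, score_table, shifted)
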