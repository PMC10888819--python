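"""End-to-end synthetic study orchestration from a single YAML config.

Stages run in dependency order — synth -> repair -> reconstruct ->
expression -> zrt -> scaling -> associate/enrich — each toggleable, with all
randomness funnelled through named seeds in the config.  The run report is a
machine-readable JSON of per-stage counts (probes dropped, ZRT genes,
significant associations, parcels); re-running with an unchanged config is a
no-op unless forced (content-hash caching on the resolved config).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import expression as expr_mod
from . import reconstruct as rec
from . import repair as rep
from . import scaling as scal
from . import synthetic as syn
from . import zrt as zrt_mod
from .io import save_table

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seeds": {"histology": 11, "expression": 22, "surfaces": 33,
              "annotations": 44, "repair": 55},
    "stages": {"synth": True, "repair": True, "reconstruct": True,
               "expression": True, "zrt": True, "scaling": True,
               "associate": True, "enrich": True},
    "histology": {"n_sections": 6, "height": 96, "width": 96, "n_labels": 4,
                  "tears_per_section": 1, "tear_size_px": 120,
                  "max_rotation_deg": 5.0, "max_translation_px": 4.0},
    "repair": {"theta": 2.5, "patch_size": 256, "patch_overlap": 8},
    "reconstruct": {"k": 2, "voxel_um": 150.0},
    "expression": {"n_genes": 300, "n_regions": 10,
                   "monotone_region_fraction": 0.05,
                   "effect_size": 0.8, "noise_sd": 0.25},
    "zrt": {"alpha": 0.01, "fc_threshold": 0.3},
    "surfaces": {"n_subjects": 30, "icosphere_subdivisions": 2,
                 "noise_sd": 0.02, "n_parcels": 10},
    "scaling": {"fwhm_mm": 10.0, "window_size": 25, "outlier_z": 2.5,
                "scan_drop_fraction": 0.05},
    "associate": {"alpha": 0.01},
    "enrich": {"n_perm": 1000},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def resolve_config(config: dict | None) -> dict:
    return _merge(DEFAULT_CONFIG, config or {})


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def stage_order(stages: dict) -> list[str]:
    order = ["synth", "repair", "reconstruct", "expression", "zrt",
             "scaling", "associate", "enrich"]
    return [s for s in order if stages.get(s)]


def run_pipeline(config: dict | None = None, out_dir=None,
                 force: bool = False) -> dict:
    """Execute enabled stages on synthetic data; return the run report."""
    cfg = resolve_config(config)
    digest = config_digest(cfg)
    out = Path(out_dir) if out_dir else None
    report_path = out / "report.json" if out else None
    if report_path and report_path.exists() and not force:
        old = json.loads(report_path.read_text())
        if old.get("config_digest") == digest:
            logger.info("config unchanged; skipping (use force to rerun)")
            old["skipped"] = True
            return old

    enabled = stage_order(cfg["stages"])
    report: dict = {"schema_version": cfg["schema_version"],
                    "config_digest": digest, "stages_run": enabled,
                    "counts": {}}
    counts = report["counts"]
    seeds = cfg["seeds"]

    truth = tensor = surf = None
    if "synth" in enabled:
        truth = syn.gen_histology_stack(
            syn.HistologyConfig(**cfg["histology"]), seeds["histology"])
        counts["synth_sections"] = truth.clean_stack.n_sections
        counts["synth_artifact_pixels"] = int(truth.artifact_masks.sum())

    if "repair" in enabled:
        if truth is None:
            raise RuntimeError("stage 'repair' needs artifacts from 'synth'")
        rcfg = rep.RepairConfig(**cfg["repair"])
        stack = truth.corrupted_stack
        model = rep.fit_label_appearance(stack.images, stack.labels,
                                         truth.artifact_masks)
        repaired, masks = [], []
        for i in range(stack.n_sections):
            r, m = rep.repair_section(stack.images[i], stack.labels[i],
                                      model, rcfg, seeds["repair"] + i)
            repaired.append(r)
            masks.append(m)
        repaired = np.stack(repaired)
        counts["repair_outlier_pixels"] = int(np.stack(masks).sum())
    else:
        repaired = None

    if "reconstruct" in enabled:
        if truth is None:
            raise RuntimeError("stage 'reconstruct' needs sections from 'synth'")
        images = repaired if repaired is not None \
            else truth.corrupted_stack.images
        graph = rec.build_alignment_graph(images, k=cfg["reconstruct"]["k"])
        tfs = rec.shortest_path_transforms(graph)
        aligned, aligned_lbl = rec.apply_transforms(
            images, truth.corrupted_stack.labels, tfs)
        counts["reconstruct_mean_cost"] = float(np.mean(
            [c for (_, c) in graph.edges.values()]))
        vol = rec.stack_to_volume(aligned, truth.clean_stack.spacing_um,
                                  truth.clean_stack.slice_spacing_um,
                                  cfg["reconstruct"]["voxel_um"])
        counts["reconstruct_volume_shape"] = list(vol.shape)
        if out:
            rec.save_volume_nifti(vol, cfg["reconstruct"]["voxel_um"],
                                  out / "volume.nii.gz")

    if "expression" in enabled:
        sim = syn.gen_expression_dataset(
            syn.ExpressionDesign(**cfg["expression"]), seeds["expression"])
        ages = {s: a for s, a in zip(sim.specimens, sim.specimen_ages)}
        tensor = expr_mod.ExpressionTensor(
            np.where(sim.missing, np.nan, sim.values), sim.genes,
            sim.specimens, sim.regions, sim.zones, ages)
        counts["expression_genes"] = len(tensor.genes)
        expression_truth = sim
    else:
        expression_truth = None

    zrt_table = None
    if "zrt" in enabled:
        if tensor is None:
            raise RuntimeError("stage 'zrt' needs a tensor from 'expression'")
        stats_df = zrt_mod.fit_gene_glms(tensor)
        zrt_table, venn = zrt_mod.classify_zrt(stats_df,
                                               cfg["zrt"]["alpha"])
        counts["zrt_genes"] = venn["zrt"]
        counts["zrt_venn"] = venn
        if out:
            save_table(zrt_table, out / "zrt_stats.tsv")

    scaling_result = None
    if "scaling" in enabled:
        surf = syn.gen_surface_cohort(
            syn.SurfaceConfig(**cfg["surfaces"]), seeds["surfaces"])
        scfg = scal.ScalingConfig(**cfg["scaling"])
        scaling_result = scal.run_scaling(surf.cohort, scfg)
        counts["scaling_parcels"] = int(
            scaling_result.parcel_means["parcel"].nunique())
        counts["scaling_dropped_scans"] = len(scaling_result.dropped_scans)
        if out:
            save_table(scaling_result.parcel_means, out / "parcel_beta.tsv")

    if "associate" in enabled:
        if tensor is None or scaling_result is None:
            raise RuntimeError("stage 'associate' needs 'zrt' and 'scaling'")
        # map tensor regions onto parcels by rank so both sides share labels
        pm = scaling_result.parcel_means.dropna(subset=["mean_beta"])
        pm = pm.sort_values("mean_beta")     # ascending beta onto region order
        n = min(len(pm), len(tensor.regions))
        beta = pd.Series(pm["mean_beta"].to_numpy()[:n],
                         index=tensor.regions[:n])
        tps = tensor.timepoints()
        batches = []
        for zone in tensor.zones:
            zi = tensor.zones.index(zone)
            for tp in sorted(set(tps)):
                sub = tensor.values[..., zi][:, tps == tp, :].mean(axis=1)
                tab = pd.DataFrame(sub, index=tensor.genes,
                                   columns=tensor.regions)
                batches.append(enr.expression_scaling_association(
                    tab, beta, zone=zone, timepoint=tp))
        assoc = enr.associate_batch(batches, cfg["associate"]["alpha"])
        sets = enr.split_allometric_sets(assoc, cfg["associate"]["alpha"])
        counts["associate_significant"] = sets["n_significant_records"]
        counts["associate_unique_genes"] = len(sets["pooled"])
        if out:
            save_table(assoc, out / "associations.tsv")

    if "enrich" in enabled:
        ann = syn.gen_annotation_resources(
            syn.AnnotationConfig(genesets=[syn.GeneSetSpec("planted", 80, 2.0)]),
            seeds["annotations"])
        res = enr.hypergeometric_enrichment(ann.interest,
                                            ann.genesets["planted"],
                                            ann.background, name="planted")
        counts["enrich_ratio"] = res.enrichment_ratio
        counts["enrich_p"] = res.p
        perm = enr.permutation_median_test(
            ann.shifted_genes, ann.score_table,
            n_perm=cfg["enrich"]["n_perm"], seed=seeds["annotations"],
            side="low")
        counts["enrich_permutation_p"] = perm.p

    if expression_truth is not None and zrt_table is not None:
        planted = set(expression_truth.planted_zrt)
        found = set(zrt_table.loc[zrt_table["zrt"], "gene"])
        counts["zrt_planted"] = len(planted)
        counts["zrt_recovered"] = len(planted & found)

    if report_path:
        out.mkdir(parents=True, exist_ok=True)
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
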