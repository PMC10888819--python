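import numpy as np
import pytest

from fetalcortex.synthetic import (
    AnnotationConfig,
    ExpressionDesign,
    GeneSetSpec,
    HistologyConfig,
    SurfaceConfig,
    gen_annotation_resources,
    gen_expression_dataset,
    gen_histology_stack,
    gen_surface_cohort,
)


@pytest.fixture(scope="session")
def small_histology():
    """Six 96x96 sections with one 120-px tear each and misalignments."""
    cfg = HistologyConfig(n_sections=6, height=96, width=96, n_labels=4,
                          tears_per_section=1, tear_size_px=120,
                          max_rotation_deg=5.0, max_translation_px=4.0)
    return gen_histology_stack(cfg, seed=101)


@pytest.fixture(scope="session")
def aligned_histology():
    """Sections without injected misalignment, for repair-only tests."""
    cfg = HistologyConfig(n_sections=5, height=96, width=96, n_labels=4,
                          tears_per_section=1, tear_size_px=200,
                          max_rotation_deg=0.0, max_translation_px=0.0)
    return gen_histology_stack(cfg, seed=202)


@pytest.fixture(scope="session")
def expression_sim():
    design = ExpressionDesign(n_genes=400)
    return design, gen_expression_dataset(design, seed=303)


@pytest.fixture(scope="session")
def surface_sim():
    cfg = SurfaceConfig(n_subjects=40, icosphere_subdivisions=2,
                        noise_sd=0.02)
    return cfg, gen_surface_cohort(cfg, seed=404)


@pytest.fixture(scope="session")
def annotation_sim():
    cfg = AnnotationConfig(
        genesets=[GeneSetSpec("enriched", 80, 2.0),
                  GeneSetSpec("uniform", 60, 1.0)])
    return cfg, gen_annotation_resources(cfg, seed=505)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
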