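import numpy as np
import pandas as pd
import pytest

from mirpathnet import ExpressionMatrix, GeneratorConfig, PipelineConfig, SampleAnnotation, generate
from mirpathnet.pipeline import run_pipeline_on_bundle

#: bundle seed used for all frozen-seed recovery checks
DEFAULT_BUNDLE_SEED = 2024


def make_annotation(samples, conditions, mutations=None):
    mut = pd.Series(mutations, index=samples) if mutations is not None else None
    return SampleAnnotation(pd.Series(conditions, index=samples), mut)


def make_matrix(values, features, samples, conditions, kind="gene"):
    ann = make_annotation(samples, conditions)
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), kind, ann)


@pytest.fixture(scope="session")
def default_bundle():
    """The frozen default synthetic bundle: planted 5-gene path (shift 1.5
    sigma), ten miRNA-target pairs at rho=-0.8, two circuits per topology."""
    return generate(GeneratorConfig(seed=DEFAULT_BUNDLE_SEED))


@pytest.fixture(scope="session")
def default_pipeline_result(default_bundle):
    """Full pipeline run on the frozen default bundle (both comparisons)."""
    b = default_bundle
    cfg = PipelineConfig(
        gene_matrix="", mirna_matrix="", annotation="", pathways="",
        predictions="", validated="", tf_mirna="", tf_gene="",
        comparisons={"case_vs_a": ("case", "ctrl_a"), "case_vs_b": ("case", "ctrl_b")},
        seed=7, n_perm=500,
    )
    return run_pipeline_on_bundle(
        cfg, b.gene_mat, b.mirna_mat, b.pathways, b.predictions, b.validated, b.catalog
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
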