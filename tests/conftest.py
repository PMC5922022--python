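import numpy as np
import pandas as pd
import pytest

import stromabalance as sb


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cohort():
    """A small single cohort with planted genes and histopathology."""
    cfg = sb.TissueProfileConfig(n_genes=600, n_cancer_samples=60, n_normal_samples=30, seed=11)
    return sb.generate_cohort(cfg, "small")


@pytest.fixture(scope="session")
def default_suite():
    """The standard five-cohort synthetic study (shared latent profiles)."""
    return sb.default_study_suite(seed=1)


def _run_default_pipeline(suite, out_dir, geneset_cohort=None, exclude=None):
    specs = sb.write_suite(suite, out_dir / "inputs")
    config = sb.PipelineConfig(
        cohorts=tuple(sb.CohortSpec(**s) for s in specs),
        out_dir=str(out_dir / "out"),
        n_top=sb.DEFAULT_SUITE_N_TOP,
        gsea_sizes=sb.DEFAULT_SUITE_GSEA_SIZES,
        seed=1,
        geneset_cohort=geneset_cohort,
        exclude=exclude,
    )
    return sb.run_pipeline(config)


@pytest.fixture(scope="session")
def default_pipeline(default_suite, tmp_path_factory):
    """Full workflow run on the default suite (gene-sets from cohort 1)."""
    out = tmp_path_factory.mktemp("pipeline_default")
    return _run_default_pipeline(default_suite, out)


def matrix_from(values, gene_ids=None, sample_ids=None, cohort_id="t"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    return sb.ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), cohort_id)
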