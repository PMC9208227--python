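import numpy as np
import pandas as pd
import pytest

from caneqtl import preprocess
from caneqtl.synthdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared across read-only tests."""
    cfg = SimConfig(n_samples=120, n_genes=25, n_variants=1200, seed=17,
                    effect_r2=0.25)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared_cohort(small_cohort):
    """QC'd genotypes, normalized/transformed expression and covariates."""
    c = small_cohort
    geno = preprocess.filter_genotypes(c.genotypes)
    gpcs = preprocess.genotype_pcs(geno, 5)
    expr = preprocess.filter_genes(c.expression)
    preprocess.normalize_expression(expr)
    hf = preprocess.hidden_factors(expr, 5)
    preprocess.transform_expression(expr)
    covars = preprocess.build_covariates(gpcs, hf, c.sex)
    return c, geno, expr, covars


@pytest.fixture
def rng():
    return np.random.default_rng(0)
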