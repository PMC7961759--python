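import numpy as np
import pytest

from mprog import CohortSpec, log_transform, simulate_cohort, top_variable_genes
from mprog.preprocess import correct_batch


@pytest.fixture(scope="session")
def small_spec():
    """Reduced cohort: 65 samples, 600 genes — fast enough for clustering."""
    return CohortSpec(n_per_subtype=(20, 15, 20, 10), n_genes=600,
                      n_signature_up=15, n_signature_down=10,
                      n_program_genes=15, n_cpg=400, n_cpg_variable=80,
                      n_cpg_dm=80, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_log_expr(small_cohort):
    logm = log_transform(small_cohort.expression)
    return correct_batch(logm, small_cohort.annotations["batch"])


@pytest.fixture(scope="session")
def small_top_expr(small_log_expr):
    return small_log_expr.subset_genes(top_variable_genes(small_log_expr, 300))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size study-structure cohort (179 samples)."""
    return simulate_cohort(CohortSpec(n_genes=3000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
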