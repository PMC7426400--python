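import numpy as np
import pytest

from methdrug.synthetic import CohortSpec, generate_cohort, generate_genome_annotation


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(n_cells=60, n_drugs=6, n_mut_genes=80, n_expr_genes=80, n_cnv_genes=80, n_cpg=120, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_annotation(small_spec):
    return generate_genome_annotation(small_spec, frac_cpg_in_tfbs=0.5, seed=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
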