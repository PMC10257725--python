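import numpy as np
import pandas as pd
import pytest

import gripvar as gv


@pytest.fixture(scope="session")
def small_cohort():
    """A PTV-rich null cohort small enough for brute-force cross-checks."""
    spec = gv.SimSpec(
        n_samples=3000,
        n_genes=60,
        seed=11,
        variants_per_gene=5.0,
        rare_maf_range=(2e-4, 9.9e-4),
        class_proportions={"ptv": 0.5, "missense": 0.3, "synonymous": 0.2},
        n_common_variants=60,
        x_gene_fraction=0.1,
    )
    return gv.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    return gv.build_design(small_cohort.covariates)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
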