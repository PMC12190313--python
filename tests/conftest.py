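import numpy as np
import pytest

from admixscan.core import GenotypeMatrix, VariantRecord
from admixscan.simdata import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """150 samples x 400 variants, 2% missing, default five-cluster structure."""
    return simulate_cohort(
        CohortSpec(n_samples=150, n_variants=400, missingness=0.02, seed=7)
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """300 samples x 200 variants with 12 planted ancestry-enriched sites."""
    return simulate_cohort(
        CohortSpec(n_samples=300, n_variants=200, n_planted=12, seed=11)
    )


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(0)
    g = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(8, 60)).astype(float)
    recs = [VariantRecord("1", 100 + i, "A", "G") for i in range(60)]
    return GenotypeMatrix(g, [f"s{i}" for i in range(8)], recs)
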