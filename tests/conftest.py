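import numpy as np
import pytest

from cnvbuffer.cohort import OmicsCohort
from cnvbuffer.preprocess import zscore_rows
from cnvbuffer.simulate import SimulationConfig, simulate_cohort

# map generator class names to classifier labels
TRUTH_TO_LABEL = {
    "non": "non_attenuated",
    "low": "low_attenuated",
    "high": "high_attenuated",
}


def standardized(cohort: OmicsCohort) -> OmicsCohort:
    """Cohort with z-scored (feature-wise) mRNA/protein/phospho matrices."""
    mats = {
        name: zscore_rows(getattr(cohort, name).T).T.reindex(cohort.samples, axis=0)
        for name in ("mrna", "protein", "phospho")
    }
    return OmicsCohort(cnv=cohort.cnv, covariates=cohort.covariates, **mats)


SMALL = dict(n_samples=120, n_genes=400, n_complexes=30, seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(**SMALL))


@pytest.fixture(scope="session")
def small_cohort_z(small_cohort):
    cohort, truth = small_cohort
    return standardized(cohort), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
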