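import numpy as np
import pytest

from psiloconn import pipeline, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort_analysis():
    """One fully analyzed default cohort (15 ADE + 6 control), shared across tests."""
    cohort = synthetic.generate_cohort(15, 6, seed=1)
    return cohort, pipeline.analyze_cohort(cohort, seed=7)
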