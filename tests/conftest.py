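import numpy as np
import pytest

from varcohort.annotation import annotate_cohort
from varcohort.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim_result():
    """Default-sized simulated cohort shared by the unit-test modules."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def callsets(sim_result):
    return sim_result.cohort.to_callsets(sim_result.reference)


@pytest.fixture(scope="session")
def cohort_annotation(sim_result, callsets):
    return annotate_cohort(
        callsets,
        sim_result.transcripts,
        sim_result.reference,
        mito_contigs=sim_result.config.mito_contigs,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
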