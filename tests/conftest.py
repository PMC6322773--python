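import pytest

from tapeweight.fixtures import fixture_calibrations, fixture_reference
from tapeweight.pipeline import apply_estimators, derive_indicators
from tapeweight.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return fixture_reference()


@pytest.fixture(scope="session")
def calibrations(reference):
    return fixture_calibrations(reference)


@pytest.fixture(scope="session")
def cohort(reference):
    """A mid-sized simulated cohort with latent truth retained."""
    return simulate_cohort(SimulationConfig(n=5000, seed=11), reference)


@pytest.fixture(scope="session")
def prepared_cohort(cohort, reference, calibrations):
    """Cohort with indicators derived and all four tape estimates attached."""
    df, _ = derive_indicators(cohort.records, reference)
    df, _ = apply_estimators(df, calibrations)
    return df
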