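import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from birthlink.synthetic import SimConfig, emit_records, simulate_population


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two cohort-years at desk scale, default data-quality parameters."""
    return SimConfig(years=(2001, 2002), births_per_year=2000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    truth = simulate_population(small_config)
    records = emit_records(truth, small_config)
    return truth, records


@pytest.fixture(scope="session")
def linked_analysis(small_cohort):
    """Error-free oracle linkage and filtered analysis set for the cohort."""
    from birthlink.linkage import oracle_link
    from birthlink.preprocess import build_analysis_set

    truth, records = small_cohort
    result = oracle_link(records, 0.0, 0.0, seed=1)
    return truth, records, result, build_analysis_set(result)
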