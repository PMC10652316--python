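import pytest
from hypothesis import settings

import escc_meta as em

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_data():
    """Packaged evidence base: (records, analysis sets)."""
    return em.table1_fixture()


@pytest.fixture(scope="session")
def analysis_effects(fixture_data):
    """log-OR effect lists keyed by 'variant/model' for each packaged analysis."""
    studies, sets = fixture_data
    return {
        f"{s.variant}/{s.model}": [em.effect_from_record(r) for r in s.resolve(studies)]
        for s in sets
    }


@pytest.fixture(scope="session")
def fixture_pipeline_table(fixture_data):
    _, sets = fixture_data
    return em.run_pipeline(em.AnalysisConfig(analyses=tuple(sets)))
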