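import pytest
from hypothesis import HealthCheck, settings

import emtscore as es

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_model():
    """Frozen reference MLR model (deterministic, trained once per session)."""
    return es.reference_model()


@pytest.fixture(scope="session")
def population():
    """Default mixed cohort: 40 E, 40 M, 20 hybrid, 20 admixture samples."""
    return es.generate_population(es.PopulationSpec(seed=7))


@pytest.fixture(scope="session")
def score_table(population, ref_model):
    """All three methods joined on the default cohort."""
    expr, labels, sigs = population
    table = (
        es.score_76gs(expr, sigs["76GS"])
        .join(es.score_ks(expr, sigs["KS"]))
        .join(es.score_mlr(expr, sigs["MLR"], ref_model))
    )
    return table, labels
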