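import pytest

from speechgraphs import GeneratorConfig, MetricConfig, generate_cohort
from speechgraphs.examples import cookie_jar_response, example_corpus, two_frame_response


@pytest.fixture
def cookie_response():
    return cookie_jar_response()


@pytest.fixture
def scene_response():
    return two_frame_response()


@pytest.fixture
def tiny_corpus():
    return example_corpus()


@pytest.fixture
def fast_metrics():
    """Reduced-replicate metric config for unit tests."""
    return MetricConfig(replicates=50, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6 participant synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_cases=6, n_controls=6, seed=42))
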