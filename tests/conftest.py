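import pytest
from hypothesis import HealthCheck, settings

from trialpub.config import AppConfig
from trialpub.pipeline import run_pipeline
from trialpub.synthetic import CorpusSpec, generate_corpus, make_paper_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec() -> CorpusSpec:
    return CorpusSpec(n_interventional=200, n_observational=40, n_registry=10, seed=7)


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return generate_corpus(small_spec)


@pytest.fixture(scope="session")
def small_result(small_spec, small_corpus):
    return run_pipeline(
        small_corpus.studies, small_corpus.articles, AppConfig(), small_spec.as_of
    )


@pytest.fixture(scope="session")
def paper_fixture_studies():
    return make_paper_fixture()


@pytest.fixture(scope="session")
def default_config() -> AppConfig:
    return AppConfig()
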