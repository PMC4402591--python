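import pytest

from kdse import build_index
from kdse.synthetic_corpus import SynthParams, generate, paper_fixtures


@pytest.fixture(scope="session")
def fixtures_bundle():
    return paper_fixtures()


@pytest.fixture(scope="session")
def fixtures_index(fixtures_bundle):
    return build_index(
        fixtures_bundle.corpus, fixtures_bundle.drugs, fixtures_bundle.ses
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A modest confounded corpus shared by read-only tests."""
    return generate(
        SynthParams(
            n_drugs=20,
            n_ses=45,
            n_abstracts=80,
            confound_rate=0.3,
            prior_coverage=0.6,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_index(small_bundle):
    return build_index(small_bundle.corpus, small_bundle.drugs, small_bundle.ses)
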