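import random

import pytest

from beltograph import DictionaryGrounder, fetch_article, filter_paragraphs
from beltograph.synthetic import (
    FIXTURE_PMCID,
    FixtureArticleClient,
    make_fixture_backend,
)


@pytest.fixture()
def fixture_doc():
    """The packaged synthetic article, fetched through the fixture client."""
    return fetch_article(FIXTURE_PMCID, FixtureArticleClient())


@pytest.fixture()
def filtered_doc(fixture_doc):
    return filter_paragraphs(fixture_doc, mode="rules")


@pytest.fixture()
def grounder():
    return DictionaryGrounder()


@pytest.fixture()
def stub_backend():
    return make_fixture_backend()


@pytest.fixture()
def rng():
    return random.Random(20240901)
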