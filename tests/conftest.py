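from __future__ import annotations

import pytest

from vapescope.corpus import default_location_lexicon, default_vaping_lexicon
from vapescope.synthetic import CorpusSpec, generate_corpus


@pytest.fixture(scope="session")
def loc_lexicon():
    return default_location_lexicon()


@pytest.fixture(scope="session")
def vap_lexicon():
    return default_vaping_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """A moderately contaminated labeled corpus shared across read-only tests."""
    return generate_corpus(CorpusSpec(n_posts=2000, seed=11))


def clean_ids(records):
    return {r.post_id for r in records if r.truth_labels["kind"] == "clean"}


def kind_ids(records, kind):
    return {r.post_id for r in records if r.truth_labels["kind"] == kind}
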