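"""Shared fixtures: the standard synthetic world, built once per session.

The standard fixture is 6 categories x 50 words in 50 dimensions
(intra-cluster cosine >= 0.9, inter-centroid <= 0.3), 25 studies x 17
samples with one value per category per sample, and 200 titles with
planted spans.  The full pipeline over it runs in about a second, so
building it once keeps the suite cheap while letting every stage be
tested against the same world.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from metaner import (
    AttributeMerger,
    FixtureSpec,
    TitleExtractor,
    build_corpus,
    make_records,
    make_titles,
    make_toy_embedding,
    train_classifier,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

SEED = 0

# the profile threshold is scaled to the fixture corpus (~425 records per
# category across 4 variants, the rarest ~10%), keeping every planted
# variant profiled
FIXTURE_MIN_FREQUENCY = 25


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=SEED)


@pytest.fixture(scope="session")
def toy_model(spec):
    return make_toy_embedding(spec)


@pytest.fixture(scope="session")
def fixture_records(spec, toy_model):
    return make_records(spec, toy_model)


@pytest.fixture(scope="session")
def merger(spec, toy_model, fixture_records):
    records, _ = fixture_records
    return AttributeMerger(
        embedding=toy_model, seeds=spec.seeds(),
        min_frequency=FIXTURE_MIN_FREQUENCY, random_state=SEED,
    ).fit(records)


@pytest.fixture(scope="session")
def corpus_split(toy_model, merger, fixture_records):
    records, _ = fixture_records
    harmonized = merger.transform(records)
    return build_corpus(harmonized, toy_model, merger.schema_.categories,
                        seed=SEED)


@pytest.fixture(scope="session")
def trained_clf(corpus_split, toy_model):
    return train_classifier(corpus_split, toy_model, random_state=SEED)


@pytest.fixture(scope="session")
def title_fixtures(spec, toy_model):
    return make_titles(spec, toy_model)


@pytest.fixture(scope="session")
def extractor(trained_clf, toy_model, corpus_split):
    return TitleExtractor(trained_clf, toy_model, corpus_split.categories)


@pytest.fixture(scope="session")
def predictions(extractor, title_fixtures):
    return extractor.predict_titles(
        [(t.sample_id, t.title) for t in title_fixtures])


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
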