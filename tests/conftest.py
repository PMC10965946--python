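import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import psphunter as psp

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

# Study conditions for the shared synthetic cohort: large enough that the
# planted signal is learnable and localizable, small enough that the whole
# chain (embedding + forest + scans) trains in seconds.
BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle() -> psp.FixtureBundle:
    return psp.make_fixture_bundle(psp.FixtureConfig(
        n_pos=40, n_neg=40, length_range=(150, 450), seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def embedding_model(bundle) -> psp.EmbeddingModel:
    return psp.fit_embedding(psp.build_corpus(bundle.records), epochs=3,
                             seed=BUNDLE_SEED + 1)


@pytest.fixture(scope="session")
def extractor(bundle, embedding_model) -> psp.FeatureExtractor:
    return psp.FeatureExtractor(
        embedding=embedding_model, annotations=bundle.tables,
        ppi=bundle.graph, tracks=bundle.tracks)


@pytest.fixture(scope="session")
def feature_table(bundle, extractor) -> dict[str, np.ndarray]:
    return {r.id: extractor.vector(r).concat() for r in bundle.records}


@pytest.fixture(scope="session")
def dataset(bundle, feature_table) -> psp.LabeledDataset:
    return psp.assemble_splits(
        bundle.positives, bundle.negatives, feature_table,
        repeats=1, seed=BUNDLE_SEED + 2,
        feature_names=psp.feature_names())[0]


@pytest.fixture(scope="session")
def model(dataset) -> psp.TrainedModel:
    full = psp.train_model(dataset, n_trees=300, seed=BUNDLE_SEED + 3)
    return psp.select_features(full, dataset, k=60)
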