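import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import microlit as ml

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The deterministic 10-document fixture suite on disk."""
    out = tmp_path_factory.mktemp("fixture")
    ml.emit_fixture_suite(out)
    return out


@pytest.fixture(scope="session")
def fixture_corpus():
    return ml.fixture_corpus()


@pytest.fixture(scope="session")
def gazetteer():
    return ml.Gazetteer.default()


@pytest.fixture(scope="session")
def fixture_dicts(fixture_dir):
    return ml.load_dictionaries([fixture_dir / "dictionaries.tsv"])


@pytest.fixture(scope="session")
def study_run():
    """One full synthetic study at the default condition (2,000 docs):
    the planted model, its ground truth, and a trained embedding."""
    spec = ml.PlantedModel.default(n_docs=2000, seed=1)
    corpus, truth = ml.generate_corpus(spec)
    docs = ml.preprocess_corpus(corpus)
    model = ml.train_embeddings(docs, seed=1)
    return spec, truth, model


@pytest.fixture(scope="session")
def hand_model():
    """50 hand-vectored terms (25 diseases x 25 microbes) in 8 dimensions,
    plus the terms-by-class map; the oracle playground for exact network
    tests."""
    rng = np.random.default_rng(2024)
    diseases = [f"disease{i:02d}" for i in range(25)]
    microbes = [f"microbe{i:02d}" for i in range(25)]
    vectors = {t: rng.normal(size=8) for t in diseases + microbes}
    model = ml.EmbeddingModel.from_vectors(vectors)
    return model, {"disease": diseases, "microbe": microbes}


def brute_force_edges(model, terms_a, terms_b, theta):
    """Independent all-pairs thresholding using only the scalar cosine
    helpers; the oracle that network construction must match exactly."""
    edges = set()
    for a in terms_a:
        va = model.term_vector(a)
        if va is None:
            continue
        for b in terms_b:
            vb = model.term_vector(b)
            if vb is None:
                continue
            if ml.cosine_distance(va, vb) <= theta:
                edges.add(frozenset((a, b)))
    return edges
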