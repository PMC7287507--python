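import warnings

import pytest

from mainfinder import (HashingEmbeddingProvider, build_feature_matrix,
                        fit_pipeline, generate_synthetic_corpus,
                        load_stop_words)
from mainfinder.patterns import mine_pattern_table

# scikit-learn convergence chatter and the miners' intentional warnings are
# part of normal operation on small corpora
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def stop_words():
    return load_stop_words()


@pytest.fixture(scope="session")
def provider():
    return HashingEmbeddingProvider(dimension=64)


@pytest.fixture(scope="session")
def synth_train():
    return generate_synthetic_corpus(200, seed=101)


@pytest.fixture(scope="session")
def synth_test():
    return generate_synthetic_corpus(200, seed=202)


@pytest.fixture(scope="session")
def mined_table(synth_train):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mine_pattern_table(synth_train)


@pytest.fixture(scope="session")
def feature_matrix(synth_train, mined_table, provider, stop_words):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X, y, keys = build_feature_matrix(synth_train, mined_table, provider,
                                          stop_words)
    return X, y, keys


@pytest.fixture(scope="session")
def trained_pipeline(synth_train, mined_table, provider, stop_words):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_pipeline(synth_train, "svc_rbf", seed=7, provider=provider,
                            stop_words=stop_words, table=mined_table)
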