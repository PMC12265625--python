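import numpy as np
import pytest

import scmeninges as sm


@pytest.fixture(scope="session")
def small_atlas():
    """4-cluster, 600-gene reference atlas with gene annotation."""
    return sm.generate_reference_atlas(4, 600, seed=11)


@pytest.fixture(scope="session")
def qc_fixture():
    return sm.generate_qc_fixture(seed=5)


@pytest.fixture(scope="session")
def gradient():
    return sm.simulate_layer_gradient(
        ["pia", "arachnoid", "dura"], 4, 40, seed=3)


@pytest.fixture(scope="session")
def small_corpus():
    """3-topic corpus small enough to fit repeatedly in tests."""
    return sm.simulate_topic_corpus(3, 60, 120, 300, alpha=0.1, seed=7)


@pytest.fixture(scope="session")
def fitted_model(small_corpus):
    corpus, _ = small_corpus
    return sm.fit_lda(corpus, n_topics=3, iterations=400, burn_in=100, seed=7)


def matched_cosine(A: np.ndarray, B: np.ndarray):
    """Hungarian-matched row cosines between two topic-gene matrices."""
    from scipy.optimize import linear_sum_assignment

    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    C = An @ Bn.T
    r, c = linear_sum_assignment(-C)
    return C[r, c], c
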