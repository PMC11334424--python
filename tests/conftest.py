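from __future__ import annotations

import numpy as np
import pytest

from kofunclust import preprocess as pp
from kofunclust import synthetic_data as sd

#: small planted scenario reused across modules (3 clusters, strong markers)
SMALL_SPEC = sd.ScenarioSpec(
    n_kos=300, samples_per_cluster=(30, 30, 30), seed=11
)


@pytest.fixture(scope="session")
def small_data():
    return sd.generate(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_norm(small_data):
    counts, *_ = small_data
    return pp.clr_normalize(pp.filter_rare_kos(counts))


@pytest.fixture(scope="session")
def small_truth(small_data):
    return small_data[4]


@pytest.fixture(scope="session")
def small_labels(small_norm, small_truth):
    return small_truth.labels(small_norm.sample_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
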