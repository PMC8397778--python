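import numpy as np
import pandas as pd
import pytest

import soilsdm as s
from soilsdm.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_dataset():
    """Small niche-structured community for fast unit tests."""
    return s.generate_dataset(n_sites=60, n_otus=6, dispersion=1.0, seed=7)


@pytest.fixture(scope="session")
def medium_dataset():
    """Study-scale environment with a handful of OTUs."""
    return s.generate_dataset(n_sites=255, n_otus=6, dispersion=1.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def brute_force_single_linkage(dist: np.ndarray, cutoff: float) -> list[set[int]]:
    """Independent oracle: iteratively merge the closest pair of clusters
    (linkage = minimum inter-cluster distance) while that minimum <= cutoff."""
    clusters = [{i} for i in range(len(dist))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        if d > cutoff:
            break
        clusters[a] |= clusters[b]
        del clusters[b]
    return clusters


@pytest.fixture(scope="session")
def random_distance_matrix_factory():
    def make(n: int, seed: int) -> np.ndarray:
        r = np.random.default_rng(seed)
        d = r.uniform(0, 80, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return d

    return make
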