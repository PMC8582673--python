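import numpy as np
import pandas as pd
import pytest

from benthonet.io import CommunityMatrix, TaxonTable


@pytest.fixture
def tiny_matrix() -> CommunityMatrix:
    """4 samples x 5 taxa with varied structure (zeros, ties, a dominant)."""
    df = pd.DataFrame(
        [
            [10, 0, 3, 1, 0],
            [8, 2, 0, 1, 0],
            [0, 5, 4, 2, 1],
            [1, 7, 6, 0, 0],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["t1", "t2", "t3", "t4", "t5"],
        dtype=float,
    )
    return CommunityMatrix(df)


@pytest.fixture
def tiny_traits() -> TaxonTable:
    df = pd.DataFrame(
        {
            "order_name": [
                "Ephemeroptera",
                "Plecoptera",
                "Diptera",
                "Trichoptera",
                "Amphipoda",
            ],
            "family_name": ["Baetidae", "Perlidae", "Chironomidae",
                            "Hydropsychidae", "Gammaridae"],
            "ffg": ["scraper", "predator", "collector_gatherer",
                    "collector_filterer", "shredder"],
        },
        index=pd.Index(["t1", "t2", "t3", "t4", "t5"], name="taxon_id"),
    )
    return TaxonTable(df)


def random_community(rng: np.random.Generator, n: int, k: int) -> CommunityMatrix:
    counts = rng.poisson(5.0, size=(n, k)).astype(float)
    return CommunityMatrix(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n)],
            columns=[f"t{j}" for j in range(k)],
        )
    )
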