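import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import stresskit as sk

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_trial() -> sk.TrialTable:
    """One genotype, two environments, two replicates of grain yield."""
    return sk.TrialTable(
        pd.DataFrame(
            {
                "genotype": ["A", "A", "A", "A"],
                "environment": ["N2", "N2", "SNI", "SNI"],
                "replicate": [1, 2, 1, 2],
                "trait": ["GY"] * 4,
                "value": [100.0, 120.0, 40.0, 60.0],
            }
        )
    )


@pytest.fixture
def worked_pairs() -> sk.YieldPairTable:
    """Three genotypes engineered so Ȳp = 80 and Ȳs = 48 with the worked
    genotype at (Ypi, Ysi) = (100, 50)."""
    return sk.YieldPairTable(
        pd.DataFrame(
            {
                "genotype": ["G1", "G2", "G3"],
                "Yp": [100.0, 60.0, 80.0],
                "Ys": [50.0, 46.0, 48.0],
            }
        ),
        stress="heat",
    )


@pytest.fixture
def heat_pairs() -> sk.YieldPairTable:
    return sk.simulate_preset("paper_heat_clusters", seed=7)


@pytest.fixture
def heat_indices(heat_pairs) -> sk.IndexTable:
    return sk.compute_indices(heat_pairs)


def random_pairs(rng: np.random.Generator, n: int = 50) -> sk.YieldPairTable:
    """Unstructured positive yield pairs with Ys < Yp on average."""
    yp = rng.uniform(50.0, 400.0, size=n)
    ys = yp * rng.uniform(0.05, 0.95, size=n)
    return sk.YieldPairTable(
        pd.DataFrame({"genotype": [f"g{i}" for i in range(n)], "Yp": yp, "Ys": ys}),
        stress="heat",
    )
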