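import numpy as np
import pandas as pd
import pytest

from nemameta import CommunityTable, EnvTable, generate_study_design


def make_table(counts: np.ndarray, groups=None) -> CommunityTable:
    """Minimal valid community table around a raw count matrix."""
    counts = np.asarray(counts)
    n, m = counts.shape
    samples = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    genera = pd.Index([f"g{j}" for j in range(m)], name="genus_id")
    if groups is None:
        groups = [("PF", "BF", "FF", "OP")[j % 4] for j in range(m)]
    return CommunityTable(
        counts=pd.DataFrame(counts, index=samples, columns=genera),
        sample_meta=pd.DataFrame(
            {
                "site": "S1",
                "land_cover": "farmland",
                "year": 2019,
                "replicate": range(1, n + 1),
                "longitude": 120.0,
                "latitude": np.linspace(40, 50, n),
            },
            index=samples,
        ),
        genus_meta=pd.DataFrame({"trophic_group": groups}, index=genera),
    )


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study design shared across tests."""
    table, env = generate_study_design(seed=11)
    return table, env


@pytest.fixture
def rng():
    return np.random.default_rng(42)
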