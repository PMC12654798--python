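import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_asv():
    """Tiny two-phylum ASV table with known counts."""
    from soilmf.synthetic import ASVTable

    counts = pd.DataFrame(
        [[5, 5, 0, 0], [1, 1, 2, 3], [0, 0, 4, 4]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    taxonomy = pd.DataFrame(
        {
            "kingdom": "Fungi",
            "phylum": ["P1", "P1", "P2", "P2"],
            "class": "unassigned", "order": "unassigned",
            "family": "unassigned",
            "genus": ["g1", "g2", "g3", "g4"],
        },
        index=pd.Index(["a1", "a2", "a3", "a4"], name="asv_id"),
    )
    return ASVTable(counts, taxonomy)


@pytest.fixture
def indicator_table():
    from soilmf.synthetic import DesignConfig, generate_indicator_table

    return generate_indicator_table(DesignConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
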