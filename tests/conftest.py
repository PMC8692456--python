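import numpy as np
import pandas as pd
import pytest

from leucarb.community_composition import ASVTable


@pytest.fixture
def small_asv_table() -> ASVTable:
    """Six samples, two clearly separated depth communities, ten ASVs."""
    rng = np.random.default_rng(123)
    surface = np.array([40, 30, 15, 8, 4, 1, 1, 0, 0, 1], dtype=float)
    deep = np.array([0, 1, 1, 4, 8, 15, 25, 25, 15, 6], dtype=float)
    counts = []
    for profile in (surface, surface, surface, deep, deep, deep):
        counts.append(rng.multinomial(500, profile / profile.sum()))
    samples = [f"s{i}" for i in range(6)]
    asvs = [f"ASV{i}" for i in range(10)]
    taxonomy = pd.Series(
        ["Actinomarina"] * 3 + ["SAR86"] * 2 + ["SAR324"] * 3 + ["SAR202"] * 2,
        index=asvs,
    )
    metadata = pd.DataFrame(
        {"depth_m": [50, 75, 90, 1500, 2000, 2500], "station": "T"},
        index=samples,
    )
    return ASVTable(
        counts=pd.DataFrame(counts, index=samples, columns=asvs),
        taxonomy=taxonomy,
        metadata=metadata,
    )
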