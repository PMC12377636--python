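import pandas as pd
import pytest

from fluorodist import BiodistributionModel, SyntheticConfig, generate_library


@pytest.fixture(scope="session")
def default_library():
    """Default-composition synthetic library (764 compounds), fixed seed."""
    return generate_library(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_results(default_library):
    records, _ = default_library
    return BiodistributionModel.from_records(records).fit()


@pytest.fixture
def toy_scored():
    """Six hand-labeled (compound, organ) rows: 4 high overall, 3 in region
    VI of which 2 are high -> expected stratum counts (x=4, y=6, m=2, n=3)."""
    return pd.DataFrame(
        {
            "compound_id": [f"C{i}" for i in range(6)],
            "organ": ["liver"] * 6,
            "skeleton": ["pentamethine"] * 6,
            "net_charge": [1, 1, 1, 1, 1, 1],
            "region": ["VI", "VI", "VI", "V", "V", "V"],
            "high": [True, True, False, True, True, False],
        }
    )
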