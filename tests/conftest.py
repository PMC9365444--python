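import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hospiseg as hs
from hospiseg.ingest import impute_suppressed
from hospiseg.segregation import composition

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def analytic_table(region: hs.SyntheticRegion) -> pd.DataFrame:
    """Masked counts -> imputed shares joined to geography (test helper)."""
    return composition(impute_suppressed(region.ipbs)).merge(
        region.crosswalk, on="hospital_id"
    )


@pytest.fixture(scope="session")
def small_config() -> hs.SyntheticConfig:
    return hs.SyntheticConfig(
        n_counties=2, hsas_per_county=2, hospitals_per_hsa=2, seed=7
    )


@pytest.fixture(scope="session")
def small_region(small_config) -> hs.SyntheticRegion:
    return hs.generate_region(small_config)


@pytest.fixture(scope="session")
def default_region() -> hs.SyntheticRegion:
    """Study-scale system: 9 counties, 36 HSAs, 6 HRRs, 72 hospitals."""
    return hs.generate_region(hs.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_analytic(default_region) -> pd.DataFrame:
    return analytic_table(default_region)


@pytest.fixture(scope="session")
def region84() -> hs.SyntheticRegion:
    """An 84-hospital system (7 counties x 2 HSAs x 6 hospitals)."""
    return hs.generate_region(
        hs.SyntheticConfig(n_counties=7, hsas_per_county=2, hospitals_per_hsa=6, seed=3)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
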