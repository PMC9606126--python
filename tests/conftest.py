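import numpy as np
import pandas as pd
import pytest

from pollendiv.io_core import PlantSurvey, PollenDataset, SiteMeta


@pytest.fixture
def toy_pollen() -> PollenDataset:
    """Two regions x two habitats, four sites, five taxa."""
    sites = [
        SiteMeta("s1", "region_poor", "forest"),
        SiteMeta("s2", "region_poor", "open"),
        SiteMeta("s3", "region_rich", "forest"),
        SiteMeta("s4", "region_rich", "open"),
    ]
    counts = np.array([
        [500, 300, 100, 43, 0],
        [200, 400, 250, 93, 0],
        [100, 100, 600, 143, 0],
        [50, 250, 350, 293, 1],
    ])
    return PollenDataset(sites=sites, taxa=list("ABCDE"), counts=counts)


@pytest.fixture
def toy_survey() -> PlantSurvey:
    records = pd.DataFrame(
        [
            ("s1", "sp1", 0.5, "forest"),
            ("s1", "sp2", 40.0, "forest"),
            ("s1", "sp3", 900.0, "open"),
            ("s2", "sp1", 5.0, "open"),
            ("s2", "sp4", 70.0, "open"),
            ("s3", "sp2", 12.0, "forest"),
            ("s4", "sp5", 600.0, "open"),
        ],
        columns=["site_id", "species", "first_distance_m", "habitat"],
    )
    return PlantSurvey(records=records)


@pytest.fixture(scope="session")
def two_region_study():
    """One two-region synthetic study shared across read-only tests."""
    from pollendiv.synthetic_data import simulate_study

    return simulate_study("two-region", seed=0)
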