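import numpy as np
import pandas as pd
import pytest

from spatioassoc import RegionConfig, generate_region


@pytest.fixture(scope="session")
def small_region():
    """A small but spatially meaningful synthetic region (shared, read-only)."""
    cfg = RegionConfig(n_tracts=600, n_zips=150, seed=42)
    tracts, zips, truth = generate_region(cfg)
    return cfg, tracts, zips, truth


@pytest.fixture()
def toy_tracts():
    """Two tracts at 10 and 20 miles due north of the single zip centroid.

    1 degree of latitude is 69.0934... miles on the package's sphere, so
    offsets are chosen in exact degree fractions of that.
    """
    mile_deg = np.pi / 180.0 * 3958.8
    return pd.DataFrame(
        {
            "tract_id": ["T1", "T2"],
            "lon": [0.0, 0.0],
            "lat": [10.0 / mile_deg, 20.0 / mile_deg],
            "population": [100.0, 100.0],
            "pm": [30.0, 60.0],
        }
    )


@pytest.fixture()
def toy_zip():
    return pd.DataFrame(
        {
            "zip_id": ["Z1"],
            "lon": [0.0],
            "lat": [0.0],
            "cases": [5],
            "total": [100],
        }
    )
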