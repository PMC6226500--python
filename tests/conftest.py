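import numpy as np
import pandas as pd
import pytest

from latgaps import BandGrid


@pytest.fixture
def grid():
    """Default 33-band grid from −80° to 85° in 5° bands."""
    return BandGrid()


def make_records(rows):
    """Build a cleaned-schema occurrence frame from (name, lat, lon, date) tuples.

    ``date`` may be None (missing); depth and group columns are filled in.
    """
    df = pd.DataFrame(rows, columns=["species_name", "latitude", "longitude", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["sample_depth_m"] = np.nan
    df["taxon_group"] = "test"
    return df


def make_raw(rows, rank="species", group="test"):
    """Raw-schema frame from (name, lat, lon, date) tuples."""
    df = pd.DataFrame(rows, columns=["scientific_name", "latitude", "longitude", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    df["sample_depth_m"] = np.nan
    df["taxon_rank"] = rank
    df["taxon_group"] = group
    return df
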