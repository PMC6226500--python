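"""Latitudinal band grids, sampling-event counts and species × band occupancy.

The grid divides latitude into equal-width bands, half-open ``[low, high)``
with the topmost band closed at the upper edge so every retained latitude is
assignable.  The default grid spans −80° to 85° in 5° bands (33 bands).

A *sampling event* is a unique combination of (rounded) latitude, longitude
and sampling date; records with no date form a single event key per
coordinate pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandGrid",
    "OccupancyMatrix",
    "band_index",
    "count_sampling_events",
    "build_occupancy",
]


@dataclass(frozen=True)
class BandGrid:
    """Equal-width latitudinal discretisation.

    Parameters
    ----------
    lower, upper
        Grid extent in decimal degrees; defaults −80 and 85 match the
        retained latitude range after quality control.
    width
        Band width in degrees (default 5).  ``(upper - lower)`` must be an
        exact multiple of ``width``.
    """

    lower: float = -80.0
    upper: float = 85.0
    width: float = 5.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        span = self.upper - self.lower
        n = span / self.width
        if span <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid span {span}° is not an exact multiple of width {self.width}°"
            )

    @property
    def n_bands(self) -> int:
        return int(round((self.upper - self.lower) / self.width))

    @property
    def edges(self) -> np.ndarray:
        """Band edges, length ``n_bands + 1``."""
        return self.lower + self.width * np.arange(self.n_bands + 1)

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower + self.width * (np.arange(self.n_bands) + 0.5)

    def band_bounds(self, b: int) -> tuple[float, float]:
        if not 0 <= b < self.n_bands:
            raise IndexError(f"band {b} outside 0..{self.n_bands - 1}")
        e = self.edges
        return float(e[b]), float(e[b + 1])

    def band_index(self, latitude: float) -> int:
        """Band containing *latitude* (scalar form of :func:`band_index`)."""
        return int(self.band_indices(np.asarray([latitude]))[0])

    def band_indices(self, latitudes) -> np.ndarray:
        """Vectorised band assignment; raises on out-of-range latitudes."""
        lat = np.asarray(latitudes, dtype=float)
        if np.any(np.isnan(lat)) or np.any(lat < self.lower) or np.any(lat > self.upper):
            bad = lat[np.isnan(lat) | (lat < self.lower) | (lat > self.upper)]
            raise ValueError(
                f"latitudes outside grid [{self.lower}, {self.upper}]: {bad[:5]}"
            )
        idx = np.searchsorted(self.edges, lat, side="right") - 1
        # topmost band is closed at the upper edge
        return np.minimum(idx, self.n_bands - 1)

    def bands_for_interval(self, low: float, high: float) -> np.ndarray:
        """Indices of all bands intersecting the closed interval [low, high]."""
        if high < low:
            raise ValueError("interval upside down")
        lo = max(low, self.lower)
        hi = min(high, self.upper)
        if hi < self.lower or lo > self.upper:
            return np.arange(0)
        return np.arange(self.band_index(lo), self.band_index(hi) + 1)

    def band_frame(self) -> pd.DataFrame:
        e = self.edges
        return pd.DataFrame(
            {"band": np.arange(self.n_bands), "lat_low": e[:-1], "lat_high": e[1:]}
        )


def band_index(latitude: float, grid: BandGrid) -> int:
    """Index of the band containing *latitude* on *grid*."""
    return grid.band_index(latitude)


_EVENT_KEY = ["latitude", "longitude", "event_date"]


def count_sampling_events(records: pd.DataFrame, grid: BandGrid) -> pd.DataFrame:
    """Per-band sampling effort.

    Returns a table with one row per band: ``band, lat_low, lat_high,
    n_events, n_records``.  Events are distinct (lat, lon, date) triples among
    the band's records, with a missing date acting as its own key value, so
    all undated records at one coordinate pair collapse into one event.
    """
    out = grid.band_frame()
    if len(records) == 0:
        out["n_events"] = 0
        out["n_records"] = 0
        return out
    bands = grid.band_indices(records["latitude"].to_numpy())
    df = records.loc[:, _EVENT_KEY].assign(band=bands)
    n_records = df.groupby("band")["band"].size()
    n_events = (
        df.drop_duplicates(subset=_EVENT_KEY + ["band"]).groupby("band")["band"].size()
    )
    out["n_events"] = out["band"].map(n_events).fillna(0).astype(int)
    out["n_records"] = out["band"].map(n_records).fillna(0).astype(int)
    return out


@dataclass
class OccupancyMatrix:
    """Species × band record counts and derived presence/absence.

    ``counts[s, b]`` is the number of records of species ``s`` in band ``b``;
    ``presence`` is its boolean support.  Column sums of ``presence`` are the
    observed richness per band.
    """

    species: list[str]
    grid: BandGrid
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.species), self.grid.n_bands):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.species)} species x {self.grid.n_bands} bands"
            )
        if (self.counts < 0).any():
            raise ValueError("negative record counts")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def presence(self) -> np.ndarray:
        return self.counts > 0

    @property
    def observed_richness(self) -> np.ndarray:
        """Observed species count per band."""
        return self.presence.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.species, name="species"),
            columns=np.arange(self.grid.n_bands),
        )


def build_occupancy(
    records: pd.DataFrame,
    grid: BandGrid,
    species: Optional[Sequence[str]] = None,
) -> OccupancyMatrix:
    """Species × band occupancy from cleaned records.

    *species* optionally fixes the row set (and order); listed species with
    no records get all-zero rows, which is needed when aligning observed
    occupancy against a known ground truth.
    """
    if len(records) == 0:
        sp = list(species) if species is not None else []
        return OccupancyMatrix(sp, grid, np.zeros((len(sp), grid.n_bands), dtype=np.int64))
    bands = grid.band_indices(records["latitude"].to_numpy())
    tab = pd.crosstab(
        records["species_name"], pd.Series(bands, index=records.index, name="band")
    )
    if species is None:
        species = list(tab.index)
    tab = tab.reindex(index=species, columns=np.arange(grid.n_bands), fill_value=0)
    return OccupancyMatrix(list(species), grid, tab.to_numpy())
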