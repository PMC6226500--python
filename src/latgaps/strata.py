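"""Bathymetric stratification of occurrence records.

Records are partitioned into three depth strata — euphotic (0–200 m),
bathyal (200–2000 m) and abyssal (2000–6500 m) — with boundaries owned by
the deeper stratum and the abyssal top closed at 6500 m.  Depths beyond
6500 m, or depths that cannot be resolved, leave a record ``unassigned``.

When a record lacks a sample depth but belongs to a benthic species, the
seafloor depth at its coordinates (from a pluggable bathymetry grid) stands
in, since a benthic specimen was collected at the bottom.  Pelagic species
without a sample depth stay unassigned — their sampling depth need not
reflect the seafloor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .binning import BandGrid, build_occupancy, count_sampling_events
from .completeness import (
    DEFAULT_MIN_EVENTS,
    DEFAULT_N_PERM,
    completeness_table,
)
from .gaps import RichnessVectors, richness_vectors

__all__ = [
    "STRATUM_BOUNDS",
    "STRATA",
    "HabitTable",
    "BathymetryGrid",
    "depth_to_stratum",
    "assign_strata",
    "StratumResult",
    "stratified_analysis",
]

#: Depth intervals in metres; lower bound inclusive, upper exclusive except
#: the abyssal top which is closed at 6500 m.
STRATUM_BOUNDS: dict[str, tuple[float, float]] = {
    "euphotic": (0.0, 200.0),
    "bathyal": (200.0, 2000.0),
    "abyssal": (2000.0, 6500.0),
}

STRATA = ("euphotic", "bathyal", "abyssal")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class HabitTable:
    """Species → benthic/pelagic habit (user supplied)."""

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {h for h in self.table.values() if h not in ("benthic", "pelagic")}
        if bad:
            raise ValueError(f"habit must be benthic or pelagic, got {sorted(bad)}")

    def is_benthic(self, species: str) -> bool:
        return self.table.get(species) == "benthic"

    @classmethod
    def from_csv(cls, path: str | Path) -> "HabitTable":
        df = pd.read_csv(path, dtype=str)
        if not {"species", "habit"}.issubset(df.columns):
            raise ValueError("habit table needs columns species, habit")
        return cls(dict(zip(df["species"], df["habit"].str.lower())))

    @classmethod
    def all_benthic(cls, species) -> "HabitTable":
        return cls({s: "benthic" for s in species})


@dataclass
class BathymetryGrid:
    """Regular lat/lon grid of seafloor depths with nearest-node lookup.

    Built from a long-format table (lat, lon, depth); queries outside the
    grid's bounding box, or at nodes with no depth value, return NaN.
    Depth is metres, positive down.
    """

    lats: np.ndarray
    lons: np.ndarray
    depths: np.ndarray = field(repr=False)  # shape (n_lats, n_lons)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.shape != (self.lats.size, self.lons.size):
            raise ValueError("depth grid shape mismatch")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("grid axes must be strictly increasing")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "BathymetryGrid":
        if not {"lat", "lon", "depth"}.issubset(df.columns):
            raise ValueError("bathymetry table needs columns lat, lon, depth")
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        grid = (
            df.pivot_table(index="lat", columns="lon", values="depth", aggfunc="mean")
            .reindex(index=lats, columns=lons)
            .to_numpy()
        )
        return cls(lats, lons, grid)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BathymetryGrid":
        return cls.from_table(pd.read_csv(path))

    def _nearest(self, axis: np.ndarray, x: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(axis, x), 1, axis.size - 1)
        left = axis[idx - 1]
        right = axis[idx]
        return np.where(np.abs(x - left) <= np.abs(x - right), idx - 1, idx)

    def __call__(self, lat, lon):
        """Seafloor depth at (lat, lon); NaN outside the grid's bounding box."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        scalar = lat.ndim == 0
        lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)
        half_dlat = np.diff(self.lats).max() / 2 if self.lats.size > 1 else np.inf
        half_dlon = np.diff(self.lons).max() / 2 if self.lons.size > 1 else np.inf
        inside = (
            (lat >= self.lats[0] - half_dlat)
            & (lat <= self.lats[-1] + half_dlat)
            & (lon >= self.lons[0] - half_dlon)
            & (lon <= self.lons[-1] + half_dlon)
        )
        out = np.full(lat.shape, np.nan)
        if inside.any():
            li = self._nearest(self.lats, lat[inside])
            lj = self._nearest(self.lons, lon[inside])
            out[inside] = self.depths[li, lj]
        return float(out[0]) if scalar else out


def depth_to_stratum(depth) -> np.ndarray:
    """Vectorised depth → stratum label; NaN, negative or >6500 m → unassigned."""
    d = np.atleast_1d(np.asarray(depth, dtype=float))
    out = np.full(d.shape, UNASSIGNED, dtype=object)
    out[(d >= 0) & (d < 200)] = "euphotic"
    out[(d >= 200) & (d < 2000)] = "bathyal"
    out[(d >= 2000) & (d <= 6500)] = "abyssal"
    return out


def assign_strata(
    records: pd.DataFrame,
    habit: Optional[HabitTable] = None,
    bathy: Optional[Callable] = None,
) -> pd.Series:
    """Stratum label for every record.

    Records with a sample depth are labelled directly.  Records without one
    fall back to the seafloor depth at their coordinates when the species is
    benthic and a bathymetry lookup is supplied; otherwise they are
    unassigned.
    """
    depth = records["sample_depth_m"].to_numpy(dtype=float)
    if habit is not None and bathy is not None:
        benthic = records["species_name"].map(habit.is_benthic).to_numpy(dtype=bool)
        fallback = np.isnan(depth) & benthic
        if fallback.any():
            depth = depth.copy()
            depth[fallback] = np.asarray(
                bathy(
                    records.loc[fallback, "latitude"].to_numpy(),
                    records.loc[fallback, "longitude"].to_numpy(),
                ),
                dtype=float,
            )
    return pd.Series(depth_to_stratum(depth), index=records.index, name="stratum")


@dataclass
class StratumResult:
    """Full per-band pipeline output within one depth stratum."""

    stratum: str
    n_records: int
    richness: RichnessVectors
    effort: pd.DataFrame
    completeness: pd.DataFrame


def stratified_analysis(
    records: pd.DataFrame,
    habit: Optional[HabitTable] = None,
    bathy: Optional[Callable] = None,
    grid: Optional[BandGrid] = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> dict[str, StratumResult]:
    """Run the gap/effort/completeness pipeline independently per stratum.

    Species gap profiles are recomputed from each stratum's own records, so
    a species contiguous overall may be disjunct within a stratum.  The
    result maps each of the three strata plus ``unassigned`` to a
    :class:`StratumResult`; per-band record totals across the four subsets
    sum to the unstratified totals.
    """
    grid = grid or BandGrid()
    labels = assign_strata(records, habit, bathy)
    out: dict[str, StratumResult] = {}
    for i, stratum in enumerate((*STRATA, UNASSIGNED)):
        sub = records.loc[labels == stratum]
        if len(sub):
            rich = richness_vectors(build_occupancy(sub, grid))
        else:
            zero = np.zeros(grid.n_bands, dtype=np.int64)
            rich = RichnessVectors(zero, zero.copy())
        out[stratum] = StratumResult(
            stratum=stratum,
            n_records=len(sub),
            richness=rich,
            effort=count_sampling_events(sub, grid),
            completeness=completeness_table(
                sub, grid, n_perm=n_perm, seed=seed + i, min_events=min_events
            ),
        )
    return out
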