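"""Standardisation, cross-group aggregation and resolution sweeps.

Per-band curves (observed/missing richness, sampling events, the two
completeness estimates) are computed per taxonomic group, standardised to
[0, 1] by each curve's maximum, then averaged across groups with a
population standard deviation.  Undefined completeness values (bands below
the event threshold) propagate as missing and are excluded from the means —
never coerced to zero, which would fabricate low completeness in sparse
bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binning import BandGrid, build_occupancy, count_sampling_events
from .completeness import DEFAULT_MIN_EVENTS, DEFAULT_N_PERM, completeness_table
from .gaps import richness_vectors

__all__ = [
    "GroupCurveSet",
    "AggregateSummary",
    "standardise_curve",
    "analyse_group",
    "aggregate_groups",
    "resolution_sweep",
]

METRICS = ("observed", "missing", "events", "coverage", "sac")


def standardise_curve(values) -> np.ndarray:
    """Divide a per-band vector by its (NaN-ignoring) maximum.

    All-zero (or all-NaN) vectors are returned unchanged with a warning —
    there is nothing to scale by.  Idempotent on already-standardised input.
    """
    v = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slice
        m = np.nanmax(v) if v.size else np.nan
    if not np.isfinite(m) or m <= 0:
        warnings.warn("curve has no positive values; returned unstandardised", stacklevel=2)
        return v.copy()
    return v / m


@dataclass
class GroupCurveSet:
    """Per-band curves for one taxonomic group (NaN marks undefined)."""

    group: str
    grid: BandGrid
    observed: np.ndarray
    missing: np.ndarray
    events: np.ndarray
    coverage: np.ndarray
    sac: np.ndarray

    def __post_init__(self) -> None:
        for name in METRICS:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.grid.n_bands,):
                raise ValueError(f"{name} length != {self.grid.n_bands}")
            setattr(self, name, v)

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.band_frame()
        out["group"] = self.group
        for name in METRICS:
            out[name] = getattr(self, name)
        return out


def analyse_group(
    records: pd.DataFrame,
    group: str = "all",
    grid: Optional[BandGrid] = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> GroupCurveSet:
    """Full per-band pipeline for one group's cleaned records."""
    grid = grid or BandGrid()
    rich = richness_vectors(build_occupancy(records, grid)) if len(records) else None
    effort = count_sampling_events(records, grid)
    comp = completeness_table(records, grid, n_perm=n_perm, seed=seed, min_events=min_events)
    zeros = np.zeros(grid.n_bands)
    return GroupCurveSet(
        group=group,
        grid=grid,
        observed=rich.observed if rich else zeros.copy(),
        missing=rich.missing if rich else zeros.copy(),
        events=effort["n_events"].to_numpy(dtype=float),
        coverage=comp["coverage"].to_numpy(),
        sac=comp["sac"].to_numpy(),
    )


@dataclass
class AggregateSummary:
    """Cross-group mean ± s.d. of the standardised per-band curves."""

    grid: BandGrid
    n_groups: int
    table: pd.DataFrame  # band, lat_low, lat_high, <metric>_mean, <metric>_sd, ...

    def mean(self, metric: str) -> np.ndarray:
        return self.table[f"{metric}_mean"].to_numpy()

    def sd(self, metric: str) -> np.ndarray:
        return self.table[f"{metric}_sd"].to_numpy()


def aggregate_groups(curves: Sequence[GroupCurveSet]) -> AggregateSummary:
    """Standardise each group's curves to [0, 1] and average across groups.

    Per band and metric: mean and population (denominator *n*) standard
    deviation over the groups for which the metric is defined there; bands
    undefined for every group stay NaN.
    """
    if not curves:
        raise ValueError("need at least one group")
    grid = curves[0].grid
    if any(c.grid != grid for c in curves):
        raise ValueError("groups use different grids")
    out = grid.band_frame()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bands
        for metric in METRICS:
            stack = np.vstack([standardise_curve(getattr(c, metric)) for c in curves])
            out[f"{metric}_mean"] = np.nanmean(stack, axis=0)
            out[f"{metric}_sd"] = np.nanstd(stack, axis=0)  # population form
    return AggregateSummary(grid=grid, n_groups=len(curves), table=out)


def resolution_sweep(
    records: pd.DataFrame,
    widths: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    lower: float = -80.0,
    upper: float = 85.0,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> pd.DataFrame:
    """Completeness pipeline at several band widths.

    Every width must divide the grid span exactly (configuration error
    otherwise).  Returns the concatenated per-band completeness tables with
    a leading ``width`` column; an empty width list yields an empty table.
    """
    frames = []
    for width in widths:
        grid = BandGrid(lower, upper, width)  # raises on non-dividing width
        tab = completeness_table(
            records, grid, n_perm=n_perm, seed=seed, min_events=min_events
        )
        tab.insert(0, "width", width)
        frames.append(tab)
    if not frames:
        return pd.DataFrame(
            columns=["width", "band", "lat_low", "lat_high", "n_records",
                     "n_events", "f1", "f2", "coverage", "sac"]
        )
    return pd.concat(frames, ignore_index=True)
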