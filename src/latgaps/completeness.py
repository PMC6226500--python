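"""Inventory completeness per latitudinal band.

Two estimators, both in [0, 1] (1 = complete inventory):

* **Sample coverage** — the estimated proportion of individuals in the
  assemblage belonging to species already recorded, computed from the number
  of records ``n`` and the singleton/doubleton counts ``f1``/``f2``::

      C = 1 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))

  Many singletons signal that many rarely-recorded species remain undetected.

* **Species-accumulation-curve (SAC) curvilinearity** — one minus the mean
  slope of the final 10% of the expected accumulation curve (species gained
  per additional sampling event, averaged over random event orderings),
  clamped to [0, 1].  A saturated (flat-tailed) curve scores 1; a curve still
  gaining a species per event scores 0.  Only computed for bands with more
  than ``min_events`` (default 40) sampling events, since the tail would
  otherwise cover too few events to measure a slope.

Records are treated as individuals for coverage (occurrence rows are the
only specimen proxy); the SAC uses the event × species incidence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .binning import BandGrid

__all__ = [
    "BandIncidence",
    "CompletenessEstimates",
    "sample_coverage",
    "band_incidences",
    "accumulation_curve",
    "exact_accumulation_curve",
    "sac_completeness",
    "band_completeness",
    "completeness_table",
]

DEFAULT_MIN_EVENTS = 40
DEFAULT_TAIL_FRACTION = 0.10
DEFAULT_N_PERM = 100


def sample_coverage(n: int, f1: int, f2: int) -> float:
    """Sample-coverage estimate of inventory completeness.

    Parameters are the record (specimen) count ``n`` and the number of
    species with exactly one (``f1``) and exactly two (``f2``) records.
    Returns NaN for ``n == 0`` (undefined) and 0.0 for ``n == 1``.
    """
    if n < 0 or f1 < 0 or f2 < 0:
        raise ValueError("counts must be non-negative")
    if f1 + 2 * f2 > n:
        raise ValueError(f"f1 + 2*f2 = {f1 + 2 * f2} exceeds n = {n}")
    if n == 0:
        return math.nan
    if n == 1:
        return 0.0
    if f1 == 0:
        return 1.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))


@dataclass
class BandIncidence:
    """Record abundances and event × species incidence within one band."""

    band: int
    abundance: pd.Series  # species -> record count in band
    incidence: np.ndarray = field(repr=False)  # events x species boolean

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)

    @property
    def n_records(self) -> int:
        return int(self.abundance.sum())

    @property
    def n_events(self) -> int:
        return self.incidence.shape[0]

    @property
    def f1(self) -> int:
        return int((self.abundance == 1).sum())

    @property
    def f2(self) -> int:
        return int((self.abundance == 2).sum())


def band_incidences(records: pd.DataFrame, grid: BandGrid) -> dict[int, BandIncidence]:
    """Split cleaned records into per-band abundance + incidence structures.

    Only bands containing at least one record appear in the result.
    """
    if len(records) == 0:
        return {}
    df = records.loc[:, ["species_name", "latitude", "longitude", "event_date"]].copy()
    df["band"] = grid.band_indices(df["latitude"].to_numpy())
    out: dict[int, BandIncidence] = {}
    for b, sub in df.groupby("band", sort=True):
        abundance = sub.groupby("species_name").size()
        event_codes = (
            sub.groupby(["latitude", "longitude", "event_date"], dropna=False, sort=False)
            .ngroup()
            .to_numpy()
        )
        species_codes, _ = pd.factorize(sub["species_name"])
        inc = np.zeros((event_codes.max() + 1, species_codes.max() + 1), dtype=bool)
        inc[event_codes, species_codes] = True
        out[int(b)] = BandIncidence(band=int(b), abundance=abundance, incidence=inc)
    return out


def _curve_from_orderings(incidence: np.ndarray, orderings: np.ndarray) -> np.ndarray:
    """Mean accumulation curve over the given event orderings (rows)."""
    M = incidence[:, incidence.any(axis=0)]  # species never seen cannot accumulate
    n_events = M.shape[0]
    totals = np.zeros(n_events, dtype=np.float64)
    for order in orderings:
        first_seen = M[order].argmax(axis=0)  # every column has a True
        totals += np.bincount(first_seen, minlength=n_events)
    return np.cumsum(totals) / len(orderings)


def accumulation_curve(
    incidence: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    exact: bool = False,
) -> np.ndarray:
    """Expected species accumulation curve over random event orderings.

    ``curve[k-1]`` is the expected number of distinct species among the first
    ``k`` events; it is non-decreasing and ends at the total species count.
    Monte-Carlo with ``n_perm`` orderings by default; ``exact=True``
    enumerates all orderings (only allowed for ≤ 8 events) and is the
    reference the Monte-Carlo estimate converges to.
    """
    M = np.asarray(incidence, dtype=bool)
    if M.ndim != 2 or M.shape[0] == 0:
        raise ValueError("incidence must be a non-empty events x species matrix")
    n_events = M.shape[0]
    if exact:
        return exact_accumulation_curve(M)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    orderings = rng.permuted(
        np.broadcast_to(np.arange(n_events), (n_perm, n_events)).copy(), axis=1
    )
    return _curve_from_orderings(M, orderings)


def exact_accumulation_curve(incidence: np.ndarray) -> np.ndarray:
    """Exhaustive-permutation accumulation curve (≤ 8 events)."""
    M = np.asarray(incidence, dtype=bool)
    n_events = M.shape[0]
    if n_events > 8:
        raise ValueError("exact enumeration limited to 8 events")
    orderings = np.array(list(itertools.permutations(range(n_events))), dtype=np.intp)
    return _curve_from_orderings(M, orderings)


def sac_completeness(
    curve: np.ndarray,
    n_events: Optional[int] = None,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> float:
    """Completeness from the tail slope of an accumulation curve.

    The slope over the last ``tail_fraction`` of events (at least one event)
    is the mean number of new species per additional event; completeness is
    ``1 - slope`` clamped to [0, 1].  NaN (undefined) unless the band has
    more than ``min_events`` events.
    """
    curve = np.asarray(curve, dtype=float)
    if n_events is None:
        n_events = len(curve)
    if n_events != len(curve):
        raise ValueError("n_events does not match curve length")
    if n_events <= min_events:
        return math.nan
    m = max(1, int(math.floor(tail_fraction * n_events)))
    slope = (curve[n_events - 1] - curve[n_events - 1 - m]) / m
    return float(min(1.0, max(0.0, 1.0 - slope)))


@dataclass(frozen=True)
class CompletenessEstimates:
    """The two per-band completeness values; NaN marks "undefined"."""

    coverage: float
    sac: float


def band_completeness(
    band: Optional[BandIncidence],
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = None,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> CompletenessEstimates:
    """Both completeness estimates for one band.

    Coverage needs at least two records; the SAC estimate needs more than
    ``min_events`` events.  ``band=None`` (no records) yields NaN for both.
    """
    if band is None or band.n_records == 0:
        return CompletenessEstimates(math.nan, math.nan)
    cov = sample_coverage(band.n_records, band.f1, band.f2) if band.n_records >= 2 else math.nan
    if band.n_events > min_events:
        curve = accumulation_curve(band.incidence, n_perm=n_perm, seed=seed)
        sac = sac_completeness(curve, band.n_events, tail_fraction, min_events)
    else:
        sac = math.nan
    return CompletenessEstimates(coverage=cov, sac=sac)


def completeness_table(
    records: pd.DataFrame,
    grid: BandGrid,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
    min_events: int = DEFAULT_MIN_EVENTS,
) -> pd.DataFrame:
    """Per-band completeness summary for a cleaned record set.

    Returns one row per band of the grid: ``band, n_records, n_events, f1,
    f2, coverage, sac``.  Band-level randomisation seeds are spawned
    deterministically from *seed*.
    """
    incidences = band_incidences(records, grid)
    child_seeds = np.random.SeedSequence(seed).spawn(grid.n_bands)
    rows = []
    for b in range(grid.n_bands):
        inc = incidences.get(b)
        est = band_completeness(
            inc, n_perm=n_perm, seed=child_seeds[b],
            tail_fraction=tail_fraction, min_events=min_events,
        )
        rows.append(
            {
                "band": b,
                "n_records": inc.n_records if inc else 0,
                "n_events": inc.n_events if inc else 0,
                "f1": inc.f1 if inc else 0,
                "f2": inc.f2 if inc else 0,
                "coverage": est.coverage,
                "sac": est.sac,
            }
        )
    out = grid.band_frame().merge(pd.DataFrame(rows), on="band")
    return out
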