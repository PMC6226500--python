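"""Spatial gaps in species' latitudinal ranges and missing richness.

A *spatial gap* is a band lying strictly between a species' lowest and
highest occupied bands that holds no record of that species.  Under the
assumption that true latitudinal ranges are contiguous, such interior gaps
flag artefactual absences, and their per-band tally — the *missing species
richness* — maps where undersampling distorts the richness gradient.

Gaps are never extrapolated beyond the recorded extremes: a species seen in
a single band contributes no gaps anywhere (edge truncation is a known blind
spot, quantified by :func:`latgaps.synthetic.recovery_report`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import OccupancyMatrix

__all__ = [
    "GapProfile",
    "RichnessVectors",
    "species_gap_profile",
    "interior_gap_matrix",
    "richness_vectors",
    "gap_species_summary",
    "band_absence_ratio",
    "per_species_table",
]


@dataclass(frozen=True)
class GapProfile:
    """Occupied extent and interior gaps of one species."""

    species_id: str
    first_band: int
    last_band: int
    occupied: frozenset[int]
    gap_bands: frozenset[int]

    @property
    def n_gaps(self) -> int:
        return len(self.gap_bands)


@dataclass(frozen=True)
class RichnessVectors:
    """Per-band observed and missing (gap) species counts."""

    observed: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed", np.asarray(self.observed, dtype=np.int64))
        object.__setattr__(self, "missing", np.asarray(self.missing, dtype=np.int64))
        if self.observed.shape != self.missing.shape:
            raise ValueError("observed/missing length mismatch")
        if (self.observed < 0).any() or (self.missing < 0).any():
            raise ValueError("negative richness")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band": np.arange(len(self.observed)),
                "observed": self.observed,
                "missing": self.missing,
            }
        )


def species_gap_profile(presence_row, species_id: str = "") -> GapProfile:
    """Gap profile of a single species from its per-band presence vector.

    The gaps are exactly the unoccupied bands strictly between the extreme
    occupied bands.  A species with no occupied band cannot be profiled.
    """
    row = np.asarray(presence_row, dtype=bool)
    occ = np.flatnonzero(row)
    if occ.size == 0:
        raise ValueError("species without records cannot be profiled")
    first, last = int(occ[0]), int(occ[-1])
    interior = np.arange(first + 1, last)
    gap = interior[~row[interior]]
    return GapProfile(
        species_id=species_id,
        first_band=first,
        last_band=last,
        occupied=frozenset(int(b) for b in occ),
        gap_bands=frozenset(int(b) for b in gap),
    )


def interior_gap_matrix(presence: np.ndarray) -> np.ndarray:
    """Boolean species × band matrix marking interior gaps.

    ``out[s, b]`` is true iff band ``b`` lies strictly inside species ``s``'s
    occupied extent and is unoccupied.  Rows with no occupied band yield
    all-false rows (they have no extent).
    """
    P = np.asarray(presence, dtype=bool)
    if P.ndim != 2:
        raise ValueError("presence must be 2-D (species x bands)")
    reached_left = np.maximum.accumulate(P, axis=1)
    reached_right = np.maximum.accumulate(P[:, ::-1], axis=1)[:, ::-1]
    return reached_left & reached_right & ~P


def richness_vectors(matrix: OccupancyMatrix) -> RichnessVectors:
    """Observed and missing species richness per band.

    ``observed[b]`` counts species present in band ``b``; ``missing[b]``
    counts species whose recorded range spans band ``b`` without occupying it.
    """
    P = matrix.presence
    return RichnessVectors(
        observed=P.sum(axis=0),
        missing=interior_gap_matrix(P).sum(axis=0),
    )


def gap_species_summary(matrix: OccupancyMatrix) -> tuple[int, float]:
    """Number and fraction of species with at least one interior gap."""
    if matrix.n_species == 0:
        raise ValueError("no species to summarise")
    has_gap = interior_gap_matrix(matrix.presence).any(axis=1)
    n = int(has_gap.sum())
    return n, n / matrix.n_species


def band_absence_ratio(vectors: RichnessVectors, band: int) -> float:
    """Missing-to-observed richness ratio at one band.

    Undefined (raises) where nothing was observed, rather than returning an
    infinite ratio.
    """
    observed = int(vectors.observed[band])
    if observed == 0:
        raise ZeroDivisionError(f"no species observed in band {band}")
    return float(vectors.missing[band]) / observed


def per_species_table(matrix: OccupancyMatrix) -> pd.DataFrame:
    """Per-species extent and gap count: species, first_band, last_band, n_gaps."""
    P = matrix.presence
    G = interior_gap_matrix(P)
    any_occ = P.any(axis=1)
    if not any_occ.all():
        raise ValueError("occupancy matrix contains species with no records")
    first = P.argmax(axis=1)
    last = P.shape[1] - 1 - P[:, ::-1].argmax(axis=1)
    return pd.DataFrame(
        {
            "species": matrix.species,
            "first_band": first,
            "last_band": last,
            "n_gaps": G.sum(axis=1),
        }
    )
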