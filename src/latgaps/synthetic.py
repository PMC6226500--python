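"""Synthetic occurrence data with known ground truth.

The generator realises the null world under which every detected latitudinal
gap is a sampling artefact: each species' true range is a single contiguous
latitude interval, so the true occupancy matrix has interval rows and no
true gaps.  Sampling is then imposed on top — per-band Poisson numbers of
sampling events, with every species truly present at an event's band
detected there independently with a fixed probability — so that the full
pipeline (QC, binning, gaps, completeness) can be tested against a known
truth, including its response to a latitude-dependent effort profile with an
equatorial trough.

Record-level noise (zero coordinates, out-of-bounds latitudes, on-land rows,
exact duplicates, date-stripped duplicates) can be injected at configurable
rates to exercise the quality-control rules; clean records draw longitudes
in [−170, 170) while :func:`toy_land_mask` declares lon ≥ 170 a synthetic
continent, so only injected rows sit on land.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .binning import BandGrid, OccupancyMatrix
from .gaps import interior_gap_matrix

__all__ = [
    "WorldConfig",
    "EffortProfile",
    "DetectionModel",
    "NoiseConfig",
    "TrueWorld",
    "make_world",
    "simulate_records",
    "toy_land_mask",
    "RecoveryReport",
    "recovery_report",
]

#: Synthetic continent used by noise injection: everything east of 170°E.
LAND_LON = 170.0


def toy_land_mask(lat, lon):
    """Land predicate for synthetic data: lon ≥ 170 is the toy continent."""
    return np.asarray(lon) >= LAND_LON


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    Range midpoints are uniform over ``midpoint_range`` (richness roughly
    uniform across latitude) or, with ``richness_shape='unimodal-tropical'``,
    normal around the equator (sd ``tropical_sd``) truncated to the same
    interval, giving a tropical richness peak.  Range widths are lognormal
    with the given median (degrees).  Each species is benthic with
    probability ``benthic_fraction`` and carries a depth interval from which
    record depths are drawn; each record's depth is missing with probability
    ``missing_depth_rate``.
    """

    n_species: int = 500
    grid: BandGrid = field(default_factory=BandGrid)
    richness_shape: str = "uniform"  # or "unimodal-tropical"
    midpoint_range: tuple[float, float] = (-70.0, 75.0)
    tropical_sd: float = 25.0
    width_median: float = 20.0
    width_sigma: float = 0.6
    benthic_fraction: float = 0.7
    missing_depth_rate: float = 0.2
    date_window: tuple[str, str] = ("1950-01-01", "2015-12-31")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if self.width_median <= 0 or self.width_sigma < 0:
            raise ValueError("degenerate range-width distribution")
        if self.richness_shape not in ("uniform", "unimodal-tropical"):
            raise ValueError(f"unknown richness_shape {self.richness_shape!r}")


@dataclass(frozen=True)
class EffortProfile:
    """Expected number of sampling events per band (Poisson rates)."""

    lambdas: np.ndarray
    grid: BandGrid

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        if lam.shape != (self.grid.n_bands,):
            raise ValueError("one rate per band required")
        if (lam < 0).any():
            raise ValueError("negative effort rate")

    @classmethod
    def uniform(cls, lam: float, grid: Optional[BandGrid] = None) -> "EffortProfile":
        grid = grid or BandGrid()
        return cls(np.full(grid.n_bands, float(lam)), grid)

    @classmethod
    def bimodal(
        cls,
        grid: Optional[BandGrid] = None,
        south_peak: float = 9000.0,
        north_peak: float = 21000.0,
        trough: float = 600.0,
        centers: tuple[float, float] = (-32.5, 52.5),
        sd: float = 15.0,
    ) -> "EffortProfile":
        """Mid-latitude effort peaks with an equatorial trough.

        Defaults emulate the observed global profile: a northern mid-latitude
        peak roughly twice the southern one and equatorial effort in the low
        hundreds of events per 5° band.
        """
        grid = grid or BandGrid()
        mid = grid.midpoints
        lam = (
            trough
            + south_peak * np.exp(-0.5 * ((mid - centers[0]) / sd) ** 2)
            + north_peak * np.exp(-0.5 * ((mid - centers[1]) / sd) ** 2)
        )
        return cls(lam, grid)

    def with_equatorial_trough(
        self, factor: float, half_width: float = 22.5
    ) -> "EffortProfile":
        """Divide the rates of bands intersecting ±half_width by *factor*.

        The default half-width covers the tropical belt (±22.5°, i.e. the
        ten 5° bands spanning −25° to 25° on the default grid), the region
        where marine sampling effort collapses relative to mid-latitudes.
        """
        if factor <= 0:
            raise ValueError("trough factor must be positive")
        lam = self.lambdas.copy()
        tropical = self.grid.bands_for_interval(-half_width, half_width)
        lam[tropical] = lam[tropical] / factor
        return EffortProfile(lam, self.grid)


@dataclass(frozen=True)
class DetectionModel:
    """Per-event detection: each truly-present species is recorded at an
    event independently with probability ``p`` (or its own ``p_species``)."""

    p: float = 0.1
    p_species: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("detection probability must be in [0, 1]")
        if self.p_species is not None:
            ps = np.asarray(self.p_species, dtype=float)
            object.__setattr__(self, "p_species", ps)
            if ((ps < 0) | (ps > 1)).any():
                raise ValueError("species detection probabilities must be in [0, 1]")

    def probs(self, n_species: int) -> np.ndarray:
        if self.p_species is not None:
            if self.p_species.shape != (n_species,):
                raise ValueError("p_species length mismatch")
            return self.p_species
        return np.full(n_species, self.p)


@dataclass(frozen=True)
class NoiseConfig:
    """Rates (fractions of the clean record count) of injected QC violations."""

    zero_coordinates: float = 0.01
    out_of_bounds_latitude: float = 0.01
    on_land: float = 0.01
    duplicate: float = 0.01
    missing_date: float = 0.01


@dataclass
class TrueWorld:
    """Ground truth: contiguous per-species ranges and derived occupancy."""

    grid: BandGrid
    species: list[str]
    range_low: np.ndarray
    range_high: np.ndarray
    occupancy: np.ndarray = field(repr=False)  # species x band boolean
    habit: np.ndarray = field(repr=False)  # 'benthic' | 'pelagic'
    depth_low: np.ndarray = field(repr=False)
    depth_high: np.ndarray = field(repr=False)
    config: Optional[WorldConfig] = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def true_richness(self) -> np.ndarray:
        """True species count per band."""
        return self.occupancy.sum(axis=0)

    def occupancy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy.astype(int),
            index=pd.Index(self.species, name="species"),
            columns=np.arange(self.grid.n_bands),
        )


def _truncated_normal(rng, loc, scale, low, high, size):
    """Resample until inside [low, high]; keeps the shape, no edge pile-up."""
    out = rng.normal(loc, scale, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(loc, scale, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def make_world(config: WorldConfig) -> TrueWorld:
    """Draw a synthetic world; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    lo, hi = config.midpoint_range

    if config.richness_shape == "uniform":
        mid = rng.uniform(lo, hi, config.n_species)
    else:  # unimodal-tropical
        mid = _truncated_normal(rng, 0.0, config.tropical_sd, lo, hi, config.n_species)

    widths = rng.lognormal(np.log(config.width_median), config.width_sigma, config.n_species)
    range_low = np.clip(mid - widths / 2, grid.lower, grid.upper)
    range_high = np.clip(mid + widths / 2, grid.lower, grid.upper)

    occupancy = np.zeros((config.n_species, grid.n_bands), dtype=bool)
    for s in range(config.n_species):
        occupancy[s, grid.bands_for_interval(range_low[s], range_high[s])] = True

    habit = np.where(
        rng.random(config.n_species) < config.benthic_fraction, "benthic", "pelagic"
    )
    # species-level depth intervals: log-uniform centres spanning the strata
    centre = np.exp(rng.uniform(np.log(5.0), np.log(5000.0), config.n_species))
    depth_low = np.clip(centre * 0.5, 0.0, 6500.0)
    depth_high = np.clip(centre * 1.5, 0.0, 6500.0)

    digits = max(4, len(str(config.n_species)))
    names = [f"Simulatus sp{i:0{digits}d}" for i in range(config.n_species)]
    return TrueWorld(
        grid=grid,
        species=names,
        range_low=range_low,
        range_high=range_high,
        occupancy=occupancy,
        habit=habit,
        depth_low=depth_low,
        depth_high=depth_high,
        config=config,
    )


def simulate_records(
    world: TrueWorld,
    effort: EffortProfile,
    detection: Optional[DetectionModel] = None,
    seed: int = 0,
    noise: Optional[NoiseConfig] = None,
) -> pd.DataFrame:
    """Simulate raw occurrence records from a true world.

    Per band, ``Poisson(lambda_b)`` sampling events are drawn, each at a
    uniform latitude within the band, a uniform longitude in [−170, 170) and
    a uniform date in the configured window.  Every species truly present in
    the band is recorded at each event with its detection probability.
    Record depths come from the species' depth interval and are missing at
    the configured rate.  With *noise*, QC-violating rows are appended and
    the table shuffled.

    Returns a raw-schema DataFrame ready for :func:`latgaps.io_qc.apply_qc`.
    """
    detection = detection or DetectionModel()
    if effort.grid != world.grid:
        raise ValueError("effort profile and world use different grids")
    rng = np.random.default_rng(seed)
    grid = world.grid
    cfg = world.config or WorldConfig()
    t0 = pd.Timestamp(cfg.date_window[0])
    n_days = int((pd.Timestamp(cfg.date_window[1]) - t0).days) + 1
    probs = detection.probs(world.n_species)

    n_events = rng.poisson(effort.lambdas)
    sp_idx_parts, lat_parts, lon_parts, day_parts = [], [], [], []
    edges = grid.edges
    for b in range(grid.n_bands):
        e = int(n_events[b])
        if e == 0:
            continue
        present = np.flatnonzero(world.occupancy[:, b])
        if present.size == 0:
            continue
        lats = rng.uniform(edges[b], edges[b + 1], e)
        lons = rng.uniform(-170.0, 170.0, e)
        days = rng.integers(0, n_days, e)
        det = rng.random((e, present.size)) < probs[present]
        ev, sp = np.nonzero(det)
        sp_idx_parts.append(present[sp])
        lat_parts.append(lats[ev])
        lon_parts.append(lons[ev])
        day_parts.append(days[ev])

    if sp_idx_parts:
        sp_idx = np.concatenate(sp_idx_parts)
        lat = np.concatenate(lat_parts)
        lon = np.concatenate(lon_parts)
        day = np.concatenate(day_parts)
    else:
        sp_idx = np.zeros(0, dtype=int)
        lat = lon = np.zeros(0)
        day = np.zeros(0, dtype=int)

    depth = rng.uniform(world.depth_low[sp_idx], world.depth_high[sp_idx])
    depth[rng.random(depth.size) < cfg.missing_depth_rate] = np.nan
    names = np.asarray(world.species, dtype=object)

    df = pd.DataFrame(
        {
            "scientific_name": names[sp_idx],
            "latitude": lat,
            "longitude": lon,
            "event_date": t0 + pd.to_timedelta(day, unit="D"),
            "sample_depth_m": depth,
            "taxon_rank": "species",
            "taxon_group": "synthetic",
        }
    )
    if noise is not None and len(df):
        df = _inject_noise(df, noise, rng)
    return df


def _inject_noise(df: pd.DataFrame, noise: NoiseConfig, rng) -> pd.DataFrame:
    """Append QC-violating rows at the configured rates and shuffle."""
    n = len(df)

    def sample(rate: float) -> pd.DataFrame:
        k = int(round(rate * n))
        return df.iloc[rng.integers(0, n, k)].copy() if k else df.iloc[:0].copy()

    zero = sample(noise.zero_coordinates)
    zero[["latitude", "longitude"]] = 0.0

    oob = sample(noise.out_of_bounds_latitude)
    if len(oob):
        south = rng.random(len(oob)) < 0.5
        oob["latitude"] = np.where(
            south, rng.uniform(-90.0, -80.01, len(oob)), rng.uniform(85.01, 90.0, len(oob))
        )

    land = sample(noise.on_land)
    if len(land):
        land["longitude"] = rng.uniform(LAND_LON + 1.0, 179.0, len(land))

    dup = sample(noise.duplicate)  # exact copies of existing rows

    undated = sample(noise.missing_date)  # duplicate keys with the date removed
    undated["event_date"] = pd.NaT

    out = pd.concat([df, zero, oob, land, dup, undated], ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


@dataclass
class RecoveryReport:
    """Comparison of pipeline output with the generating truth."""

    table: pd.DataFrame
    n_unrecorded: int
    n_captured: int

    @property
    def capture_fraction(self) -> float:
        """Fraction of truly-present-but-unrecorded (species, band) pairs the
        gap statistic flags; NaN when sampling missed nothing."""
        if self.n_unrecorded == 0:
            return float("nan")
        return self.n_captured / self.n_unrecorded


def recovery_report(world: TrueWorld, observed: OccupancyMatrix) -> RecoveryReport:
    """Score gap detection against the ground truth.

    *observed* must be built on the world's grid with rows aligned to (a
    subset of) the world's species; species never recorded contribute
    all-false rows.  Per band the report lists true richness, observed
    richness, the gap statistic's missing richness, and the count of species
    truly present but unrecorded.  Absences at a species' range edges are
    invisible to the gap statistic (edge truncation) and therefore count as
    uncaptured.
    """
    if observed.grid != world.grid:
        raise ValueError("observed occupancy uses a different grid")
    unknown = set(observed.species) - set(world.species)
    if unknown:
        raise ValueError(f"observed species not in world: {sorted(unknown)[:5]}")
    pos = {s: i for i, s in enumerate(world.species)}
    obs = np.zeros_like(world.occupancy)
    for i, s in enumerate(observed.species):
        obs[pos[s]] = observed.presence[i]

    gap = interior_gap_matrix(obs)
    unrecorded = world.occupancy & ~obs
    captured = unrecorded & gap

    table = pd.DataFrame(
        {
            "band": np.arange(world.grid.n_bands),
            "true_richness": world.true_richness,
            "observed_richness": obs.sum(axis=0),
            "missing_richness": gap.sum(axis=0),
            "n_unrecorded": unrecorded.sum(axis=0),
            "n_captured": captured.sum(axis=0),
        }
    )
    return RecoveryReport(
        table=table,
        n_unrecorded=int(unrecorded.sum()),
        n_captured=int(captured.sum()),
    )
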