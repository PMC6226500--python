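"""Reading occurrence tables and quality control.

Occurrence data are handled as :class:`pandas.DataFrame` objects with a fixed
column schema.  Raw tables carry::

    scientific_name, latitude, longitude, event_date, sample_depth_m,
    taxon_rank, taxon_group

and cleaned tables carry::

    species_name, latitude, longitude, event_date, sample_depth_m, taxon_group

:func:`apply_qc` runs the filters in a fixed, audited order; every dropped
record is counted in a :class:`QCReport` so that
``n_input - sum(removed) == n_output`` always holds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "RAW_COLUMNS",
    "CLEAN_COLUMNS",
    "DARWIN_CORE_MAP",
    "LATITUDE_BOUNDS",
    "NameStatusTable",
    "QCReport",
    "read_occurrences",
    "write_occurrences",
    "round_half_away",
    "apply_qc",
]

#: Canonical raw-record columns.
RAW_COLUMNS = (
    "scientific_name",
    "latitude",
    "longitude",
    "event_date",
    "sample_depth_m",
    "taxon_rank",
    "taxon_group",
)

#: Canonical cleaned-record columns.
CLEAN_COLUMNS = (
    "species_name",
    "latitude",
    "longitude",
    "event_date",
    "sample_depth_m",
    "taxon_group",
)

#: Default column map: Darwin Core source columns for each canonical field.
DARWIN_CORE_MAP: dict[str, str] = {
    "scientific_name": "scientificName",
    "latitude": "decimalLatitude",
    "longitude": "decimalLongitude",
    "event_date": "eventDate",
    "sample_depth_m": "minimumDepthInMeters",
    "taxon_rank": "taxonRank",
    "taxon_group": "taxonGroup",
}

#: Retained latitude interval (inclusive): south of -80 lies the Antarctic
#: continent, north of 85 the Arctic ice cap.
LATITUDE_BOUNDS = (-80.0, 85.0)

_NAME_STATUSES = frozenset({"accepted", "synonym", "invalid", "non_marine", "fossil"})


@dataclass(frozen=True)
class NameStatusTable:
    """Taxonomic name resolution table (stand-in for a live registry lookup).

    Maps each raw scientific name to a status and, for accepted names and
    synonyms, the accepted binomial.  Names absent from the table are treated
    by :func:`apply_qc` as unresolved and dropped under their own rule.
    """

    table: Mapping[str, tuple[str, Optional[str]]]

    def __post_init__(self) -> None:
        for name, (status, accepted) in self.table.items():
            if status not in _NAME_STATUSES:
                raise ValueError(f"unknown name status {status!r} for {name!r}")
            if (accepted is not None) != (status in ("accepted", "synonym")):
                raise ValueError(
                    f"accepted_name must be present iff status is accepted/synonym "
                    f"(name {name!r}, status {status!r})"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.table

    def status(self, name: str) -> Optional[str]:
        entry = self.table.get(name)
        return entry[0] if entry else None

    def accepted(self, name: str) -> Optional[str]:
        entry = self.table.get(name)
        return entry[1] if entry else None

    @classmethod
    def accept_all(cls, names: Iterable[str]) -> "NameStatusTable":
        """Table accepting every listed name as-is (used for synthetic data)."""
        return cls({n: ("accepted", n) for n in names})

    @classmethod
    def from_csv(cls, path: str | Path) -> "NameStatusTable":
        """Read a three-column CSV: raw_name, status, accepted_name."""
        df = pd.read_csv(path, dtype=str)
        required = {"raw_name", "status"}
        if not required.issubset(df.columns):
            raise ValueError(f"name table needs columns {sorted(required)}")
        accepted = df.get("accepted_name", pd.Series([None] * len(df)))
        table = {
            row.raw_name: (row.status, acc if isinstance(acc, str) and acc else None)
            for row, acc in zip(df.itertuples(), accepted)
        }
        return cls(table)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(n, s, a) for n, (s, a) in self.table.items()],
            columns=["raw_name", "status", "accepted_name"],
        ).to_csv(path, index=False)


@dataclass
class QCReport:
    """Audit trail of a QC run: ordered per-rule removal counts."""

    n_input: int = 0
    n_output: int = 0
    steps: list[tuple[str, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def removed(self, rule: str) -> int:
        for name, n in self.steps:
            if name == rule:
                return n
        raise KeyError(rule)

    def total_removed(self) -> int:
        return sum(n for _, n in self.steps)

    def check(self) -> None:
        if self.n_input - self.total_removed() != self.n_output:
            raise AssertionError(
                f"QC bookkeeping broken: {self.n_input} - {self.total_removed()} "
                f"!= {self.n_output}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "steps": [{"rule": r, "n_removed": n} for r, n in self.steps],
            "warnings": list(self.warnings),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __str__(self) -> str:
        lines = [f"QC report: {self.n_input} records in, {self.n_output} out"]
        for rule, n in self.steps:
            lines.append(f"  {rule:<24s} -{n}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)


def read_occurrences(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    delimiter: Optional[str] = None,
    taxon_group: Optional[str] = None,
) -> pd.DataFrame:
    """Read a delimited occurrence table into the canonical raw schema.

    Parameters
    ----------
    path
        CSV/TSV file.  The delimiter is taken from the extension
        (``.tsv``/``.tab`` → tab, otherwise comma) unless given explicitly.
    column_map
        Mapping from canonical field name to source column.  Defaults to the
        Darwin Core names in :data:`DARWIN_CORE_MAP`.  Optional fields
        (``sample_depth_m``, ``taxon_rank``, ``taxon_group``) may be omitted
        from the map; mandatory mapped columns must exist in the file.
    taxon_group
        Constant group label used when no ``taxon_group`` column is mapped.

    Unparseable coordinates, depths and dates are coerced to missing;
    no rounding or filtering happens at read time.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cmap = dict(DARWIN_CORE_MAP if column_map is None else column_map)

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    optional = {"sample_depth_m", "taxon_rank", "taxon_group"}
    out = pd.DataFrame(index=raw.index)
    for field_name in RAW_COLUMNS:
        src = cmap.get(field_name)
        if src not in raw.columns and field_name in raw.columns:
            src = field_name  # canonical names accepted as-is
        if src is None or src not in raw.columns:
            if field_name in optional:
                out[field_name] = pd.NA
                continue
            raise KeyError(
                f"column map for {field_name!r} refers to {src!r}, "
                f"not present in {path.name}"
            )
        out[field_name] = raw[src]

    for col in ("latitude", "longitude", "sample_depth_m"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["event_date"] = pd.to_datetime(out["event_date"], errors="coerce", format="mixed")
    out["taxon_rank"] = out["taxon_rank"].fillna("unknown").astype(str).str.lower()
    if out["taxon_group"].isna().all():
        out["taxon_group"] = taxon_group if taxon_group is not None else "all"
    return out


def write_occurrences(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a (raw or cleaned) occurrence table as delimited text."""
    df.to_csv(path, sep=delimiter, index=False, date_format="%Y-%m-%d")


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (0.005 → 0.01, −0.005 → −0.01).

    Deterministic across platforms, unlike banker's rounding; applied to
    coordinates so that e.g. both hemispheres round symmetrically.
    """
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


def _collapse_to_binomial(names: pd.Series) -> pd.Series:
    """First two whitespace tokens: drops subspecific epithets."""
    return names.astype(str).str.strip().str.split().str[:2].str.join(" ")


def apply_qc(
    records: pd.DataFrame,
    names: NameStatusTable,
    land_mask: Optional[Callable] = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the quality-control filters in a fixed order.

    Order of rules (each logged in the report):

    1. ``missing_coordinates`` — latitude or longitude absent;
    2. ``zero_coordinates`` — latitude and longitude both exactly 0;
    3. ``on_land`` — ``land_mask(lat, lon)`` true.  Skipped with a warning
       when no mask is supplied (a coastline is not bundled);
    4. coordinates rounded to two decimals (half away from zero; no drop);
    5. ``rank_above_species`` — records above species rank dropped;
       subspecies collapsed to the binomial;
    6. ``name_unresolved`` / ``name_invalid`` — names absent from *names*
       dropped as unresolved; invalid, fossil and non-marine names dropped;
       synonyms mapped to their accepted name;
    7. ``latitude_out_of_bounds`` — latitude outside [−80, 85] (inclusive);
    8. ``duplicate_records`` — exact (species, lat, lon, date) duplicates
       keep the first occurrence; undated records are kept only when their
       (species, lat, lon) is unique in the dataset.

    Negative sample depths are set to missing (warned, not dropped).

    ``records`` may be a raw table or a previously cleaned one (cleaned
    tables lack ``scientific_name``/``taxon_rank``; they are treated as
    species-rank records), which makes the function idempotent.

    Returns the cleaned table and the :class:`QCReport`.
    """
    df = records.copy()
    if "scientific_name" not in df.columns:
        if "species_name" not in df.columns:
            raise KeyError("records need a scientific_name or species_name column")
        df["scientific_name"] = df["species_name"]
    if "taxon_rank" not in df.columns:
        df["taxon_rank"] = "species"
    if "taxon_group" not in df.columns:
        df["taxon_group"] = "all"
    if "sample_depth_m" not in df.columns:
        df["sample_depth_m"] = np.nan
    if "event_date" not in df.columns:
        df["event_date"] = pd.NaT
    df["event_date"] = pd.to_datetime(df["event_date"], errors="coerce", format="mixed")

    report = QCReport(n_input=len(df))

    def drop(rule: str, bad: pd.Series) -> None:
        nonlocal df
        n = int(bad.sum())
        report.steps.append((rule, n))
        if n:
            df = df.loc[~bad]

    # 1. missing coordinates
    drop("missing_coordinates", df["latitude"].isna() | df["longitude"].isna())

    # 2. (0, 0) coordinates
    drop("zero_coordinates", (df["latitude"] == 0.0) & (df["longitude"] == 0.0))

    # 3. on-land records (pluggable predicate; 20 km-buffered coastline not bundled)
    if land_mask is not None:
        try:
            on_land = np.asarray(land_mask(df["latitude"].to_numpy(), df["longitude"].to_numpy()))
        except Exception:
            on_land = np.fromiter(
                (bool(land_mask(la, lo)) for la, lo in zip(df["latitude"], df["longitude"])),
                dtype=bool,
                count=len(df),
            )
        drop("on_land", pd.Series(on_land, index=df.index))
    else:
        report.steps.append(("on_land", 0))
        msg = "no land mask supplied; on-land filtering skipped"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    # 4. round coordinates to two decimals (precedes deduplication so that
    #    near-identical coordinates collapse into one sampling event)
    df["latitude"] = round_half_away(df["latitude"].to_numpy(), 2)
    df["longitude"] = round_half_away(df["longitude"].to_numpy(), 2)

    # 5. taxonomic rank: keep species and subspecies, collapse the latter
    rank = df["taxon_rank"].astype(str).str.lower()
    drop("rank_above_species", ~rank.isin(["species", "subspecies"]))
    df["species_name"] = _collapse_to_binomial(df["scientific_name"])

    # 6. name resolution via the supplied table
    accepted_targets = {a for s, a in names.table.values() if a is not None}
    resolution: dict[str, Optional[str]] = {}
    for name in df["species_name"].unique():
        status = names.status(name)
        if status in ("accepted", "synonym"):
            resolution[name] = names.accepted(name)
        elif status is None and name in accepted_targets:
            # a name only known as a synonym's target is implicitly accepted
            resolution[name] = name
        else:
            resolution[name] = None  # unresolved or invalid/fossil/non_marine
    known_names = set(names.table) | accepted_targets
    drop("name_unresolved", ~df["species_name"].isin(known_names))
    resolved = df["species_name"].map(resolution)
    drop("name_invalid", resolved.isna())
    df["species_name"] = df["species_name"].map(resolution)

    # 7. latitude bounds (inclusive)
    lo, hi = LATITUDE_BOUNDS
    drop("latitude_out_of_bounds", (df["latitude"] < lo) | (df["latitude"] > hi))

    # 8. deduplication on (species, lat, lon, date); undated records survive
    #    only when (species, lat, lon) is otherwise unique
    key_cols = ["species_name", "latitude", "longitude", "event_date"]
    dated_dup = df.duplicated(subset=key_cols)  # NaT compares equal here
    coord_key_size = df.groupby(
        ["species_name", "latitude", "longitude"], sort=False
    )["latitude"].transform("size")
    undated_dup = df["event_date"].isna() & (coord_key_size > 1)
    drop("duplicate_records", dated_dup | undated_dup)

    # depth validation (strata bookkeeping, not a record drop)
    n_neg = int((df["sample_depth_m"] < 0).sum())
    if n_neg:
        df.loc[df["sample_depth_m"] < 0, "sample_depth_m"] = np.nan
        report.warnings.append(f"{n_neg} negative sample depths set to missing")

    out = df.loc[:, list(CLEAN_COLUMNS)].reset_index(drop=True)
    report.n_output = len(out)
    report.check()
    return out, report
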