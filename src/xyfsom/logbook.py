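"""Trip-level logbook tables and their encodings.

A logbook is one row per fishing trip: trip id, year, season (cold/warm),
gear type, and one kg/trip catch-rate column per species or commercial
group. This module holds the in-memory container (:class:`TripTable`), the
column standardization used before map training, the one-hot class encoding
of the trip factors (the Y matrix of a supervised SOM), and the CSV
reader/writer for the interchange schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GEARS = ("BL", "VL", "VL_SBL")
SEASONS = ("cold", "warm")
#: Canonical ordering of classification factors in combined class labels.
FACTOR_ORDER = ("gear", "season", "year")
METADATA_COLUMNS = ("trip_id", "year", "season", "gear")


@dataclass
class TripTable:
    """Trips x (metadata + species catch-rate columns).

    ``catch`` is an (n_trips, n_species) float array in kg/trip; zero means
    the species was not landed on that trip.
    """

    trip_id: np.ndarray
    year: np.ndarray
    season: np.ndarray
    gear: np.ndarray
    catch: np.ndarray
    species_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.trip_id = np.asarray(self.trip_id, dtype=object)
        self.year = np.asarray(self.year, dtype=int)
        self.season = np.asarray(self.season, dtype=object)
        self.gear = np.asarray(self.gear, dtype=object)
        self.catch = np.asarray(self.catch, dtype=float)
        self.species_names = tuple(str(s) for s in self.species_names)
        n = len(self.trip_id)
        if self.catch.ndim != 2 or self.catch.shape != (n, len(self.species_names)):
            raise ValueError(
                f"catch matrix shape {self.catch.shape} does not match "
                f"{n} trips x {len(self.species_names)} species"
            )
        for name, arr in (("year", self.year), ("season", self.season), ("gear", self.gear)):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if len(set(self.species_names)) != len(self.species_names):
            raise ValueError("species_names must be unique")
        bad_season = set(self.season) - set(SEASONS)
        if bad_season:
            raise ValueError(f"unknown season values {sorted(bad_season)}; allowed {SEASONS}")
        bad_gear = set(self.gear) - set(GEARS)
        if bad_gear:
            raise ValueError(f"unknown gear values {sorted(bad_gear)}; allowed {GEARS}")
        if np.any(~np.isfinite(self.catch)):
            i, j = np.argwhere(~np.isfinite(self.catch))[0]
            raise ValueError(
                f"non-finite catch at trip {self.trip_id[i]!r} (row {i}), "
                f"species {self.species_names[j]!r}"
            )
        if np.any(self.catch < 0):
            i, j = np.argwhere(self.catch < 0)[0]
            raise ValueError(
                f"negative catch at trip {self.trip_id[i]!r} (row {i}), "
                f"species {self.species_names[j]!r}"
            )

    @property
    def n_trips(self) -> int:
        return len(self.trip_id)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def subset(self, index: np.ndarray) -> "TripTable":
        """Row subset (positional indices or boolean mask)."""
        index = np.asarray(index)
        return TripTable(
            trip_id=self.trip_id[index],
            year=self.year[index],
            season=self.season[index],
            gear=self.gear[index],
            catch=self.catch[index],
            species_names=self.species_names,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trip_id": self.trip_id,
                "year": self.year,
                "season": self.season,
                "gear": self.gear,
            }
        )
        for j, sp in enumerate(self.species_names):
            df[sp] = self.catch[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TripTable":
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"logbook is missing required columns {missing}")
        species = [c for c in df.columns if c not in METADATA_COLUMNS]
        if not species:
            raise ValueError("logbook has no species columns")
        return cls(
            trip_id=df["trip_id"].to_numpy(dtype=object),
            year=df["year"].to_numpy(dtype=int),
            season=df["season"].to_numpy(dtype=object),
            gear=df["gear"].to_numpy(dtype=object),
            catch=df[species].to_numpy(dtype=float),
            species_names=tuple(species),
        )


# ---------------------------------------------------------------------------
# Column standardization
# ---------------------------------------------------------------------------

def standardize_columns(table: TripTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score every species column (sample SD, denominator n-1).

    Returns ``(Z, column_means, column_sds)``. Constant columns are returned
    as all-zeros with their SD recorded as 1, so that de-standardization is
    always the exact inverse. Raises on empty tables and non-finite entries
    (the latter is already impossible for a validated :class:`TripTable`).
    """
    if table.n_trips == 0:
        raise ValueError("no trips")
    if table.n_trips < 2:
        raise ValueError("standardization needs at least 2 trips")
    X = table.catch
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds = np.where(sds == 0.0, 1.0, sds)
    return (X - means) / sds, means, sds


def destandardize_columns(Z: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Inverse of :func:`standardize_columns`."""
    return np.asarray(Z, dtype=float) * sds + means


# ---------------------------------------------------------------------------
# Class encoding (the Y matrix)
# ---------------------------------------------------------------------------

@dataclass
class ClassEncoding:
    """One-hot encoding of trip factors into a class indicator matrix.

    Class labels concatenate the requested factor levels in the fixed order
    gear | season | year, e.g. ``"BL|cold|2007"``; the label list covers the
    distinct combinations observed in the encoded table.
    """

    factors: tuple[str, ...]
    class_labels: tuple[str, ...]
    indicator: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)


def _row_labels(table: TripTable, factors: Sequence[str]) -> np.ndarray:
    parts = {
        "gear": table.gear.astype(str),
        "season": table.season.astype(str),
        "year": table.year.astype(str),
    }
    cols = [parts[f] for f in factors]
    out = cols[0]
    for c in cols[1:]:
        out = np.char.add(np.char.add(out.astype(str), "|"), c.astype(str))
    return np.asarray(out, dtype=object)


def _canonical_factors(factors: Iterable[str]) -> tuple[str, ...]:
    factors = set(factors)
    unknown = factors - set(FACTOR_ORDER)
    if unknown:
        raise ValueError(f"unknown factors {sorted(unknown)}; allowed {FACTOR_ORDER}")
    if not factors:
        raise ValueError("at least one factor is required")
    return tuple(f for f in FACTOR_ORDER if f in factors)


def encode_classes(
    table: TripTable, factors: Iterable[str] = FACTOR_ORDER
) -> ClassEncoding:
    """Build the one-hot Y matrix for the requested trip factors.

    Label order is deterministic: gear in (BL, VL, VL_SBL), season in
    (cold, warm), year ascending, nested in that priority.
    """
    factors = _canonical_factors(factors)
    if table.n_trips == 0:
        raise ValueError("no trips")
    labels = _row_labels(table, factors)

    level_order = {
        "gear": {g: i for i, g in enumerate(GEARS)},
        "season": {s: i for i, s in enumerate(SEASONS)},
    }

    def sort_key(label: str):
        parts = label.split("|")
        key = []
        for f, p in zip(factors, parts):
            key.append(level_order[f][p] if f in level_order else int(p))
        return tuple(key)

    class_labels = tuple(sorted(set(labels), key=sort_key))
    index = {lab: i for i, lab in enumerate(class_labels)}
    indicator = np.zeros((table.n_trips, len(class_labels)))
    for i, lab in enumerate(labels):
        indicator[i, index[lab]] = 1.0
    return ClassEncoding(factors=factors, class_labels=class_labels, indicator=indicator)


def labels_for_table(
    table: TripTable, factors: Sequence[str], known_labels: Sequence[str]
) -> np.ndarray:
    """Map each trip to its class label, erroring on combinations never seen
    by the encoding (e.g. a year absent from training)."""
    factors = _canonical_factors(factors)
    labels = _row_labels(table, factors)
    unseen = sorted(set(labels) - set(known_labels))
    if unseen:
        raise ValueError(f"unseen class level(s) at prediction time: {unseen}")
    return labels


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_logbook(path: str | Path) -> TripTable:
    """Read and validate a logbook CSV.

    Schema: header ``trip_id,year,season,gear`` followed by one column per
    species (kg/trip). Rows with missing year/season/gear are dropped with a
    logged count; unknown gear/season tokens and negative catches raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing required columns {missing_cols}")

    incomplete = df[["year", "season", "gear"]].isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "%s: dropping %d row(s) with missing year/season/gear", path.name, int(incomplete.sum())
        )
        df = df.loc[~incomplete].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path.name}: no usable trips")

    for col, allowed in (("season", SEASONS), ("gear", GEARS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path.name}: unknown {col} token {df[col].iloc[row]!r} at data row {row}"
            )

    species = [c for c in df.columns if c not in METADATA_COLUMNS]
    catch = df[species].to_numpy(dtype=float)
    if np.any(~np.isfinite(catch)):
        i, j = np.argwhere(~np.isfinite(catch))[0]
        raise ValueError(f"{path.name}: non-finite catch at data row {i}, column {species[j]!r}")
    if np.any(catch < 0):
        i, j = np.argwhere(catch < 0)[0]
        raise ValueError(f"{path.name}: negative catch at data row {i}, column {species[j]!r}")
    return TripTable.from_dataframe(df)


def write_logbook(table: TripTable, path: str | Path) -> None:
    """Write a TripTable to the CSV interchange schema (UTF-8, '.' decimal)."""
    table.to_dataframe().to_csv(path, index=False)
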