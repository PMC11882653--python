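"""Desk-scale realized-niche summaries.

Occurrence cleaning with an audit trail, nearest-cell climate joins
against a pre-extracted cell table or small in-memory grid, and
per-species precipitation-breadth summaries with a rank-vs-breadth
monotone trend test.  Retrieval of occurrence or climate data from
external services is deliberately out of scope; inputs are small local
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import SchemaError

#: Darwin-Core-style aliases accepted on input.
_COLUMN_ALIASES = {
    "decimalLatitude": "lat",
    "decimalLongitude": "lon",
    "scientificName": "species",
}

YEAR_MIN, YEAR_MAX = 1979, 2013  # inclusive occurrence window


@dataclass(frozen=True)
class CleaningAudit:
    n_input: int
    missing_coords: int
    bad_coords: int
    out_of_period: int
    duplicates_removed: int
    masked: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.missing_coords
            + self.bad_coords
            + self.out_of_period
            + self.duplicates_removed
            + self.masked
        )
        assert self.n_input == self.n_retained + removed, "audit counts must sum"


def clean_occurrences(
    records: pd.DataFrame,
    *,
    year_min: int = YEAR_MIN,
    year_max: int = YEAR_MAX,
    land_mask=None,
) -> Tuple[pd.DataFrame, CleaningAudit]:
    """Filter occurrence rows, reporting how many each stage removed.

    Stages, in order: missing coordinates; coordinates outside
    [−90, 90] × [−180, 180]; year outside [``year_min``, ``year_max``]
    (inclusive at both ends); exact (species, lat, lon, year) duplicates;
    optional land mask (``land_mask(lat, lon) -> bool`` vectorised).
    Cleaning is idempotent.
    """
    df = records.rename(columns=_COLUMN_ALIASES).copy()
    required = ["species", "lat", "lon", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence table missing columns {missing}")
    n_input = len(df)

    has_coords = df["lat"].notna() & df["lon"].notna()
    n_missing = int((~has_coords).sum())
    df = df[has_coords]

    in_range = df["lat"].between(-90, 90) & df["lon"].between(-180, 180)
    n_bad = int((~in_range).sum())
    df = df[in_range]

    in_period = df["year"].between(year_min, year_max)
    n_period = int((~in_period).sum())
    df = df[in_period]

    deduped = df.drop_duplicates(subset=["species", "lat", "lon", "year"])
    n_dup = len(df) - len(deduped)
    df = deduped

    n_masked = 0
    if land_mask is not None:
        on_land = np.asarray(land_mask(df["lat"].to_numpy(), df["lon"].to_numpy()), bool)
        n_masked = int((~on_land).sum())
        df = df[on_land]

    audit = CleaningAudit(
        n_input=n_input,
        missing_coords=n_missing,
        bad_coords=n_bad,
        out_of_period=n_period,
        duplicates_removed=n_dup,
        masked=n_masked,
        n_retained=len(df),
    )
    return df.reset_index(drop=True), audit


@dataclass(frozen=True)
class ClimateGrid:
    """A small gridded climate lookup held in memory.

    ``values[i, j]`` is the climate value at latitude ``lats[i]``,
    longitude ``lons[j]`` (cell centers).  Ties between equidistant cells
    break deterministically to the lower-indexed cell.
    """

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    @classmethod
    def from_cell_table(cls, table: pd.DataFrame) -> "ClimateGrid":
        """Build from a (lat, lon, value) pre-extracted cell table."""
        for c in ("lat", "lon", "value"):
            if c not in table.columns:
                raise SchemaError(f"climate cell table missing column {c!r}")
        lats = np.sort(table["lat"].unique())
        lons = np.sort(table["lon"].unique())
        values = np.full((len(lats), len(lons)), np.nan)
        li = {v: i for i, v in enumerate(lats)}
        lj = {v: j for j, v in enumerate(lons)}
        for _, row in table.iterrows():
            values[li[row["lat"]], lj[row["lon"]]] = row["value"]
        return cls(lats=lats, lons=lons, values=values)

    def _nearest(self, coords: np.ndarray, axis_vals: np.ndarray) -> np.ndarray:
        # lower-indexed cell wins exact ties: searchsorted + half-step compare
        d = np.abs(coords[:, None] - axis_vals[None, :])
        return np.argmin(d, axis=1)  # argmin returns the first (lowest) index on ties

    def lookup(self, lats, lons) -> np.ndarray:
        lats = np.atleast_1d(np.asarray(lats, float))
        lons = np.atleast_1d(np.asarray(lons, float))
        i = self._nearest(lats, self.lats)
        j = self._nearest(lons, self.lons)
        return self.values[i, j]

    def covers(self, lats, lons, *, pad_factor: float = 1.0) -> np.ndarray:
        """True where a coordinate is within the grid extent (± half a cell)."""
        def _inside(c, axis):
            if len(axis) > 1:
                half = pad_factor * 0.5 * float(np.diff(axis).max())
            else:
                half = np.inf
            return (c >= axis[0] - half) & (c <= axis[-1] + half)

        lats = np.atleast_1d(np.asarray(lats, float))
        lons = np.atleast_1d(np.asarray(lons, float))
        return _inside(lats, self.lats) & _inside(lons, self.lons)


def join_climate(records: pd.DataFrame, grid: ClimateGrid, *, column: str = "precip") -> pd.DataFrame:
    """Nearest-cell climate join; uncovered records flagged, not dropped."""
    df = records.rename(columns=_COLUMN_ALIASES).copy()
    for c in ("lat", "lon"):
        if c not in df.columns:
            raise SchemaError(f"occurrence table missing column {c!r}")
    if df.empty:
        raise ValueError("no records to join")
    covered = grid.covers(df["lat"].to_numpy(), df["lon"].to_numpy())
    if not covered.any():
        raise ValueError("no overlap between records and climate grid")
    values = grid.lookup(df["lat"].to_numpy(), df["lon"].to_numpy())
    df[column] = np.where(covered, values, np.nan)
    df[f"{column}_covered"] = covered
    return df


@dataclass(frozen=True)
class BreadthSummary:
    species: str
    n: int
    median: float
    iqr: float
    range_5_95: float


@dataclass(frozen=True)
class NicheBreadthResult:
    summaries: Tuple[BreadthSummary, ...]
    spearman_rho: Optional[float]  # rank vs 5–95% range width; None if < 2 species
    spearman_p: Optional[float]
    excluded: Tuple[str, ...]  # species with too few values for the trend


def niche_breadth(
    values_by_species: Mapping[str, Sequence[float]],
    ranks: Mapping[str, int],
    *,
    min_n: int = 5,
) -> NicheBreadthResult:
    """Per-species spread summaries plus a rank-vs-breadth trend test.

    Breadth is the 5–95% inter-quantile range; the trend test is a
    Spearman rank correlation of habitat rank against breadth (expected
    negative when strongly associated species occupy narrower envelopes).
    Species with fewer than ``min_n`` values are summarised but excluded
    from the trend.
    """
    summaries, excluded = [], []
    xs, ys = [], []
    for species, vals in values_by_species.items():
        v = np.asarray([x for x in np.asarray(vals, float) if np.isfinite(x)])
        if len(v) == 0:
            excluded.append(species)
            continue
        q5, q25, q50, q75, q95 = np.percentile(v, [5, 25, 50, 75, 95])
        summaries.append(
            BreadthSummary(
                species=species,
                n=len(v),
                median=float(q50),
                iqr=float(q75 - q25),
                range_5_95=float(q95 - q5),
            )
        )
        if len(v) >= min_n and species in ranks:
            xs.append(ranks[species])
            ys.append(float(q95 - q5))
        elif len(v) < min_n:
            excluded.append(species)
    rho = p = None
    if len(xs) >= 2:
        if np.ptp(ys) == 0 or np.ptp(xs) == 0:
            rho, p = 0.0, 1.0
        else:
            res = sps.spearmanr(xs, ys)
            rho, p = float(res.statistic), float(res.pvalue)
    return NicheBreadthResult(
        summaries=tuple(summaries),
        spearman_rho=rho,
        spearman_p=p,
        excluded=tuple(dict.fromkeys(excluded)),
    )
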