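"""Reading, validation, filtering and rescaling of abundance time series.

The canonical input mirrors the public Living Planet Database portal layout:
a wide CSV with one row per monitored population, metadata columns and one
column per calendar year (1970-2014 by default).  Blank or sentinel cells mean
"not surveyed that year".  A long format (series_id, year, abundance) is also
accepted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAXON_CLASSES = (
    "Actinopterygii",
    "Elasmobranchii",
    "Amphibia",
    "Aves",
    "Mammalia",
    "Reptilia",
)
REALMS = ("freshwater", "marine", "terrestrial")

#: default sentinel strings meaning "not surveyed"
DEFAULT_SENTINELS = ("", "NA", "NULL")

#: default metadata column map for the wide portal dialect
DEFAULT_COLUMN_MAP = {
    "id": "ID",
    "binomial": "Binomial",
    "class": "Class",
    "realm": "System",
    "biome": "Biome",
    "lat": "Latitude",
    "lon": "Longitude",
    "unit": "Units",
}

#: abundance-metric labels treated as true population counts (not indices)
COUNT_LIKE_UNITS = frozenset(
    {
        "number of individuals",
        "pairs",
        "nests",
        "population estimate",
        "count",
        "individuals",
    }
)


class FormatError(ValueError):
    """Input file does not match the expected dialect."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass
class PopulationTimeSeries:
    """One monitored population: metadata plus (year, abundance) records.

    Years are strictly increasing; abundances are finite and non-negative.
    """

    series_id: str
    species: str = ""
    taxon_class: str = ""
    realm: str = ""
    biome: str = ""
    latitude: float = np.nan
    longitude: float = np.nan
    unit: str = ""
    iucn_category: str | None = None
    threats: frozenset = field(default_factory=frozenset)
    years: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    abundances: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.years.size != self.abundances.size:
            raise ValidationError(
                f"{self.series_id}: years and abundances differ in length"
            )
        if self.years.size == 0:
            raise ValidationError(f"{self.series_id}: no observations")
        if not np.all(np.isfinite(self.abundances)):
            raise ValidationError(f"{self.series_id}: non-finite abundance")
        if np.any(self.abundances < 0):
            raise ValidationError(f"{self.series_id}: negative abundance")

    @property
    def n_obs(self) -> int:
        return int(self.years.size)

    @property
    def duration(self) -> int:
        """Span of monitoring in years (last year minus first)."""
        return int(self.years[-1] - self.years[0])

    def is_constant(self, rtol: float = 1e-12) -> bool:
        a = self.abundances
        return bool(np.ptp(a) <= rtol * max(1.0, abs(a).max()))


@dataclass
class ScaledSeries:
    """A population series after within-series rescaling of abundance.

    ``minmax01`` maps onto [0, 1]; ``zscore`` centres on zero with unit
    sample standard deviation.  Constant series cannot be rescaled and are
    flagged instead: they map to all-0.5 (minmax01) or all-0 (zscore).
    """

    series_id: str
    years: np.ndarray
    values: np.ndarray
    scaling: str
    constant_flag: bool = False

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_obs(self) -> int:
        return int(self.years.size)


def _parse_cell(raw, sentinels) -> float | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if s in sentinels or s.lower() == "nan":
        return None
    return float(s)


def read_lpd_wide(
    path,
    column_map: dict | None = None,
    year_range: tuple[int, int] = (1970, 2014),
    sentinels=DEFAULT_SENTINELS,
) -> list[PopulationTimeSeries]:
    """Read a wide-format portal-style CSV into a list of series.

    Parameters
    ----------
    path : str or file-like
        CSV with the metadata columns named in ``column_map`` and one column
        per calendar year within ``year_range``.
    column_map : dict, optional
        Maps logical names (id, binomial, class, realm, biome, lat, lon,
        unit) to the file's column headers.  Defaults to the portal headers.
    sentinels : iterable of str
        Cell values meaning "not surveyed"; such years are simply absent
        from the resulting series.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical in ("id", "binomial"):
        if cmap[logical] not in df.columns:
            raise FormatError(f"missing mandatory column: {cmap[logical]!r}")
    year_cols = [
        c for c in df.columns if c.isdigit() and year_range[0] <= int(c) <= year_range[1]
    ]
    if not year_cols:
        raise FormatError(
            f"no year columns in range {year_range[0]}-{year_range[1]} found"
        )
    sentinels = set(sentinels)
    out = []
    for _, row in df.iterrows():
        sid = row[cmap["id"]]
        years, vals = [], []
        for c in year_cols:
            v = _parse_cell(row[c], sentinels)
            if v is not None:
                years.append(int(c))
                vals.append(v)
        if not years:
            logger.warning("series %s has no surveyed years; skipped", sid)
            continue
        if min(vals) < 0:
            raise ValidationError(f"negative abundance in series {sid}")

        def get(logical, default=""):
            col = cmap.get(logical)
            return row[col] if col in df.columns else default

        lat = get("lat")
        lon = get("lon")
        out.append(
            PopulationTimeSeries(
                series_id=str(sid),
                species=get("binomial"),
                taxon_class=get("class"),
                realm=get("realm"),
                biome=get("biome"),
                latitude=float(lat) if lat not in ("", None) else np.nan,
                longitude=float(lon) if lon not in ("", None) else np.nan,
                unit=get("unit"),
                years=np.array(sorted(years)),
                abundances=np.array(vals)[np.argsort(years)],
            )
        )
    return out


def read_long(path, id_col="series_id", year_col="year", value_col="abundance",
              meta_cols: dict | None = None) -> list[PopulationTimeSeries]:
    """Read a long-format CSV (one row per survey) into series.

    ``meta_cols`` maps PopulationTimeSeries field names to column headers for
    any per-series metadata carried in the long table (constant within a
    series).
    """
    df = pd.read_csv(path)
    for c in (id_col, year_col, value_col):
        if c not in df.columns:
            raise FormatError(f"missing mandatory column: {c!r}")
    meta_cols = meta_cols or {}
    out = []
    for sid, g in df.groupby(id_col, sort=False):
        g = g.sort_values(year_col)
        meta = {}
        for fname, col in meta_cols.items():
            if col in g.columns:
                meta[fname] = g[col].iloc[0]
        out.append(
            PopulationTimeSeries(
                series_id=str(sid),
                years=g[year_col].to_numpy(dtype=int),
                abundances=g[value_col].to_numpy(dtype=float),
                **meta,
            )
        )
    return out


def to_long_frame(data: list[PopulationTimeSeries]) -> pd.DataFrame:
    """Canonical long table: one row per survey, metadata repeated."""
    rows = []
    for s in data:
        for y, a in zip(s.years, s.abundances):
            rows.append(
                dict(
                    series_id=s.series_id,
                    year=int(y),
                    abundance=a,
                    species=s.species,
                    taxon_class=s.taxon_class,
                    realm=s.realm,
                    biome=s.biome,
                    latitude=s.latitude,
                    longitude=s.longitude,
                    unit=s.unit,
                )
            )
    return pd.DataFrame(rows)


def write_long(data: list[PopulationTimeSeries], path, metadata_sidecar=None) -> None:
    """Write the canonical long CSV (and an optional JSON metadata sidecar)."""
    to_long_frame(data).to_csv(path, index=False)
    if metadata_sidecar is not None:
        meta = {
            s.series_id: dict(
                species=s.species,
                taxon_class=s.taxon_class,
                realm=s.realm,
                biome=s.biome,
                unit=s.unit,
                iucn_category=s.iucn_category,
                threats=sorted(s.threats),
                n_obs=s.n_obs,
            )
            for s in data
        }
        with open(metadata_sidecar, "w") as fh:
            json.dump(meta, fh, indent=1)


def aggregate_within_year(series: PopulationTimeSeries) -> PopulationTimeSeries:
    """Collapse multiple surveys within a calendar year to their mean.

    Populations surveyed more than once per year are reduced to one record
    per year (arithmetic mean of raw abundances); other series pass through
    unchanged.
    """
    years, inv = np.unique(series.years, return_inverse=True)
    if years.size == series.years.size:
        return series
    sums = np.zeros(years.size)
    counts = np.zeros(years.size)
    np.add.at(sums, inv, series.abundances)
    np.add.at(counts, inv, 1.0)
    return replace(series, years=years, abundances=sums / counts)


def filter_min_points(
    data: list[PopulationTimeSeries], k: int = 5
) -> list[PopulationTimeSeries]:
    """Drop series with fewer than ``k`` surveys.

    Short records rarely capture directional change; the pipeline default of
    5 points follows standard practice for this kind of compilation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = [s for s in data if s.n_obs >= k]
    logger.info(
        "filter_min_points(k=%d): kept %d of %d series (%d removed)",
        k, len(kept), len(data), len(data) - len(kept),
    )
    return kept


def scale_series(series: PopulationTimeSeries, method: str = "minmax01") -> ScaledSeries:
    """Rescale one series' abundances to a common magnitude.

    minmax01: (v - min) / (max - min), the within-population [0, 1] scaling
    applied before trend estimation.  zscore: (v - mean) / sd with the sample
    (n-1) standard deviation.  Constant series are retained and flagged
    (mapped to all-0.5 resp. all-0) rather than dropped, so that downstream
    fits return a zero trend with zero variance instead of failing.
    """
    a = series.abundances
    if method == "minmax01":
        lo, hi = a.min(), a.max()
        if hi - lo <= 0:
            return ScaledSeries(series.series_id, series.years,
                                np.full(a.shape, 0.5), method, True)
        return ScaledSeries(series.series_id, series.years, (a - lo) / (hi - lo), method)
    if method == "zscore":
        sd = a.std(ddof=1) if a.size > 1 else 0.0
        if sd <= 0:
            return ScaledSeries(series.series_id, series.years,
                                np.zeros(a.shape), method, True)
        return ScaledSeries(series.series_id, series.years, (a - a.mean()) / sd, method)
    raise ValueError(f"unknown scaling method: {method!r}")


def is_count_like(unit: str) -> bool:
    """True when an abundance-metric label denotes actual counts of
    individuals (as opposed to a derived index)."""
    u = unit.strip().lower()
    if u in COUNT_LIKE_UNITS:
        return True
    return "index" not in u and ("individual" in u or "count" in u or
                                 "pair" in u or "nest" in u or "estimate" in u)
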