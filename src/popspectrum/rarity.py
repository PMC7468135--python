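"""Species rarity metrics: geographic range, mean population size, habitat
specificity.

Rarity follows a simplified 'seven forms of rarity' view: a species is rare
when it has a small geographic range, a small population size, or narrow
habitat specificity.  Geographic range is the area (km^2) of the convex
hull of occurrence records after coordinate cleaning and quantile trimming;
mean population size is the mean raw abundance of a monitored population
(count-like survey units only); habitat specificity is the number of
distinct habitat categories a species occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .datasets import PopulationTimeSeries, is_count_like

__all__ = [
    "OccurrencePoint",
    "RarityMetrics",
    "CleaningConfig",
    "DegenerateRangeError",
    "clean_occurrences",
    "quantile_trim",
    "hull_area_km2",
    "mean_population_size",
    "habitat_specificity",
    "geographic_range_km2",
]

EARTH_RADIUS_KM = 6371.0
#: GBIF secretariat, Copenhagen
GBIF_HQ = (55.6761, 12.5683)

#: small default capital-city gazetteer (decimal degrees); callers supply a
#: fuller list for production cleaning
DEFAULT_CAPITALS = (
    ("London", 51.5074, -0.1278),
    ("Paris", 48.8566, 2.3522),
    ("Berlin", 52.5200, 13.4050),
    ("Madrid", 40.4168, -3.7038),
    ("Rome", 41.9028, 12.4964),
    ("Copenhagen", 55.6761, 12.5683),
    ("Stockholm", 59.3293, 18.0686),
    ("Oslo", 59.9139, 10.7522),
    ("Helsinki", 60.1699, 24.9384),
    ("Dublin", 53.3498, -6.2603),
    ("Washington", 38.9072, -77.0369),
    ("Ottawa", 45.4215, -75.6972),
    ("Mexico City", 19.4326, -99.1332),
    ("Brasilia", -15.8267, -47.9218),
    ("Buenos Aires", -34.6037, -58.3816),
    ("Pretoria", -25.7479, 28.2293),
    ("Nairobi", -1.2921, 36.8219),
    ("Cairo", 30.0444, 31.2357),
    ("Moscow", 55.7558, 37.6173),
    ("Beijing", 39.9042, 116.4074),
    ("Tokyo", 35.6762, 139.6503),
    ("New Delhi", 28.6139, 77.2090),
    ("Canberra", -35.2809, 149.1300),
    ("Wellington", -41.2866, 174.7756),
)


class DegenerateRangeError(ValueError):
    """Too few or collinear points: the hull area is undefined."""


@dataclass
class OccurrencePoint:
    """One occurrence record with the cleaning-rule labels applied to it."""

    species: str
    latitude: float
    longitude: float
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if not (-90 <= self.latitude <= 90) or not (-180 <= self.longitude <= 180):
            raise ValueError(
                f"coordinates out of range: ({self.latitude}, {self.longitude})"
            )


@dataclass
class RarityMetrics:
    """The three rarity metrics for one species (None where undefined)."""

    species: str
    range_km2: float | None = None
    mean_pop_size: float | None = None
    habitat_specificity: int | None = None


@dataclass
class CleaningConfig:
    """Occurrence-cleaning rules and radii (decimal degrees).

    Radii are interpreted as great-circle central angles by default;
    ``box_match=True`` switches to simple per-coordinate box matching.
    """

    gbif_hq: tuple = GBIF_HQ
    hq_radius_deg: float = 1.0
    institutions: tuple = ()
    institution_radius_deg: float = 0.0001
    capitals: tuple = tuple((lat, lon) for _, lat, lon in DEFAULT_CAPITALS)
    capital_radius_deg: float = 0.1
    box_match: bool = False


def _central_angle_deg(lat1, lon1, lat2, lon2) -> float:
    """Great-circle central angle between two points, in degrees."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (np.sin((p2 - p1) / 2) ** 2
         + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2)
    return float(np.degrees(2 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))))


def _near(pt: OccurrencePoint, target, radius_deg, box_match) -> bool:
    tlat, tlon = target
    if box_match:
        return (abs(pt.latitude - tlat) <= radius_deg
                and abs(pt.longitude - tlon) <= radius_deg)
    return _central_angle_deg(pt.latitude, pt.longitude, tlat, tlon) <= radius_deg


def _no_decimals(v: float) -> bool:
    return v == float(int(v))


def clean_occurrences(points, config: CleaningConfig | None = None):
    """Flag and remove suspect occurrence records.

    Removal rules (each removal is labelled with its rule):
      * ``no-decimal``          integer latitude or longitude;
      * ``lat-eq-lon``          latitude equal to longitude;
      * ``hq-radius``           within 1 degree of the GBIF headquarters;
      * ``institution-radius``  within 0.0001 degrees of a listed institution;
      * ``capital-radius``      within 0.1 degrees of a listed capital city.

    Returns ``(kept, removed)``; idempotent on the kept list.  An empty kept
    list is allowed.
    """
    config = config or CleaningConfig()
    kept, removed = [], []
    for pt in points:
        flags = set()
        if _no_decimals(pt.latitude) or _no_decimals(pt.longitude):
            flags.add("no-decimal")
        if pt.latitude == pt.longitude:
            flags.add("lat-eq-lon")
        if _near(pt, config.gbif_hq, config.hq_radius_deg, config.box_match):
            flags.add("hq-radius")
        for inst in config.institutions:
            if _near(pt, inst, config.institution_radius_deg, config.box_match):
                flags.add("institution-radius")
                break
        for cap in config.capitals:
            if _near(pt, cap, config.capital_radius_deg, config.box_match):
                flags.add("capital-radius")
                break
        pt.flags |= flags
        (removed if flags else kept).append(pt)
    return kept, removed


def quantile_trim(points, lo: float = 0.02, hi: float = 0.98):
    """Keep points whose latitude AND longitude both lie within the
    [lo, hi] empirical quantile interval of their coordinate (linear
    interpolation, boundary inclusive).  Trims outliers such as records from
    captive populations far outside the wild range.
    """
    pts = list(points)
    if len(pts) < 5:
        raise ValueError(f"need >= 5 points to quantile-trim, have {len(pts)}")
    lats = np.array([p.latitude for p in pts])
    lons = np.array([p.longitude for p in pts])
    la_lo, la_hi = np.quantile(lats, [lo, hi])
    lo_lo, lo_hi = np.quantile(lons, [lo, hi])
    return [p for p, la, ln in zip(pts, lats, lons)
            if la_lo <= la <= la_hi and lo_lo <= ln <= lo_hi]


def hull_area_km2(points, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Area (km^2) of the convex hull of occurrence points on a sphere.

    The hull is taken in (longitude, latitude) coordinates; its area is
    evaluated with the spherical polygon formula of Chamberlain & Duquette
    (exact in the small-polygon limit, sub-0.1% for ranges up to continental
    scale).  Hulls spanning the antimeridian are not supported and raise.
    """
    pts = list(points)
    lonlat = np.array([(p.longitude, p.latitude) for p in pts])
    if len(pts) >= 2 and np.ptp(lonlat[:, 0]) > 180:
        raise ValueError("hull spans the antimeridian; unsupported")
    if len(pts) < 3:
        raise DegenerateRangeError(f"need >= 3 points, have {len(pts)}")
    try:
        hull = ConvexHull(lonlat)
    except QhullError as err:
        raise DegenerateRangeError(f"degenerate (collinear?) points: {err}") from None
    verts = lonlat[hull.vertices]  # counter-clockwise
    lam = np.radians(verts[:, 0])
    phi = np.radians(verts[:, 1])
    lam2 = np.roll(lam, -1)
    phi2 = np.roll(phi, -1)
    area = -0.5 * radius_km**2 * np.sum((lam2 - lam) * (2 + np.sin(phi) + np.sin(phi2)))
    return float(abs(area))


def geographic_range_km2(points, config: CleaningConfig | None = None,
                         lo: float = 0.02, hi: float = 0.98,
                         radius_km: float = EARTH_RADIUS_KM):
    """Full range pipeline: clean, quantile-trim, hull, geodesic area.

    Returns ``(area_km2, n_points_used)``; raises DegenerateRangeError when
    fewer than three non-collinear points survive.
    """
    kept, _ = clean_occurrences(points, config)
    if len(kept) < 5:
        raise DegenerateRangeError(
            f"only {len(kept)} points survive cleaning; need >= 5"
        )
    trimmed = quantile_trim(kept, lo=lo, hi=hi)
    return hull_area_km2(trimmed, radius_km=radius_km), len(trimmed)


def mean_population_size(series: PopulationTimeSeries) -> float | None:
    """Mean raw abundance over the monitoring period, defined only for
    count-like survey units (population indices are excluded)."""
    if not is_count_like(series.unit):
        return None
    return float(np.mean(series.abundances))


def habitat_specificity(habitats) -> int | None:
    """Number of distinct habitat categories; None when no data."""
    cats = [h for h in habitats if str(h).strip()]
    if not cats:
        return None
    return len(set(cats))
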