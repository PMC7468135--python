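"""Synthetic datasets with the statistical structure the analysis assumes.

The generator provides ground truth for every stage's recovery tests: series
simulated from the very random-walk-with-observation-error model that stage
1 fits, species/taxa/realm/biome labels with known fixed and random effects
for stage 2, birth-death trees with tunable phylogenetic signal, and
occurrence point clouds with injected dirty records for the cleaning rules.

Defaults emulate the structure of a Living-Planet-style compilation: series
lengths follow a shifted Poisson with mean 23.3 annual points (minimum 5),
surveys fall within 1970-2014, and the six vertebrate classes and three
realms appear with configurable frequencies.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .datasets import PopulationTimeSeries, REALMS, TAXON_CLASSES
from .phylogeny import PhyloCorrelation
from .rarity import OccurrencePoint

__all__ = [
    "SyntheticTruth",
    "SimulationConfig",
    "simulate_series",
    "simulate_dataset",
    "simulate_tree",
    "simulate_tree_trends",
    "simulate_occurrences",
]

#: mean number of annual survey points per series in the emulated database
DEFAULT_MEAN_POINTS = 23.3
MIN_POINTS = 5
YEAR_RANGE = (1970, 2014)

DEFAULT_CLASS_EFFECTS = {
    "Actinopterygii": -0.001,
    "Elasmobranchii": -0.01,
    "Amphibia": -0.01,
    "Aves": 0.004,
    "Mammalia": 0.01,
    "Reptilia": 0.02,
}

BIOMES = (
    "temperate broadleaf forest",
    "tropical forest",
    "montane grasslands",
    "mediterranean forests",
    "temperate wetlands",
    "polar freshwaters",
    "tropical coral",
    "boreal forests",
)

IUCN_CATEGORIES = ("LC", "NT", "VU", "EN", "CR")
THREAT_TYPES = (
    "habitat change", "exploitation", "invasive species",
    "pollution", "climate change", "disease",
)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic dataset."""

    n_series: int = 2000
    n_species: int = 400
    mean_points: float = DEFAULT_MEAN_POINTS
    min_points: int = MIN_POINTS
    sigma: float = 0.03       # process-noise sd on the [0, 1] scale
    tau: float = 0.02         # observation-error sd
    class_effects: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS))
    species_intercept_sd: float = 0.01
    realm_probs: tuple = (0.25, 0.25, 0.50)  # freshwater, marine, terrestrial
    survey_gap_prob: float = 0.0             # chance a scheduled year is missed
    raw_counts: bool = False                 # back-transform to positive counts

    def __post_init__(self):
        if self.n_species > self.n_series:
            raise ValueError("config error: more species than series "
                             "(one series needs at least one species)")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass
class SyntheticTruth:
    """Generating parameters for every simulated series and species."""

    per_series: pd.DataFrame
    species_intercepts: dict[str, float]
    class_effects: dict[str, float]
    config: SimulationConfig
    seed: int | None
    phylo_signal: float | None = None


def simulate_series(mu, sigma2, tau2, years, seed=None,
                    start=0.5, raw_counts=False, series_id="sim",
                    **meta) -> PopulationTimeSeries:
    """One series from the random-walk-with-drift observation model.

    The latent state follows X_t = X_{t-1} + mu + eps_t with
    eps ~ N(0, sigma2) at annual resolution; observed values add iid
    N(0, tau2) error and are recorded only at the requested ``years``.
    ``raw_counts=True`` maps the latent scale through exp() onto a positive
    count-like scale (for I/O and population-size fixtures).
    """
    if sigma2 < 0 or tau2 < 0:
        raise ValueError("variances must be non-negative")
    years = np.asarray(years, dtype=int)
    if years.size < 2:
        raise ValueError("need >= 2 survey years")
    rng = np.random.default_rng(seed)
    span = years[-1] - years[0]
    steps = rng.normal(mu, np.sqrt(sigma2), span)
    latent_path = start + np.concatenate([[0.0], np.cumsum(steps)])
    obs = latent_path[years - years[0]] + rng.normal(0.0, np.sqrt(tau2), years.size)
    if raw_counts:
        obs = np.round(1000.0 * np.exp(obs)).clip(min=0)
    else:
        obs = obs - obs.min() if obs.min() < 0 else obs
    return PopulationTimeSeries(series_id=series_id, years=years,
                               abundances=obs, **meta)


def _draw_years(rng, mean_points, min_points, gap_prob):
    n_target = min_points + rng.poisson(max(mean_points - min_points, 0.0))
    n_target = int(min(n_target, YEAR_RANGE[1] - YEAR_RANGE[0] + 1))
    start = int(rng.integers(YEAR_RANGE[0], YEAR_RANGE[1] - n_target + 2))
    years = np.arange(start, start + n_target)
    if gap_prob > 0 and n_target > min_points:
        keep = rng.random(n_target) >= gap_prob
        keep[0] = keep[-1] = True
        if keep.sum() >= min_points:
            years = years[keep]
    return years


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None):
    """A full synthetic compilation plus its ground truth.

    Returns ``(list of PopulationTimeSeries, SyntheticTruth)``.  Per-series
    drift is class effect + species intercept; series lengths follow the
    configured shifted Poisson; labels are drawn with the configured
    frequencies.  Byte-identical output for a fixed seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    classes = list(config.class_effects)
    # species are nested within classes
    sp_class = rng.choice(len(classes), size=config.n_species)
    sp_names = [f"Genus species{i:04d}" for i in range(config.n_species)]
    sp_b = rng.normal(0.0, config.species_intercept_sd, config.n_species)
    series = []
    truth_rows = []
    for i in range(config.n_series):
        sp = int(i % config.n_species) if i < config.n_species \
            else int(rng.integers(config.n_species))
        cls = classes[sp_class[sp]]
        mu_i = config.class_effects[cls] + sp_b[sp]
        years = _draw_years(rng, config.mean_points, config.min_points,
                            config.survey_gap_prob)
        realm = REALMS[rng.choice(3, p=config.realm_probs)]
        biome = BIOMES[rng.integers(len(BIOMES))]
        meta = dict(
            species=sp_names[sp], taxon_class=cls, realm=realm, biome=biome,
            latitude=float(rng.uniform(-60, 70)),
            longitude=float(rng.uniform(-170, 170)),
            unit="index" if rng.random() < 0.3 else "number of individuals",
            iucn_category=IUCN_CATEGORIES[rng.integers(len(IUCN_CATEGORIES))],
            threats=frozenset(
                rng.choice(THREAT_TYPES,
                           size=rng.integers(1, 4), replace=False).tolist()
            ),
        )
        s = simulate_series(
            mu_i, config.sigma**2, config.tau**2, years,
            seed=rng.integers(2**31), raw_counts=config.raw_counts,
            series_id=f"S{i:05d}", **meta,
        )
        series.append(s)
        truth_rows.append(dict(
            series_id=s.series_id, mu=mu_i, sigma2=config.sigma**2,
            tau2=config.tau**2, n_points=s.n_obs, start_year=int(s.years[0]),
            species=meta["species"], taxon_class=cls, realm=realm, biome=biome,
            iucn_category=meta["iucn_category"], unit=meta["unit"],
        ))
    truth = SyntheticTruth(
        per_series=pd.DataFrame(truth_rows),
        species_intercepts=dict(zip(sp_names, sp_b)),
        class_effects=dict(config.class_effects),
        config=config, seed=seed,
    )
    return series, truth


def simulate_tree(n_tips: int, seed: int | None = None,
                  birth_rate: float = 1.0, death_rate: float = 0.2,
                  taxon_prefix: str = "Genus species") -> dendropy.Tree:
    """A birth-death tree with ``n_tips`` extant tips (binomial-style labels)."""
    from dendropy.simulate import treesim

    names = [f"{taxon_prefix}{i:04d}" for i in range(n_tips)]
    taxa = dendropy.TaxonNamespace(names)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_tips, taxon_namespace=taxa,
        rng=_pyrandom.Random(None if seed is None else int(seed)),
    )
    return tree


def simulate_tree_trends(corr: PhyloCorrelation, phylo_signal: float,
                         var_total: float, seed: int | None = None) -> pd.Series:
    """Species trait values with a controlled share of tree-structured
    variance: sqrt(signal*var_total) * BM-draw + sqrt((1-signal)*var_total)
    * iid normal."""
    if not 0 <= phylo_signal <= 1:
        raise ValueError("phylo_signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    q = len(corr.species)
    if var_total == 0:
        return pd.Series(np.zeros(q), index=corr.species)
    L = np.linalg.cholesky(corr.matrix + 1e-10 * np.eye(q))
    bm = L @ rng.standard_normal(q)
    iid = rng.standard_normal(q)
    vals = (np.sqrt(phylo_signal * var_total) * bm
            + np.sqrt((1 - phylo_signal) * var_total) * iid)
    return pd.Series(vals, index=corr.species)


def simulate_occurrences(center, spread, n, dirty_fraction=0.0,
                         seed: int | None = None, species="Genus species0000"):
    """A Gaussian occurrence cloud with injected dirty records.

    Dirty records (integer coordinates, lat == lon, or points at the GBIF
    headquarters) are injected at the stated fraction; returns
    ``(points, truth_flags)`` where truth_flags[i] names the injected defect
    ('' for clean points).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lat0, lon0 = center
    lats = np.clip(rng.normal(lat0, spread, n), -89.9, 89.9)
    lons = np.clip(rng.normal(lon0, spread, n), -179.9, 179.9)
    # keep clean points non-integer and off the lat==lon diagonal
    frac = lats - np.floor(lats)
    lats = np.where((frac < 1e-6) | (frac > 1 - 1e-6), lats + 0.005, lats)
    frac = lons - np.floor(lons)
    lons = np.where((frac < 1e-6) | (frac > 1 - 1e-6), lons + 0.005, lons)
    lons = np.where(np.abs(lats - lons) < 1e-9, lons + 0.013, lons)
    flags = [""] * n
    n_dirty = int(round(dirty_fraction * n))
    kinds = ("no-decimal", "lat-eq-lon", "hq-radius")
    for i in range(n_dirty):
        kind = kinds[i % len(kinds)]
        if kind == "no-decimal":
            lats[i] = float(int(lats[i]))
        elif kind == "lat-eq-lon":
            lons[i] = lats[i]
        else:
            lats[i], lons[i] = 55.6761 + rng.uniform(-0.5, 0.5), 12.5683
        flags[i] = kind
    pts = [OccurrencePoint(species, float(la), float(lo))
           for la, lo in zip(lats, lons)]
    return pts, flags
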