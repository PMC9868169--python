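"""Seeded synthetic landscapes: complete input bundles for the pipeline.

Generates everything the disturbance pipeline consumes — a clustered
categorical land-use mosaic, a population surface concentrated on
settlement classes, per-period sector statistics, and smooth emission
fields with optionally planted high-emission clusters (ground truth for
hot-spot recovery tests) — all bit-reproducible from one seed.

The default scenario mirrors a river-basin study at toy scale: a 100×100
grid of 1-km cells, seven periods labeled 1990–2018, arable-dominated
class proportions, urban population density an order of magnitude above
rural.  Land-use clustering comes from thresholding a Gaussian-smoothed
seeded noise field at the class-proportion quantiles, which makes realized
class shares match the requested proportions almost exactly while giving
tunable spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import DEFAULT_LEGEND, GridSpec, LAND_USE_CLASSES, LandUseGrid, ValueGrid
from .pollution import EmissionField
from .resources import SECTORS, SectorStatistics

__all__ = ["ScenarioConfig", "generate_landuse", "generate_population",
           "generate_statistics", "generate_emission_field", "generate_bundle"]

#: Arable-dominated default class proportions (fractions of the basin area).
DEFAULT_PROPORTIONS: dict[str, float] = {
    "arable": 0.50,
    "forest": 0.12,
    "grassland": 0.08,
    "artificial_water": 0.02,
    "natural_water": 0.04,
    "urban": 0.08,
    "rural": 0.10,
    "industrial": 0.03,
    "unused": 0.03,
}

DEFAULT_PERIODS = ("1990", "1995", "2000", "2005", "2010", "2015", "2018")


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic scenario; the seed determines everything."""

    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100, 1000.0, 0.0, 100_000.0, "synthetic-meters"))
    class_proportions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    clustering_strength: float = 2.0
    periods: Sequence[str] = DEFAULT_PERIODS
    #: multiplicative growth of each sector's total per period step
    trend: Mapping[str, float] = field(default_factory=lambda: {s: 1.05 for s in SECTORS})
    #: base totals per sector for the first period (quantity units)
    base_totals: Mapping[str, float] = field(
        default_factory=lambda: {
            "agriculture": 5.0e5,
            "industry": 3.0e5,
            "urban_public": 1.0e5,
            "forestry_husbandry": 4.0e4,
            "transport": 8.0e4,
        }
    )
    urban_density_mean: float = 2500.0  # persons/km²
    rural_density_mean: float = 400.0
    #: planted clusters: list of ((row, col) center, radius cells, effect in background SDs)
    cluster_plants: Sequence[tuple[tuple[int, int], int, float]] = ()

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if self.clustering_strength < 0:
            raise ValueError("clustering_strength must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def generate_landuse(config: ScenarioConfig) -> LandUseGrid:
    """Clustered categorical mosaic matching the configured class shares.

    A seeded uniform noise field is Gaussian-smoothed with
    sigma = ``clustering_strength`` (0 → i.i.d. cells) and thresholded at
    the empirical quantiles given by the cumulative class proportions, so
    realized shares track the requested proportions closely.
    """
    rng = config.rng(1)
    noise = rng.random(config.grid.shape)
    if config.clustering_strength > 0:
        noise = ndimage.gaussian_filter(noise, sigma=config.clustering_strength, mode="reflect")
    classes = [c for c in LAND_USE_CLASSES if config.class_proportions.get(c, 0.0) > 0]
    props = np.array([config.class_proportions[c] for c in classes])
    cum = np.cumsum(props)[:-1]
    thresholds = np.quantile(noise, cum) if len(cum) else np.array([])
    idx = np.searchsorted(thresholds, noise, side="right")
    code_of = {name: code for code, name in DEFAULT_LEGEND.items()}
    codes = np.zeros(config.grid.shape, dtype=np.int64)
    for i, cls in enumerate(classes):
        codes[idx == i] = code_of[cls]
    return LandUseGrid(config.grid, codes, DEFAULT_LEGEND)


def generate_population(land_use: LandUseGrid, config: ScenarioConfig) -> ValueGrid:
    """Population density (persons/km²): lognormal on urban ≫ rural, 0 elsewhere."""
    rng = config.rng(2)
    out = np.zeros(land_use.spec.shape)
    for cls, mean in (("urban", config.urban_density_mean), ("rural", config.rural_density_mean)):
        sel = land_use.class_mask(cls)
        n = int(sel.sum())
        if n and mean > 0:
            sigma = 0.4
            mu = np.log(mean) - sigma**2 / 2.0
            out[sel] = rng.lognormal(mu, sigma, size=n)
    out[~land_use.mask] = np.nan
    return ValueGrid(land_use.spec, out, units="persons/km2")


def generate_statistics(config: ScenarioConfig, jitter: float = 0.0) -> SectorStatistics:
    """Per-period sector totals following the configured multiplicative trend.

    ``total(sector, period p) = base · trend^p`` with optional relative
    lognormal jitter (seeded).
    """
    rng = config.rng(3)
    rows = []
    for p, period in enumerate(config.periods):
        for sector, base in config.base_totals.items():
            growth = config.trend.get(sector, 1.0) ** p
            q = base * growth
            if jitter > 0:
                q *= rng.lognormal(0.0, jitter)
            rows.append(
                {"period_label": period, "region_label": "basin", "sector": sector,
                 "quantity": q, "units": "quantity/yr"}
            )
    return SectorStatistics(pd.DataFrame(rows))


def generate_emission_field(
    config: ScenarioConfig,
    pollutant: str = "CO2",
    period_index: int = 0,
) -> tuple[EmissionField, np.ndarray]:
    """Coarse smooth emission field (4× cell size) with planted clusters.

    Returns the field plus the ground-truth cluster mask at the *target*
    resolution.  The background is a positive Gaussian-smoothed surface;
    each planted cluster adds ``effect × background SD`` within its radius.
    """
    rng = config.rng(10 + period_index * 7 + (hash(pollutant) % 7))
    spec = config.grid
    factor = 4
    nr = max(2, spec.n_rows // factor)
    nc = max(2, spec.n_cols // factor)
    coarse = ndimage.gaussian_filter(rng.random((nr, nc)), sigma=1.5, mode="reflect")
    coarse = coarse - coarse.min()
    sd = coarse.std()
    base_level = coarse.mean() + 1e-9
    coarse = coarse + 0.2 * base_level  # keep the background strictly positive

    mask = np.zeros(spec.shape, dtype=bool)
    rr, cc = np.mgrid[0:nr, 0:nc]
    rr_t, cc_t = np.mgrid[0:spec.n_rows, 0:spec.n_cols]
    for (ci, cj), radius, effect in config.cluster_plants:
        in_coarse = (rr - ci / factor) ** 2 + (cc - cj / factor) ** 2 <= (radius / factor) ** 2
        coarse[in_coarse] += effect * sd
        mask |= (rr_t - ci) ** 2 + (cc_t - cj) ** 2 <= radius**2

    cell = spec.cell_size * factor
    xs = spec.origin_x + (np.arange(nc) + 0.5) * cell
    ys = spec.origin_y - (np.arange(nr) + 0.5) * cell
    xm = np.broadcast_to(xs, (nr, nc))
    ym = np.broadcast_to(ys[:, None], (nr, nc))
    samples = np.column_stack([xm.ravel(), ym.ravel(), coarse.ravel()])
    return EmissionField(samples, pollutant), mask


def generate_bundle(config: ScenarioConfig) -> dict:
    """Generate the full input bundle for one scenario.

    Returns a dict with ``land_use``, ``population``, ``statistics`` (water
    and energy), and per-period emission fields with their cluster masks.
    """
    land_use = generate_landuse(config)
    population = generate_population(land_use, config)
    water = generate_statistics(config)
    energy = generate_statistics(replace(config, seed=config.seed + 1))
    emissions = {}
    for p, period in enumerate(config.periods):
        emissions[period] = {
            pol: generate_emission_field(config, pol, p) for pol in ("CO2", "N2O")
        }
    return {
        "config": config,
        "land_use": land_use,
        "population": population,
        "water_stats": water,
        "energy_stats": energy,
        "emissions": emissions,
    }
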