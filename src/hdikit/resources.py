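"""Resource-consumption surfaces (RCI components).

Builds per-period water- and energy-consumption density surfaces
(quantity per km² per year) by spreading sectoral statistical totals over
the land-use classes that generate the demand, and adding residential
consumption computed from population density times per-capita rates.
Energy carriers are first converted to standard coal equivalent (tce).

Allocation is conservative: the integral of every surface (cell value ×
cell area) equals the sum of the allocated totals to ~1e-9 relative.
Standardization of the surfaces to 0–10 scores and the RCI sum live in
:mod:`hdikit.scoring`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, AllocationError, ConversionError, CoverageError
from .grid import LandUseGrid, ValueGrid

__all__ = [
    "SECTORS",
    "SectorStatistics",
    "FuelConversionTable",
    "PerCapitaRates",
    "DEFAULT_SECTOR_CLASS_MAP",
    "to_standard_coal",
    "temporal_average",
    "allocate_per_area",
    "residential_consumption",
    "transport_energy_spread",
    "build_consumption_surface",
]

logger = logging.getLogger(__name__)

SECTORS = (
    "agriculture",
    "industry",
    "urban_residents",
    "rural_residents",
    "forestry_husbandry",
    "urban_public",
    "transport",
    "other",
)

#: Default mapping from sectors to the land-use classes that receive their
#: totals.  Resident sectors are handled through per-capita rates instead.
DEFAULT_SECTOR_CLASS_MAP: dict[str, frozenset[str]] = {
    "agriculture": frozenset({"arable"}),
    "industry": frozenset({"industrial"}),
    "urban_public": frozenset({"urban"}),
    "forestry_husbandry": frozenset({"forest", "grassland"}),
    "transport": frozenset({"urban", "rural", "industrial"}),
}


@dataclass
class SectorStatistics:
    """Sectoral consumption/emission totals by period and region.

    Wraps a DataFrame with columns ``period_label, region_label, sector,
    quantity, units``; (period, region, sector) must be unique and
    quantities non-negative.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = {"period_label", "region_label", "sector", "quantity", "units"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"SectorStatistics missing columns: {sorted(missing)}")
        if (df["quantity"] < 0).any():
            raise ValueError("sector quantities must be non-negative")
        bad = set(df["sector"]) - set(SECTORS)
        if bad:
            raise ValueError(f"unknown sectors: {sorted(bad)}")
        if df.duplicated(["period_label", "region_label", "sector"]).any():
            raise ValueError("(period, region, sector) records must be unique")
        self.records = df.reset_index(drop=True)

    def total(self, period: str, sector: str) -> float:
        sel = (self.records["period_label"] == period) & (self.records["sector"] == sector)
        return float(self.records.loc[sel, "quantity"].sum())

    def sectors_present(self, period: str) -> set[str]:
        return set(self.records.loc[self.records["period_label"] == period, "sector"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "SectorStatistics":
        return cls(pd.read_csv(path, dtype={"period_label": str, "region_label": str}))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class FuelConversionTable:
    """Energy-carrier → standard-coal-equivalent factors (tce per native unit)."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        self.factors = dict(self.factors)
        for carrier, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"conversion factor for {carrier!r} must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FuelConversionTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df["carrier"], df["factor"].astype(float))))


@dataclass(frozen=True)
class PerCapitaRates:
    """Per-person yearly consumption rates for urban and rural residents."""

    urban_rate: float
    rural_rate: float

    def __post_init__(self) -> None:
        if self.urban_rate < 0 or self.rural_rate < 0:
            raise ValueError("per-capita rates must be non-negative")


def to_standard_coal(quantities: Mapping[str, float], table: FuelConversionTable) -> float:
    """Convert carrier amounts to a total in standard coal equivalent (tce)."""
    total = 0.0
    for carrier, amount in quantities.items():
        if carrier not in table.factors:
            raise ConversionError(f"no standard-coal factor for carrier {carrier!r}")
        total += amount * table.factors[carrier]
    return total


def temporal_average(series: Iterable[tuple[int, float]], window: Iterable[int]) -> float:
    """Arithmetic mean of a yearly series over exactly the window years.

    Supports the 5-year blocks and the closing 3-year block (2016–2018)
    alike — the window is just an explicit set of years.  Missing years
    raise :class:`~hdikit.errors.CoverageError` listing them.
    """
    lookup = dict(series)
    window = sorted(set(window))
    if not window:
        raise CoverageError("empty averaging window")
    missing = [y for y in window if y not in lookup]
    if missing:
        raise CoverageError(f"series missing years {missing} required by the averaging window")
    return float(np.mean([lookup[y] for y in window]))


def allocate_per_area(
    total: float,
    land_use: LandUseGrid,
    target_classes: Iterable[str],
    split: Mapping[str, float] | str = "proportional_area",
) -> ValueGrid:
    """Spread a total over target-class cells as a per-km² density surface.

    ``split="proportional_area"`` gives every target cell the same density
    (total / total target area).  An explicit ``{class: fraction}`` mapping
    divides the total between classes first (fractions must sum to 1), with
    uniform density within each class.  Non-target cells get 0; nodata cells
    stay nodata.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    target_classes = set(target_classes)
    area = land_use.spec.cell_area_km2
    counts = land_use.class_counts()
    present = {c for c in target_classes if counts.get(c, 0) > 0}
    if not present:
        raise AllocationError(f"no cells of target classes {sorted(target_classes)} in land-use grid")
    if split == "proportional_area":
        total_area = sum(counts[c] for c in present) * area
        fractions = {c: counts[c] * area / total_area for c in present}
    else:
        fractions = dict(split)
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ValueError("explicit split fractions must sum to 1")
        dropped = {c for c in fractions if c not in present and fractions[c] > 0}
        if dropped:
            raise AllocationError(f"split assigns mass to absent classes: {sorted(dropped)}")
    out = np.zeros(land_use.spec.shape)
    for cls in present:
        density = total * fractions.get(cls, 0.0) / (counts[cls] * area)
        out[land_use.class_mask(cls)] = density
    out[~land_use.mask] = np.nan
    return ValueGrid(land_use.spec, out, units="quantity/km2")


def residential_consumption(
    population: ValueGrid,
    land_use: LandUseGrid,
    rates: PerCapitaRates,
) -> ValueGrid:
    """Residential consumption density from population density × per-capita rate.

    Urban cells get ``density * urban_rate``, rural cells
    ``density * rural_rate`` (units: quantity/km²/yr for density in
    persons/km²); every other class gets 0.
    """
    if population.spec != land_use.spec:
        raise AlignmentError("population and land-use grids are not aligned")
    pop = population.values
    if np.nanmin(pop) < 0 if np.isfinite(pop).any() else False:
        raise ValueError("population density must be non-negative")
    if (pop[np.isfinite(pop)] < 0).any():
        raise ValueError("population density must be non-negative")
    out = np.zeros(land_use.spec.shape)
    urban = land_use.class_mask("urban")
    rural = land_use.class_mask("rural")
    out[urban] = np.nan_to_num(pop[urban]) * rates.urban_rate
    out[rural] = np.nan_to_num(pop[rural]) * rates.rural_rate
    out[~land_use.mask] = np.nan
    return ValueGrid(land_use.spec, out, units="quantity/km2")


def transport_energy_spread(total: float, land_use: LandUseGrid) -> ValueGrid:
    """Transport energy is not confined to roads: spread it over the built
    classes (urban, rural, industrial) proportionally to their areas."""
    return allocate_per_area(total, land_use, {"urban", "rural", "industrial"}, "proportional_area")


def build_consumption_surface(
    stats: SectorStatistics,
    period: str,
    land_use: LandUseGrid,
    population: ValueGrid,
    rates: PerCapitaRates,
    sector_map: Mapping[str, Iterable[str]] | None = None,
    ignore_sectors: Iterable[str] = ("other",),
) -> ValueGrid:
    """Total consumption density surface for one period and one resource.

    Sums the per-area allocation of every mapped sector total plus the
    population-based residential component.  Resident sectors
    (``urban_residents``/``rural_residents``) are always served by the
    per-capita rates; their statistical totals, if present, are treated as
    bookkeeping and ignored with a log message.  Any other sector neither
    mapped nor listed in ``ignore_sectors`` raises ``ValueError`` — sectors
    are never silently dropped.
    """
    if sector_map is None:
        sector_map = DEFAULT_SECTOR_CLASS_MAP
    ignore = set(ignore_sectors) | {"urban_residents", "rural_residents"}
    out = np.zeros(land_use.spec.shape)
    for sector in sorted(stats.sectors_present(period)):
        if sector in sector_map:
            total = stats.total(period, sector)
            if total > 0:
                surf = allocate_per_area(total, land_use, sector_map[sector])
                out = out + np.nan_to_num(surf.values)
        elif sector in ignore:
            logger.info("sector %r ignored for period %s (handled elsewhere or configured off)", sector, period)
        else:
            raise ValueError(f"sector {sector!r} is neither mapped nor explicitly ignored")
    res = residential_consumption(population, land_use, rates)
    out = out + np.nan_to_num(res.values)
    out[~land_use.mask] = np.nan
    return ValueGrid(land_use.spec, out, units="quantity/km2")
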