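"""Resource-consumption surfaces: conversion, averaging, allocation, conservation."""

import numpy as np
import pandas as pd
import pytest

from hdikit.errors import AllocationError, ConversionError, CoverageError
from hdikit.grid import DEFAULT_LEGEND, GridSpec, LandUseGrid, ValueGrid
from hdikit.resources import (
    FuelConversionTable,
    PerCapitaRates,
    SectorStatistics,
    allocate_per_area,
    build_consumption_surface,
    residential_consumption,
    temporal_average,
    to_standard_coal,
    transport_energy_spread,
)


def surface_integral(grid):
    """Total quantity represented by a density surface (value x cell area)."""
    return np.nansum(grid.values) * grid.spec.cell_area_km2


class TestStandardCoal:
    def test_empty_mapping_is_zero(self):
        assert to_standard_coal({}, FuelConversionTable({"coal": 0.7})) == 0.0

    def test_single_carrier_linear(self):
        table = FuelConversionTable({"electricity": 0.1229})
        assert to_standard_coal({"electricity": 1000.0}, table) == pytest.approx(122.9)

    def test_additivity_over_carriers(self, rng):
        table = FuelConversionTable({"a": 0.7, "b": 1.4})
        qa, qb = rng.random(2) * 100
        combined = to_standard_coal({"a": qa, "b": qb}, table)
        separate = to_standard_coal({"a": qa}, table) + to_standard_coal({"b": qb}, table)
        assert combined == pytest.approx(separate, rel=1e-12)

    def test_unknown_carrier_raises(self):
        with pytest.raises(ConversionError, match="diesel"):
            to_standard_coal({"diesel": 1.0}, FuelConversionTable({"coal": 0.7}))


class TestTemporalAverage:
    def test_constant_series(self):
        series = [(y, 5.0) for y in range(2001, 2006)]
        assert temporal_average(series, range(2001, 2006)) == 5.0

    def test_three_year_window_mean(self):
        assert temporal_average([(2016, 1.0), (2017, 2.0), (2018, 3.0)], {2016, 2017, 2018}) == 2.0

    def test_matches_summation_oracle(self, rng):
        vals = rng.random(5) * 10
        series = list(zip(range(1991, 1996), vals))
        assert temporal_average(series, range(1991, 1996)) == pytest.approx(vals.sum() / 5.0)

    def test_missing_years_listed(self):
        with pytest.raises(CoverageError, match="1993"):
            temporal_average([(1991, 1.0), (1992, 2.0)], {1991, 1992, 1993})


class TestAllocatePerArea:
    def test_uniform_split_over_four_cells(self):
        spec = GridSpec(2, 2, 1000.0, 0.0, 2000.0)
        lu = LandUseGrid(spec, np.ones((2, 2), dtype=int), DEFAULT_LEGEND)  # all arable
        out = allocate_per_area(100.0, lu, {"arable"})
        assert (out.values == 25.0).all()  # 100 over 4 km²

    def test_zero_total_gives_zero_grid(self, random_landuse):
        out = allocate_per_area(0.0, random_landuse, {"arable"})
        assert np.nansum(out.values) == 0.0

    def test_proportional_split_conserves_and_equalizes_density(self, random_landuse):
        out = allocate_per_area(1234.5, random_landuse, {"forest", "grassland"})
        assert surface_integral(out) == pytest.approx(1234.5, rel=1e-9)
        for cls in ("forest", "grassland"):
            vals = out.values[random_landuse.class_mask(cls)]
            assert np.allclose(vals, vals[0])
        # proportional split: identical densities across both classes
        f = out.values[random_landuse.class_mask("forest")][0]
        g = out.values[random_landuse.class_mask("grassland")][0]
        assert f == pytest.approx(g)

    def test_explicit_fractions_conserve(self, random_landuse):
        out = allocate_per_area(100.0, random_landuse, {"forest", "grassland"},
                                split={"forest": 0.8, "grassland": 0.2})
        assert surface_integral(out) == pytest.approx(100.0, rel=1e-9)

    def test_no_target_cells_raises(self, spec):
        lu = LandUseGrid(spec, np.ones(spec.shape, dtype=int), DEFAULT_LEGEND)
        with pytest.raises(AllocationError):
            allocate_per_area(10.0, lu, {"urban"})


class TestResidential:
    def test_zero_population_zero_surface(self, random_landuse):
        pop = ValueGrid(random_landuse.spec, np.zeros(random_landuse.spec.shape))
        out = residential_consumption(pop, random_landuse, PerCapitaRates(2.0, 1.0))
        assert np.nansum(out.values) == 0.0

    def test_single_urban_cell(self):
        spec = GridSpec(2, 2, 1000.0, 0.0, 2000.0)
        codes = np.ones((2, 2), dtype=int)
        codes[0, 0] = 6  # urban
        lu = LandUseGrid(spec, codes, DEFAULT_LEGEND)
        pop = np.zeros((2, 2))
        pop[0, 0] = 1000.0
        out = residential_consumption(ValueGrid(spec, pop), lu, PerCapitaRates(2.0, 1.0))
        assert out.values[0, 0] == 2000.0
        assert np.nansum(out.values) == 2000.0

    def test_mixed_grid_matches_cellwise_oracle(self, random_landuse, rng):
        pop = ValueGrid(random_landuse.spec, rng.random(random_landuse.spec.shape) * 500)
        rates = PerCapitaRates(3.5, 1.25)
        out = residential_consumption(pop, random_landuse, rates)
        expected = np.zeros(random_landuse.spec.shape)
        urban = random_landuse.class_mask("urban")
        rural = random_landuse.class_mask("rural")
        expected[urban] = pop.values[urban] * 3.5
        expected[rural] = pop.values[rural] * 1.25
        np.testing.assert_allclose(out.values, expected)

    def test_negative_density_raises(self, random_landuse):
        pop = ValueGrid(random_landuse.spec, np.full(random_landuse.spec.shape, -1.0))
        with pytest.raises(ValueError):
            residential_consumption(pop, random_landuse, PerCapitaRates(1.0, 1.0))


class TestTransportSpread:
    def test_only_urban_gets_everything(self, spec):
        lu = LandUseGrid(spec, np.full(spec.shape, 6), DEFAULT_LEGEND)
        out = transport_energy_spread(500.0, lu)
        assert surface_integral(out) == pytest.approx(500.0, rel=1e-9)

    def test_equal_areas_equal_densities(self):
        spec = GridSpec(3, 3, 1000.0, 0.0, 3000.0)
        codes = np.array([[6, 6, 6], [7, 7, 7], [8, 8, 8]])
        out = transport_energy_spread(90.0, LandUseGrid(spec, codes, DEFAULT_LEGEND))
        assert np.allclose(out.values, 10.0)

    def test_arbitrary_mix_conserves(self, random_landuse):
        out = transport_energy_spread(777.0, random_landuse)
        assert surface_integral(out) == pytest.approx(777.0, rel=1e-9)


class TestBuildSurface:
    def _stats(self, totals, period="1990"):
        rows = [
            {"period_label": period, "region_label": "basin", "sector": s,
             "quantity": q, "units": "u"}
            for s, q in totals.items()
        ]
        return SectorStatistics(pd.DataFrame(rows))

    def test_all_zero_inputs_zero_surface(self, random_landuse):
        stats = self._stats({"agriculture": 0.0, "industry": 0.0})
        pop = ValueGrid(random_landuse.spec, np.zeros(random_landuse.spec.shape))
        out = build_consumption_surface(stats, "1990", random_landuse, pop, PerCapitaRates(1.0, 1.0))
        assert np.nansum(out.values) == 0.0

    def test_single_sector_reduces_to_allocation(self, random_landuse):
        stats = self._stats({"agriculture": 321.0})
        pop = ValueGrid(random_landuse.spec, np.zeros(random_landuse.spec.shape))
        out = build_consumption_surface(stats, "1990", random_landuse, pop, PerCapitaRates(1.0, 1.0))
        alone = allocate_per_area(321.0, random_landuse, {"arable"})
        np.testing.assert_allclose(
            np.nan_to_num(out.values), np.nan_to_num(alone.values), rtol=1e-12
        )

    def test_global_conservation_with_residents(self, random_landuse, rng):
        totals = {"agriculture": 500.0, "industry": 300.0, "urban_public": 120.0,
                  "forestry_husbandry": 80.0, "transport": 60.0}
        stats = self._stats(totals)
        pop_vals = rng.random(random_landuse.spec.shape) * 800
        pop = ValueGrid(random_landuse.spec, pop_vals)
        rates = PerCapitaRates(2.0, 0.5)
        out = build_consumption_surface(stats, "1990", random_landuse, pop, rates)
        area = random_landuse.spec.cell_area_km2
        urban = random_landuse.class_mask("urban")
        rural = random_landuse.class_mask("rural")
        residential = (pop_vals[urban].sum() * 2.0 + pop_vals[rural].sum() * 0.5) * area
        assert surface_integral(out) == pytest.approx(sum(totals.values()) + residential, rel=1e-9)

    def test_unmapped_sector_raises(self, random_landuse):
        stats = self._stats({"other": 5.0})
        pop = ValueGrid(random_landuse.spec, np.zeros(random_landuse.spec.shape))
        with pytest.raises(ValueError):
            build_consumption_surface(
                stats, "1990", random_landuse, pop, PerCapitaRates(1.0, 1.0), ignore_sectors=()
            )

    def test_monotone_in_sector_totals(self, random_landuse):
        pop = ValueGrid(random_landuse.spec, np.zeros(random_landuse.spec.shape))
        lo = build_consumption_surface(self._stats({"agriculture": 100.0}), "1990",
                                       random_landuse, pop, PerCapitaRates(0, 0))
        hi = build_consumption_surface(self._stats({"agriculture": 150.0}), "1990",
                                       random_landuse, pop, PerCapitaRates(0, 0))
        diff = np.nan_to_num(hi.values) - np.nan_to_num(lo.values)
        assert (diff >= 0).all() and diff.max() > 0


def test_sector_statistics_validation():
    base = {"period_label": "1990", "region_label": "r", "sector": "industry",
            "quantity": 1.0, "units": "u"}
    with pytest.raises(ValueError):
        SectorStatistics(pd.DataFrame([base, base]))  # duplicate key
    with pytest.raises(ValueError):
        SectorStatistics(pd.DataFrame([{**base, "quantity": -1.0}]))
    with pytest.raises(ValueError):
        SectorStatistics(pd.DataFrame([{**base, "sector": "mining"}]))
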