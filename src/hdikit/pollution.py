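"""Pollutant-emission surfaces (PEI components).

Three surfaces feed the pollution-emission index: CO2 and N2O fields
(typically coarse global inventory grids, downscaled to the working
resolution by ordinary kriging or inverse-distance weighting) and a
non-point source pollution surface confined to arable and rural land.

Non-point pollution follows the observation that diffuse pollution loads
concentrate in rural settlements (per-capita nitrogen-oxide emissions) and
in fertilized arable land (application rate times the fraction of
fertilizer not effectively used).  All other classes are exactly zero.

The diffuse-pollution pressure index is reduced to its land-cover
indicator (LCI): the emission surface min–max rescaled to [0, 1]; the
distance/runoff/slope indicators of the full index need terrain and soil
inputs and are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from .errors import AlignmentError, RangeError
from .grid import GridSpec, LandUseGrid, ValueGrid

__all__ = [
    "EmissionField",
    "NonPointParams",
    "interpolate_to_grid",
    "nonpoint_emission_surface",
    "land_cover_indicator",
    "build_pei_components",
]

logger = logging.getLogger(__name__)


@dataclass
class EmissionField:
    """Point samples of an emission inventory in projected meters.

    ``samples`` is an (n, 3) array of (x, y, value); values must be
    non-negative and coordinates finite.  Coarse grids are represented by
    their cell-center samples.
    """

    samples: np.ndarray
    pollutant: str = "CO2"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (x, y, value)")
        if not np.isfinite(self.samples[:, :2]).all():
            raise ValueError("sample coordinates must be finite")
        if (self.samples[:, 2] < 0).any():
            raise ValueError("emission values must be non-negative")

    @classmethod
    def from_grid(cls, grid: ValueGrid, pollutant: str = "CO2") -> "EmissionField":
        xm, ym = grid.spec.center_mesh()
        ok = grid.mask
        return cls(np.column_stack([xm[ok], ym[ok], grid.values[ok]]), pollutant)


@dataclass(frozen=True)
class NonPointParams:
    """Parameters of the non-point pollution surface.

    per_capita_rural_emission
        Nitrogen-oxide emission per rural person per year (mass/person/yr).
    fertilizer_effective_use_rate
        Fraction of applied fertilizer effectively used by crops, in (0, 1];
        the complement leaches as diffuse pollution.
    arable_application_rate
        Fertilizer application rate on arable land (mass/km²/yr).
    """

    per_capita_rural_emission: float
    fertilizer_effective_use_rate: float
    arable_application_rate: float

    def __post_init__(self) -> None:
        if self.per_capita_rural_emission <= 0 or self.arable_application_rate <= 0:
            raise ValueError("emission rates must be positive")
        if not 0.0 < self.fertilizer_effective_use_rate <= 1.0:
            raise ValueError("fertilizer effective use rate must be in (0, 1]")


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def _exp_variogram(h, sill, rng):
    return sill * (1.0 - np.exp(-h / np.maximum(rng, 1e-12)))


def _fit_exponential_variogram(xy: np.ndarray, v: np.ndarray, n_lags: int = 12):
    """Weighted-least-squares fit of a zero-nugget exponential variogram."""
    d = pdist(xy)
    g = 0.5 * pdist(v[:, None], metric="sqeuclidean")
    max_lag = d.max() / 2.0
    edges = np.linspace(0, max_lag, n_lags + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() >= 2:
            centers.append(d[sel].mean())
            gammas.append(g[sel].mean())
            counts.append(sel.sum())
    centers, gammas, counts = map(np.asarray, (centers, gammas, counts))
    if len(centers) < 2 or not (gammas > 0).any():
        raise np.linalg.LinAlgError("empirical semivariogram degenerate")
    p0 = (max(gammas.max(), 1e-12), max(centers.mean(), 1e-6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            _exp_variogram, centers, gammas, p0=p0,
            sigma=1.0 / np.sqrt(counts), bounds=([1e-12, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    return popt  # (sill, range)


def _idw(xy: np.ndarray, v: np.ndarray, targets: np.ndarray, power: float = 2.0) -> np.ndarray:
    tree = cKDTree(xy)
    d, idx = tree.query(targets, k=min(len(xy), 12))
    if d.ndim == 1:  # single neighbor: restore (n_targets, 1) shape
        d = d[:, None]
        idx = idx[:, None]
    exact = d[:, 0] < 1e-9
    w = 1.0 / np.maximum(d, 1e-9) ** power
    est = (w * v[idx]).sum(axis=1) / w.sum(axis=1)
    est[exact] = v[idx[exact, 0]]
    return est


def interpolate_to_grid(
    field: EmissionField,
    target: GridSpec,
    method: str = "ordinary_kriging",
) -> ValueGrid:
    """Interpolate emission samples onto the target grid.

    Ordinary kriging uses a zero-nugget exponential variogram fitted to the
    empirical semivariogram by weighted least squares, making it an exact
    interpolator at sample locations.  A singular kriging system falls back
    to inverse-distance weighting with a warning.  Negative estimates are
    clamped to zero (and logged): emissions are physically non-negative.
    """
    if method not in {"ordinary_kriging", "idw"}:
        raise ValueError(f"unknown interpolation method {method!r}")
    n = len(field.samples)
    if n == 0:
        raise ValueError("empty emission field")
    xy = field.samples[:, :2]
    v = field.samples[:, 2]
    xm, ym = target.center_mesh()
    targets = np.column_stack([xm.ravel(), ym.ravel()])

    if method == "ordinary_kriging" and n < 5:
        raise ValueError("ordinary kriging needs at least 5 samples")

    est = None
    if method == "ordinary_kriging":
        try:
            sill, rng = _fit_exponential_variogram(xy, v)
            gamma = _exp_variogram(cdist(xy, xy), sill, rng)
            a = np.empty((n + 1, n + 1))
            a[:n, :n] = gamma
            a[n, :], a[:, n] = 1.0, 1.0
            a[n, n] = 0.0
            b = np.empty((n + 1, len(targets)))
            b[:n] = _exp_variogram(cdist(xy, targets), sill, rng)
            b[n] = 1.0
            lam = np.linalg.solve(a, b)
            est = lam[:n].T @ v
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"kriging system singular ({exc}); falling back to IDW", stacklevel=2)
    if est is None:
        est = _idw(xy, v, targets)
    n_neg = int((est < 0).sum())
    if n_neg:
        logger.info("clamped %d negative interpolation estimates to 0", n_neg)
        est = np.maximum(est, 0.0)
    return ValueGrid(target, est.reshape(target.shape), units="emission")


# ---------------------------------------------------------------------------
# Non-point pollution and LCI
# ---------------------------------------------------------------------------

def nonpoint_emission_surface(
    land_use: LandUseGrid,
    population: ValueGrid,
    params: NonPointParams,
) -> ValueGrid:
    """Diffuse-pollution surface: rural per-capita + arable fertilizer loss.

    Rural cells: population density × per-capita rural emission.
    Arable cells: application rate × (1 − effective use rate).
    Every other class: exactly 0.  Nodata propagates from the land-use grid.
    """
    if land_use.spec != population.spec:
        raise AlignmentError("land-use and population grids are not aligned")
    pop = population.values
    if (pop[np.isfinite(pop)] < 0).any():
        raise ValueError("population density must be non-negative")
    out = np.zeros(land_use.spec.shape)
    rural = land_use.class_mask("rural")
    arable = land_use.class_mask("arable")
    out[rural] = np.nan_to_num(pop[rural]) * params.per_capita_rural_emission
    out[arable] = params.arable_application_rate * (1.0 - params.fertilizer_effective_use_rate)
    out[~land_use.mask] = np.nan
    return ValueGrid(land_use.spec, out, units="emission/km2")


def land_cover_indicator(emission_surface: ValueGrid) -> ValueGrid:
    """Land-cover indicator: emission surface min–max rescaled to [0, 1].

    A constant surface maps to all zeros (degenerate range).  The indicator
    is invariant under positive affine rescaling of the input and preserves
    value ranks.
    """
    vals = emission_surface.values
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("all-nodata emission surface")
    if (vals[ok] < 0).any():
        raise RangeError("emission surface must be non-negative")
    lo, hi = vals[ok].min(), vals[ok].max()
    out = np.full(vals.shape, np.nan)
    out[ok] = 0.0 if hi == lo else (vals[ok] - lo) / (hi - lo)
    return ValueGrid(emission_surface.spec, out, units="lci")


def build_pei_components(
    co2: ValueGrid,
    n2o: ValueGrid,
    nonpoint: ValueGrid,
) -> tuple[ValueGrid, ValueGrid, ValueGrid]:
    """Bundle the three per-period emission surfaces for standardization.

    Pass-through contract with an alignment check; temporal averaging (5-year
    blocks) is applied upstream via :func:`temporal_average_grids`.
    """
    if not (co2.spec == n2o.spec == nonpoint.spec):
        raise AlignmentError("PEI component grids are not aligned")
    return co2, n2o, nonpoint


def temporal_average_grids(grids: Sequence[ValueGrid]) -> ValueGrid:
    """Cellwise mean of yearly grids (nodata propagates)."""
    if not grids:
        raise ValueError("no grids to average")
    spec = grids[0].spec
    if any(g.spec != spec for g in grids):
        raise AlignmentError("grids to average are not aligned")
    return ValueGrid(spec, np.mean([g.values for g in grids], axis=0), grids[0].units)
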