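"""Spatiotemporal pattern analytics on disturbance surfaces.

Three analytics summarize how disturbance intensity moves and clusters:

* **Weighted centroid migration** — the HDI-weighted mean location
  ``X = Σ x_ij·HDI_ij / Σ HDI_ij`` (and likewise Y) per period, chained into
  a track with per-segment displacement, compass bearing and speed.
* **Global Moran's I** — spatial autocorrelation
  ``I = ΣΣ W_ij (x_i−x̄)(x_j−x̄) / (S² ΣΣ W_ij)`` with S² the population
  variance, plus a Z test under the normality null (E[I] = −1/(n−1)) and an
  optional permutation null.
* **Getis-Ord Gi*** — local concentration ``G*_i = Σ_j W_ij(d)·x_j / Σ_j x_j``
  with binary distance-band weights including the self term, standardized to
  Z scores and thresholded into hot/cold categories at ±1.645/±1.960/±2.576.

Weights schemes: rook and queen contiguity and a distance band over cell
centers; the toolkit defaults to queen/binary for Moran's I and a band of
twice the cell size (with self) for Gi*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import norm

from .errors import DegenerateInputError
from .grid import GridSpec, ValueGrid
from .scoring import HDIGrid

__all__ = [
    "SpatialWeights",
    "CentroidTrack",
    "HotspotResult",
    "build_weights",
    "weighted_centroid",
    "centroid_track",
    "morans_i",
    "moran_z",
    "moran_permutation",
    "getis_ord_gistar",
]

logger = logging.getLogger(__name__)

_CARDINAL = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass
class SpatialWeights:
    """Sparse binary neighbor structure over the valid cells of a grid.

    ``w`` is an n×n CSR matrix with zero diagonal; ``cell_index`` maps
    (row, col) of each valid cell to its position 0..n−1.
    """

    n: int
    w: sparse.csr_matrix
    scheme: str
    cells: np.ndarray  # (n, 2) array of (row, col)

    def row_standardized(self) -> sparse.csr_matrix:
        rs = np.asarray(self.w.sum(axis=1)).ravel()
        inv = np.where(rs > 0, 1.0 / np.maximum(rs, 1e-300), 0.0)
        return sparse.diags(inv) @ self.w

    @property
    def s0(self) -> float:
        return float(self.w.sum())


def build_weights(
    spec: GridSpec,
    mask: np.ndarray | None = None,
    scheme: str = "queen",
    d: float | None = None,
) -> SpatialWeights:
    """Build a symmetric binary spatial weights matrix over valid cells.

    ``rook`` links edge-sharing neighbors, ``queen`` adds corners,
    ``distance_band`` links cells whose center distance is in (0, d].
    No self-neighbors (the Gi* self term is added separately).
    """
    if mask is None:
        mask = np.ones(spec.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    cells = np.argwhere(mask)
    n = len(cells)
    if n < 2:
        raise DegenerateInputError("need at least 2 valid cells for spatial weights")
    index = -np.ones(spec.shape, dtype=int)
    index[mask] = np.arange(n)
    rows_i, cols_j = [], []
    if scheme in {"rook", "queen"}:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        for di, dj in offsets:
            ri, rj = cells[:, 0] + di, cells[:, 1] + dj
            ok = (ri >= 0) & (ri < spec.n_rows) & (rj >= 0) & (rj < spec.n_cols)
            ok[ok] &= mask[ri[ok], rj[ok]]
            rows_i.append(np.arange(n)[ok])
            cols_j.append(index[ri[ok], rj[ok]])
    elif scheme == "distance_band":
        if d is None or d < spec.cell_size:
            raise DegenerateInputError(
                f"distance band d={d} below cell size {spec.cell_size} gives empty neighborhoods"
            )
        xs, ys = spec.cell_centers()
        pts = np.column_stack([xs[cells[:, 1]], ys[cells[:, 0]]])
        tree = cKDTree(pts)
        pairs = tree.query_pairs(d * (1 + 1e-12), output_type="ndarray")
        rows_i = [pairs[:, 0], pairs[:, 1]]
        cols_j = [pairs[:, 1], pairs[:, 0]]
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    i = np.concatenate(rows_i) if rows_i else np.array([], dtype=int)
    j = np.concatenate(cols_j) if cols_j else np.array([], dtype=int)
    w = sparse.csr_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
    w.sum_duplicates()
    w.data[:] = 1.0
    return SpatialWeights(n=n, w=w, scheme=scheme if d is None else f"{scheme}({d}m)", cells=cells)


# ---------------------------------------------------------------------------
# Centroid migration
# ---------------------------------------------------------------------------

def weighted_centroid(hdi: HDIGrid | ValueGrid) -> tuple[float, float]:
    """Intensity-weighted mean location of a disturbance surface.

    Uses cell-center coordinates; nodata cells are excluded.  An all-zero
    (or all-nodata) surface has no centroid and raises
    :class:`~hdikit.errors.DegenerateInputError`.
    """
    vals = hdi.hdi if isinstance(hdi, HDIGrid) else hdi.values
    spec = hdi.spec
    ok = np.isfinite(vals)
    total = float(vals[ok].sum()) if ok.any() else 0.0
    if total <= 0:
        raise DegenerateInputError("centroid undefined: disturbance surface sums to zero")
    xm, ym = spec.center_mesh()
    x = float((xm[ok] * vals[ok]).sum() / total)
    y = float((ym[ok] * vals[ok]).sum() / total)
    return x, y


def _bearing_deg(dx: float, dy: float) -> float:
    """Compass bearing in degrees clockwise from north."""
    return math.degrees(math.atan2(dx, dy)) % 360.0


def cardinal_direction(bearing_deg: float) -> str:
    """Bin a compass bearing to the 8 cardinal/intercardinal directions."""
    return _CARDINAL[int(round(bearing_deg / 45.0)) % 8]


@dataclass
class CentroidTrack:
    """Time-ordered centroids and per-segment kinematics.

    ``points`` is a list of (period_label, X, Y); ``segments`` a list of
    dicts with displacement (m), bearing (degrees clockwise from north),
    direction (8-wind), interval (years) and speed (m/year).
    """

    points: list[tuple[str, float, float]]
    segments: list[dict]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.segments)


def centroid_track(
    centroids: Sequence[tuple[str, float, float]],
    interval_years: Sequence[float] | Mapping[tuple[str, str], float],
) -> CentroidTrack:
    """Chain per-period centroids into a migration track.

    ``interval_years`` gives the elapsed years of each consecutive segment,
    either as a sequence (len(centroids) − 1) or a mapping keyed by
    (from_label, to_label).  Speed is displacement divided by the actual
    interval length.
    """
    if len(centroids) < 2:
        raise ValueError("need at least two centroids for a track")
    segments = []
    for (la, xa, ya), (lb, xb, yb) in zip(centroids[:-1], centroids[1:]):
        years = interval_years[(la, lb)] if isinstance(interval_years, Mapping) else interval_years[len(segments)]
        if not years > 0:
            raise ValueError(f"non-positive interval for segment {la}->{lb}: {years}")
        dx, dy = xb - xa, yb - ya
        disp = math.hypot(dx, dy)
        bearing = _bearing_deg(dx, dy) if disp > 0 else float("nan")
        segments.append(
            {
                "from": la,
                "to": lb,
                "displacement_m": disp,
                "bearing_deg": bearing,
                "direction": cardinal_direction(bearing) if disp > 0 else "",
                "interval_years": float(years),
                "speed_m_per_year": disp / years,
            }
        )
    return CentroidTrack(points=list(centroids), segments=segments)


# ---------------------------------------------------------------------------
# Global Moran's I
# ---------------------------------------------------------------------------

def _check_field(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise DegenerateInputError("need at least 2 cells")
    if np.var(x) == 0:
        raise DegenerateInputError("zero-variance field: Moran's I undefined")
    return x


def morans_i(values: np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I with binary (non-standardized) weights.

    ``I = n · Σ_ij W_ij z_i z_j / (S0 · Σ z²)`` with z the mean deviations —
    the double-sum form normalized by the population variance.
    """
    x = _check_field(values)
    if len(x) != weights.n:
        raise ValueError("values length does not match weights")
    z = x - x.mean()
    num = float(z @ (weights.w @ z))
    s0 = weights.s0
    return len(x) * num / (s0 * float(z @ z))


def _moran_moments_normality(weights: SpatialWeights) -> tuple[float, float]:
    n = weights.n
    w = weights.w
    s0 = weights.s0
    wt = w.T.tocsr()
    s1 = 0.5 * float((w + wt).power(2).sum())
    rs = np.asarray(w.sum(axis=1)).ravel() + np.asarray(w.sum(axis=0)).ravel()
    s2 = float((rs**2).sum())
    e_i = -1.0 / (n - 1)
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i**2
    return e_i, var


def moran_z(values: np.ndarray, weights: SpatialWeights) -> tuple[float, float, float]:
    """(I, Z, two-sided p) for global Moran's I under the normality null."""
    i_obs = morans_i(values, weights)
    e_i, var = _moran_moments_normality(weights)
    z = (i_obs - e_i) / math.sqrt(var)
    p = 2.0 * float(norm.sf(abs(z)))
    return i_obs, z, p


def moran_permutation(
    values: np.ndarray,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation null for Moran's I (seeded).

    Returns the observed I, the permutation distribution's mean/sd, a
    pseudo p-value and the full distribution.
    """
    x = _check_field(values)
    i_obs = morans_i(x, weights)
    rng = np.random.default_rng(seed)
    z = x - x.mean()
    denom = float(z @ z)
    n = len(x)
    s0 = weights.s0
    sims = np.empty(n_permutations)
    for r in range(n_permutations):
        zp = rng.permutation(z)
        sims[r] = n * float(zp @ (weights.w @ zp)) / (s0 * denom)
    extreme = int((np.abs(sims - sims.mean()) >= abs(i_obs - sims.mean())).sum())
    return {
        "i": i_obs,
        "mean": float(sims.mean()),
        "sd": float(sims.std(ddof=1)),
        "p_sim": (extreme + 1) / (n_permutations + 1),
        "sims": sims,
    }


# ---------------------------------------------------------------------------
# Getis-Ord Gi*
# ---------------------------------------------------------------------------

@dataclass
class HotspotResult:
    """Per-cell Gi*, Z scores and hot/cold categories on the source grid."""

    spec: GridSpec
    gi_star: np.ndarray
    z_scores: np.ndarray
    category: np.ndarray  # dtype=object strings

    CATEGORIES = ("cold99", "cold95", "cold90", "not_significant", "hot90", "hot95", "hot99")


def _categorize(z: np.ndarray) -> np.ndarray:
    cat = np.full(z.shape, "not_significant", dtype=object)
    cat[z >= 1.645] = "hot90"
    cat[z >= 1.960] = "hot95"
    cat[z >= 2.576] = "hot99"
    cat[z <= -1.645] = "cold90"
    cat[z <= -1.960] = "cold95"
    cat[z <= -2.576] = "cold99"
    return cat


def getis_ord_gistar(
    values: ValueGrid,
    d: float | None = None,
    weights: SpatialWeights | None = None,
) -> HotspotResult:
    """Getis-Ord Gi* hot/cold-spot analysis with a binary distance band.

    ``G*_i = Σ_j W_ij(d) x_j / Σ_j x_j`` where the band includes the focal
    cell itself (W_ii = 1, the starred statistic).  Z scores use the
    randomization moments; categories follow the ±1.645/1.960/2.576
    thresholds.  Default band: twice the cell size.  A constant field
    yields Z = 0 everywhere by convention (logged).
    """
    spec = values.spec
    ok = values.mask
    x = values.values[ok]
    if (x < 0).any():
        raise ValueError("Gi* requires non-negative values")
    if x.sum() <= 0:
        raise DegenerateInputError("Gi* undefined on a zero-sum field")
    if weights is None:
        if d is None:
            d = 2.0 * spec.cell_size
        weights = build_weights(spec, ok, "distance_band", d=d)
    n = weights.n
    w_self = weights.w + sparse.identity(n, format="csr")
    wx = np.asarray(w_self @ x).ravel()
    gi = wx / float(x.sum())
    xbar = x.mean()
    s = math.sqrt(float((x**2).mean()) - xbar**2)
    wi = np.asarray(w_self.sum(axis=1)).ravel()
    s1i = np.asarray(w_self.power(2).sum(axis=1)).ravel()
    if s == 0:
        logger.info("constant field: all Gi* Z scores set to 0 by convention")
        z = np.zeros(n)
    else:
        denom = s * np.sqrt(np.maximum((n * s1i - wi**2) / (n - 1), 0.0))
        z = (wx - xbar * wi) / np.where(denom > 0, denom, np.inf)
    gi_grid = np.full(spec.shape, np.nan)
    z_grid = np.full(spec.shape, np.nan)
    cat_grid = np.full(spec.shape, "", dtype=object)
    gi_grid[ok] = gi
    z_grid[ok] = z
    cat_grid[ok] = _categorize(z)
    return HotspotResult(spec, gi_grid, z_grid, cat_grid)
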