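"""Georeferenced grid data model, I/O, alignment, masking and nodata handling.

All grids live on a :class:`GridSpec`: a regular raster in a single projected
coordinate system with cell sizes in meters.  Cell ``(i, j)`` (0-based, row
index increasing southward) has its center at::

    x = origin_x + (j + 0.5) * cell_size
    y = origin_y - (i + 0.5) * cell_size

where ``(origin_x, origin_y)`` is the outer (north-west) corner of cell
``(0, 0)``.  Two grids are *aligned* iff their specs are equal field by field.

Continuous grids (:class:`ValueGrid`) use ``NaN`` as the nodata sentinel, so
nodata propagates through ordinary NumPy arithmetic.  Categorical grids
(:class:`LandUseGrid`) carry an integer code matrix plus a legend; the code
mapped to the ``"nodata"`` class marks missing cells.

Supported formats: GeoTIFF (via tifffile, with ModelPixelScale/ModelTiepoint/
GeoAsciiParams/GDAL_NODATA tags) and ESRI ASCII grid (text, fixture-friendly).
No reprojection is performed — inputs must share one projected CRS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, EmptyZoneError, LegendError

__all__ = [
    "GridSpec",
    "ValueGrid",
    "LandUseGrid",
    "LAND_USE_CLASSES",
    "DEFAULT_LEGEND",
    "read_raster",
    "write_raster",
    "align",
    "zonal_mask",
    "zones_from_geojson",
]

#: The nine land-use classes of the disturbance framework plus nodata.
LAND_USE_CLASSES = (
    "arable",
    "forest",
    "grassland",
    "artificial_water",
    "natural_water",
    "urban",
    "rural",
    "industrial",
    "unused",
)

#: Default code → class legend (0 is reserved for nodata).
DEFAULT_LEGEND: dict[int, str] = {0: "nodata", **{i + 1: c for i, c in enumerate(LAND_USE_CLASSES)}}


@dataclass(frozen=True)
class GridSpec:
    """Geometry and CRS label of a regular raster grid."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float
    origin_y: float
    crs_label: str = "local-meters"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs of shape (n_cols,), ys of shape (n_rows,)) cell-center coordinates."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (n_rows, n_cols) meshes of cell-center x and y."""
        xs, ys = self.cell_centers()
        return np.broadcast_to(xs, self.shape).copy(), np.broadcast_to(ys[:, None], self.shape).copy()

    def aligned_with(self, other: "GridSpec") -> bool:
        return self == other


@dataclass
class ValueGrid:
    """Continuous raster with NaN nodata and a free-text unit label."""

    spec: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(f"values shape {self.values.shape} != spec shape {self.spec.shape}")
        if np.isinf(self.values).any():
            raise ValueError("values must be finite where not nodata (NaN)")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "ValueGrid":
        return ValueGrid(self.spec, np.asarray(values, dtype=float), self.units if units is None else units)


@dataclass
class LandUseGrid:
    """Categorical raster of land-use codes plus a code → class legend."""

    spec: GridSpec
    codes: np.ndarray
    legend: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("land-use codes must be integers")
        if self.codes.shape != self.spec.shape:
            raise ValueError(f"codes shape {self.codes.shape} != spec shape {self.spec.shape}")
        self.legend = dict(self.legend)
        present = np.unique(self.codes)
        unknown = [int(c) for c in present if int(c) not in self.legend]
        if unknown:
            raise LegendError(f"land-use codes missing from legend: {unknown}")

    @property
    def nodata_codes(self) -> set[int]:
        return {c for c, name in self.legend.items() if name == "nodata"}

    @property
    def mask(self) -> np.ndarray:
        """Valid (non-nodata) cells."""
        out = np.ones(self.codes.shape, dtype=bool)
        for c in self.nodata_codes:
            out &= self.codes != c
        return out

    def class_mask(self, cls: str) -> np.ndarray:
        codes = [c for c, name in self.legend.items() if name == cls]
        out = np.zeros(self.codes.shape, dtype=bool)
        for c in codes:
            out |= self.codes == c
        return out

    def class_counts(self) -> dict[str, int]:
        """Cell counts per class, nodata excluded."""
        out: dict[str, int] = {}
        for code, name in self.legend.items():
            if name == "nodata":
                continue
            out[name] = out.get(name, 0) + int((self.codes == code).sum())
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


def write_raster(grid: ValueGrid | LandUseGrid, path: str | Path) -> None:
    """Write a grid as GeoTIFF (.tif/.tiff) or ESRI ASCII (.asc/.txt)."""
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt"}:
        _write_ascii(grid, path)
    else:
        _write_geotiff(grid, path)


def _write_geotiff(grid: ValueGrid | LandUseGrid, path: Path) -> None:
    import tifffile

    spec = grid.spec
    if isinstance(grid, LandUseGrid):
        data = grid.codes.astype(np.int32)
        nodata = str(min(grid.nodata_codes)) if grid.nodata_codes else ""
        desc = json.dumps({"kind": "categorical", "legend": {str(k): v for k, v in grid.legend.items()}})
    else:
        data = grid.values.astype(np.float64)
        nodata = "nan"
        desc = json.dumps({"kind": "continuous", "units": grid.units})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
        (_TAG_GEO_ASCII, "s", 0, spec.crs_label + "|"),
    ]
    if nodata:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, nodata))
    tifffile.imwrite(path, data, description=desc, extratags=extratags)


def _write_ascii(grid: ValueGrid | LandUseGrid, path: Path) -> None:
    spec = grid.spec
    if isinstance(grid, LandUseGrid):
        nodata = min(grid.nodata_codes) if grid.nodata_codes else -9999
        data = grid.codes
        fmt = "%d"
    else:
        nodata = -9999.0
        data = np.where(np.isfinite(grid.values), grid.values, nodata)
        fmt = "%.17g"
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.asarray(data), fmt=fmt)
    # sidecar with CRS label + legend so round trips are lossless
    meta: dict = {"crs_label": spec.crs_label}
    if isinstance(grid, LandUseGrid):
        meta["legend"] = {str(k): v for k, v in grid.legend.items()}
    else:
        meta["units"] = grid.units
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_raster(
    path: str | Path,
    kind: str,
    legend: Mapping[int, str] | None = None,
    crs_label: str | None = None,
) -> ValueGrid | LandUseGrid:
    """Read a raster file.

    Parameters
    ----------
    path
        GeoTIFF (.tif/.tiff) or ESRI ASCII (.asc/.txt) file.
    kind
        ``"categorical"`` (returns :class:`LandUseGrid`) or ``"continuous"``
        (returns :class:`ValueGrid`).  Categorical reads reject non-integer
        bands and codes absent from the legend.
    legend
        Code → class mapping for categorical reads; defaults to the legend
        embedded in the file, else :data:`DEFAULT_LEGEND`.
    """
    if kind not in {"categorical", "continuous"}:
        raise ValueError(f"kind must be 'categorical' or 'continuous', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    if path.suffix.lower() in {".asc", ".txt"}:
        return _read_ascii(path, kind, legend, crs_label)
    return _read_geotiff(path, kind, legend, crs_label)


def _read_geotiff(path: Path, kind, legend, crs_label):
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            data = page.asarray()
            tags = page.tags
            if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
                raise IOError(f"{path} lacks GeoTIFF georeferencing tags")
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            tie = tags[_TAG_MODEL_TIEPOINT].value
            if crs_label is None:
                crs_label = (
                    str(tags[_TAG_GEO_ASCII].value).rstrip("|")
                    if _TAG_GEO_ASCII in tags
                    else "local-meters"
                )
            raw_desc = tags["ImageDescription"].value if "ImageDescription" in tags else ""
            nodata_tag = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else "nan"
    except IOError:
        raise
    except Exception as exc:  # unreadable / not a TIFF
        raise IOError(f"cannot read raster {path}: {exc}") from exc
    origin_x, origin_y = tie[3], tie[4]
    if not math.isclose(sx, sy):
        raise IOError("only square cells are supported")
    spec = GridSpec(data.shape[0], data.shape[1], float(sx), float(origin_x), float(origin_y), crs_label)
    try:
        desc = json.loads(raw_desc)
    except (json.JSONDecodeError, TypeError):
        desc = {}
    if kind == "categorical":
        if not np.issubdtype(data.dtype, np.integer):
            raise LegendError(f"categorical read of {path}: band dtype {data.dtype} is not integer")
        if legend is None:
            legend = {int(k): v for k, v in desc.get("legend", {}).items()} or DEFAULT_LEGEND
        return LandUseGrid(spec, data.astype(np.int64), legend)
    values = data.astype(float)
    if str(nodata_tag).strip().lower() != "nan":
        values[values == float(nodata_tag)] = np.nan
    return ValueGrid(spec, values, units=desc.get("units", ""))


def _read_ascii(path: Path, kind, legend, crs_label):
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise IOError(f"{path}: ESRI ASCII header missing {key}")
    data = np.loadtxt(lines[n_header:], ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise IOError(f"{path}: data shape {data.shape} does not match header ({n_rows}, {n_cols})")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if crs_label is None:
        crs_label = meta.get("crs_label", "local-meters")
    spec = GridSpec(
        n_rows, n_cols, header["cellsize"],
        header["xllcorner"], header["yllcorner"] + n_rows * header["cellsize"], crs_label,
    )
    nodata = header.get("nodata_value")
    if kind == "categorical":
        if not np.allclose(data, np.round(data)):
            raise LegendError(f"categorical read of {path}: non-integer values present")
        if legend is None:
            legend = {int(k): v for k, v in meta.get("legend", {}).items()} or DEFAULT_LEGEND
        return LandUseGrid(spec, data.astype(np.int64), legend)
    values = data.astype(float)
    if nodata is not None:
        values[values == nodata] = np.nan
    return ValueGrid(spec, values, units=meta.get("units", ""))


# ---------------------------------------------------------------------------
# Alignment and masking
# ---------------------------------------------------------------------------

def _resample_indices(src: GridSpec, dst: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source (row, col) indices sampled at each destination cell center.

    Returns (rows, cols, inside-mask); out-of-bounds destinations are clipped
    and flagged False in the mask.
    """
    xs, ys = dst.cell_centers()
    cols = np.floor((xs - src.origin_x) / src.cell_size).astype(int)
    rows = np.floor((src.origin_y - ys) / src.cell_size).astype(int)
    in_c = (cols >= 0) & (cols < src.n_cols)
    in_r = (rows >= 0) & (rows < src.n_rows)
    inside = in_r[:, None] & in_c[None, :]
    return (
        np.clip(rows, 0, src.n_rows - 1)[:, None].repeat(dst.n_cols, axis=1),
        np.clip(cols, 0, src.n_cols - 1)[None, :].repeat(dst.n_rows, axis=0),
        inside,
    )


def align(
    grids: Sequence[ValueGrid | LandUseGrid],
    target: GridSpec,
    method: str = "nearest",
) -> list[ValueGrid | LandUseGrid]:
    """Resample grids onto ``target``.

    Categorical grids are always resampled nearest-neighbor regardless of
    ``method``; continuous grids honor ``method`` (``nearest`` or
    ``bilinear``).  Grids already on ``target`` are returned unchanged.
    Mismatched CRS labels raise :class:`AlignmentError` — there is no
    implicit reprojection.
    """
    if method not in {"nearest", "bilinear"}:
        raise ValueError(f"unknown resampling method {method!r}")
    out: list[ValueGrid | LandUseGrid] = []
    for g in grids:
        if g.spec.crs_label != target.crs_label:
            raise AlignmentError(
                f"CRS mismatch: grid has {g.spec.crs_label!r}, target has {target.crs_label!r}"
            )
        if g.spec == target:
            out.append(g)
            continue
        if isinstance(g, LandUseGrid):
            rows, cols, inside = _resample_indices(g.spec, target)
            codes = g.codes[rows, cols]
            fill = min(g.nodata_codes) if g.nodata_codes else 0
            codes = np.where(inside, codes, fill)
            legend = dict(g.legend)
            legend.setdefault(int(fill), "nodata")
            out.append(LandUseGrid(target, codes, legend))
        elif method == "nearest":
            rows, cols, inside = _resample_indices(g.spec, target)
            vals = g.values[rows, cols]
            out.append(ValueGrid(target, np.where(inside, vals, np.nan), g.units))
        else:
            xs, ys = target.cell_centers()
            fj = (xs - g.spec.origin_x) / g.spec.cell_size - 0.5
            fi = (g.spec.origin_y - ys) / g.spec.cell_size - 0.5
            coords = np.meshgrid(fi, fj, indexing="ij")
            vals = ndimage.map_coordinates(
                g.values, coords, order=1, mode="constant", cval=np.nan
            )
            out.append(ValueGrid(target, vals, g.units))
    return out


def zonal_mask(grid: ValueGrid, zones: LandUseGrid | ValueGrid, zone_id: int) -> ValueGrid:
    """Mask ``grid`` to one zone: cells outside ``zone_id`` become nodata."""
    if grid.spec != zones.spec:
        raise AlignmentError("grid and zone raster are not aligned")
    zcodes = zones.codes if isinstance(zones, LandUseGrid) else zones.values
    in_zone = zcodes == zone_id
    if not in_zone.any():
        raise EmptyZoneError(f"zone id {zone_id} not present in zone raster")
    return grid.copy_with(np.where(in_zone, grid.values, np.nan))


def zones_from_geojson(geojson: Mapping | str | Path, spec: GridSpec, id_property: str = "zone_id") -> LandUseGrid:
    """Rasterize GeoJSON polygons onto ``spec`` by cell-center point-in-polygon.

    Each feature needs an integer ``id_property``; cells covered by no
    feature get code 0 (nodata).
    """
    from shapely.geometry import shape, Point
    from shapely.prepared import prep

    if isinstance(geojson, (str, Path)):
        geojson = json.loads(Path(geojson).read_text())
    codes = np.zeros(spec.shape, dtype=np.int64)
    xmesh, ymesh = spec.center_mesh()
    legend = {0: "nodata"}
    for feat in geojson.get("features", []):
        zid = int(feat["properties"][id_property])
        geom = prep(shape(feat["geometry"]))
        hit = np.array(
            [geom.contains(Point(x, y)) for x, y in zip(xmesh.ravel(), ymesh.ravel())]
        ).reshape(spec.shape)
        codes[hit] = zid
        legend[zid] = f"zone_{zid}"
    return LandUseGrid(spec, codes, legend)
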