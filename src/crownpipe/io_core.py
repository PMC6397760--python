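"""Domain types and file I/O for the crown pipeline.

Every other module works on the in-memory types defined here: a canopy
height model (CHM) raster, a co-registered hyperspectral reflectance cube,
tabular stem and crown records, per-pixel crown observations, and vector
crown polygons.

Conventions
-----------
* All coordinates are projected metric easting/northing (UTM-style).  The
  normalized matching costs downstream are built from metre-valued RMS
  errors, so geographic (degree) coordinates must be projected upstream.
* Rasters: row 0 is the northernmost row; ``origin`` is the (easting,
  northing) of the grid's upper-left *outer* corner; pixel ``(r, c)``
  covers the half-open square ``[ox + c*s, ox + (c+1)*s) x
  (oy - (r+1)*s, oy - r*s]`` and its centre sits at ``corner + s/2``.
  Indices are 0-based everywhere.
* Nodata is ``NaN`` internally; any declared nodata sentinel is mapped to
  NaN on read.  NaN pixels never enter masks or features.

GeoTIFF files are read and written with :mod:`tifffile`, carrying the
standard GeoTIFF ``ModelPixelScale``/``ModelTiepoint`` tags, the
``GDAL_NODATA`` tag and a JSON ``ImageDescription`` holding the CRS label
(and, for cubes, the band wavelengths).  A sidecar plain-text wavelength
list (``<path>.wavelengths.txt``, one value per line) is also accepted.
Tables are CSV with a header; crown polygons are GeoJSON.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GDAL_NODATA = 42113

__all__ = [
    "CanopyHeightModel",
    "SpectralCube",
    "StemRecord",
    "CrownRecord",
    "CrownPolygon",
    "PixelObservation",
    "read_chm",
    "write_chm",
    "read_cube",
    "write_cube",
    "band_nearest",
    "read_stems",
    "write_stems",
    "read_crowns",
    "write_crowns",
    "read_pixel_table",
    "write_pixel_table",
    "read_crown_polygons",
    "write_crown_polygons",
    "write_label_raster",
    "read_label_raster",
    "load_yaml_config",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CanopyHeightModel:
    """Single-band raster of canopy height above ground, in metres.

    Parameters
    ----------
    heights:
        2-D float array, metres above ground; NaN marks nodata.
    origin:
        (easting, northing) of the upper-left outer corner of the grid, m.
    pixel_size:
        Side length of the (square) pixels, m.
    crs_label:
        Free-text coordinate-system identifier, e.g. ``"EPSG:32617"``.
    """

    heights: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.size == 0:
            raise ValueError("heights must be a non-empty 2-D grid")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        finite = self.heights[np.isfinite(self.heights)]
        if finite.size and finite.min() < 0:
            raise ValueError("CHM heights must be >= 0 (or NaN for nodata)")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape  # type: ignore[return-value]

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of the centre of pixel ``(row, col)``."""
        ox, oy = self.origin
        s = self.pixel_size
        return (ox + (col + 0.5) * s, oy - (row + 0.5) * s)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectors of column-centre eastings and row-centre northings."""
        ox, oy = self.origin
        s = self.pixel_size
        n_rows, n_cols = self.shape
        xs = ox + (np.arange(n_cols) + 0.5) * s
        ys = oy - (np.arange(n_rows) + 0.5) * s
        return xs, ys


@dataclass
class SpectralCube:
    """Hyperspectral reflectance cube co-registered with a CHM.

    ``reflectance`` is band x row x col, unitless; ``wavelengths_nm`` holds
    one strictly increasing centre wavelength per band.
    """

    reflectance: np.ndarray
    wavelengths_nm: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.reflectance.ndim != 3 or self.reflectance.size == 0:
            raise ValueError("reflectance must be a non-empty band x row x col grid")
        if self.wavelengths_nm.ndim != 1:
            raise ValueError("wavelengths_nm must be 1-D")
        if self.reflectance.shape[0] != self.wavelengths_nm.size:
            raise ValueError(
                f"band count {self.reflectance.shape[0]} != number of "
                f"wavelengths {self.wavelengths_nm.size}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.reflectance.shape[1:]  # type: ignore[return-value]

    def check_coregistered(self, chm: CanopyHeightModel) -> None:
        """Raise if this cube does not share the CHM's grid geometry."""
        if self.grid_shape != chm.shape:
            raise ValueError(
                f"cube grid {self.grid_shape} does not match CHM grid {chm.shape}"
            )
        if self.origin != chm.origin or self.pixel_size != chm.pixel_size:
            raise ValueError("cube georeference does not match CHM georeference")


@dataclass
class StemRecord:
    """A field-measured stem: position, height, diameter, optional species."""

    stem_id: str
    x_pos: float
    y_pos: float
    stem_height_m: float
    stem_diameter_cm: float
    species: str | None = None
    plot_id: str | None = None

    def __post_init__(self) -> None:
        if not self.stem_height_m > 0:
            raise ValueError(f"stem_height_m must be > 0, got {self.stem_height_m}")
        if not self.stem_diameter_cm > 0:
            raise ValueError(
                f"stem_diameter_cm must be > 0, got {self.stem_diameter_cm}"
            )


@dataclass
class CrownRecord:
    """A remotely sensed crown: position, area and owning plot."""

    crown_id: str
    x_pos: float
    y_pos: float
    area_m2: float
    plot_id: str

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValueError(f"area_m2 must be > 0, got {self.area_m2}")


@dataclass
class CrownPolygon:
    """Vector outline of one segmented crown with its treetop apex."""

    crown_id: str
    boundary: list[tuple[float, float]]
    apex: tuple[float, float]
    area_m2: float

    def __post_init__(self) -> None:
        if len(self.boundary) < 4:
            raise ValueError("boundary ring must have at least 4 vertices (closed)")
        if tuple(self.boundary[0]) != tuple(self.boundary[-1]):
            raise ValueError("boundary ring must be closed (first == last vertex)")
        poly = _ShapelyPolygon(self.boundary)
        if not poly.is_valid:
            raise ValueError(f"crown {self.crown_id}: boundary self-intersects")
        if not self.area_m2 > 0:
            raise ValueError(f"area_m2 must be > 0, got {self.area_m2}")
        if not math.isclose(poly.area, self.area_m2, rel_tol=1e-6):
            raise ValueError(
                f"crown {self.crown_id}: area_m2 {self.area_m2} does not match "
                f"boundary polygon area {poly.area}"
            )


@dataclass
class PixelObservation:
    """One crown pixel: CHM height plus the full reflectance spectrum."""

    crown_id: str
    height_m: float
    reflectances: np.ndarray

    def __post_init__(self) -> None:
        self.reflectances = np.asarray(self.reflectances, dtype=float)
        if self.reflectances.ndim != 1:
            raise ValueError("reflectances must be a 1-D vector")


# ---------------------------------------------------------------------------
# GeoTIFF raster I/O
# ---------------------------------------------------------------------------


def _geo_extratags(origin: tuple[float, float], pixel_size: float) -> list:
    ox, oy = origin
    s = float(pixel_size)
    # NaN is the native nodata of float rasters, so no GDAL_NODATA tag is
    # written; sentinel tags from other producers are honoured on read.
    return [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(ox), float(oy), 0.0)),
    ]


def _read_geo_tags(page) -> tuple[tuple[float, float], float, dict, float | None]:
    """Extract (origin, pixel_size, description dict, nodata) from a TIFF page."""
    scale_tag = page.tags.get(TAG_MODEL_PIXEL_SCALE)
    tie_tag = page.tags.get(TAG_MODEL_TIEPOINT)
    if scale_tag is None or tie_tag is None:
        raise ValueError(
            "raster is missing GeoTIFF ModelPixelScale/ModelTiepoint tags"
        )
    sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise ValueError(f"non-square pixels: scale x={sx} != y={sy}")
    tie = tie_tag.value
    # tie: raster (i, j, k) -> model (x, y, z); require the corner tiepoint
    i, j = float(tie[0]), float(tie[1])
    x, y = float(tie[3]), float(tie[4])
    origin = (x - i * sx, y + j * sy)
    desc: dict = {}
    if page.description:
        try:
            parsed = json.loads(page.description)
            if isinstance(parsed, dict):
                desc = parsed
        except (ValueError, TypeError):
            pass
    nodata: float | None = None
    nd_tag = page.tags.get(TAG_GDAL_NODATA)
    if nd_tag is not None:
        try:
            nodata = float(str(nd_tag.value).strip())
        except ValueError:
            nodata = None
    return origin, sx, desc, nodata


def write_chm(chm: CanopyHeightModel, path: str | Path) -> None:
    """Write a CHM as a single-band float32 GeoTIFF."""
    desc = json.dumps({"crs_label": chm.crs_label})
    tifffile.imwrite(
        str(path),
        chm.heights.astype(np.float32),
        photometric="minisblack",
        description=desc,
        extratags=_geo_extratags(chm.origin, chm.pixel_size),
    )


def read_chm(path: str | Path) -> CanopyHeightModel:
    """Read a single-band georeferenced GeoTIFF into a :class:`CanopyHeightModel`.

    The file's nodata sentinel (GDAL_NODATA tag), if any, is mapped to NaN.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(float)
        page = tif.pages[0]
        origin, pixel_size, desc, nodata = _read_geo_tags(page)
    if arr.ndim == 3:
        if arr.shape[0] != 1 and arr.shape[-1] != 1:
            raise ValueError(
                f"expected a single-band CHM raster, file has shape {arr.shape}"
            )
        arr = arr.reshape(arr.shape[1:] if arr.shape[0] == 1 else arr.shape[:2])
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D single-band raster, got ndim={arr.ndim}")
    if nodata is not None and not math.isnan(nodata):
        arr = np.where(arr == nodata, np.nan, arr)
    return CanopyHeightModel(
        heights=arr,
        origin=origin,
        pixel_size=pixel_size,
        crs_label=str(desc.get("crs_label", "")),
    )


def write_cube(cube: SpectralCube, path: str | Path) -> None:
    """Write a cube as a multi-page float32 GeoTIFF (one page per band).

    Wavelengths are stored in the JSON ImageDescription and also in a
    plain-text sidecar ``<path>.wavelengths.txt``.
    """
    path = Path(path)
    desc = json.dumps(
        {"crs_label": cube.crs_label, "wavelengths_nm": cube.wavelengths_nm.tolist()}
    )
    tifffile.imwrite(
        str(path),
        cube.reflectance.astype(np.float32),
        photometric="minisblack",
        description=desc,
        extratags=_geo_extratags(cube.origin, cube.pixel_size),
    )
    sidecar = path.with_name(path.name + ".wavelengths.txt")
    sidecar.write_text("\n".join(f"{w:.6f}" for w in cube.wavelengths_nm) + "\n")


def read_cube(path: str | Path) -> SpectralCube:
    """Read a multi-band georeferenced GeoTIFF into a :class:`SpectralCube`.

    Wavelengths come from the embedded JSON description or, failing that,
    from a ``<path>.wavelengths.txt`` sidecar (one wavelength per line).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray().astype(float)
        page = tif.pages[0]
        origin, pixel_size, desc, nodata = _read_geo_tags(page)
    if arr.ndim == 2:
        arr = arr[np.newaxis, :, :]
    if arr.ndim != 3:
        raise ValueError(f"expected a band x row x col raster, got ndim={arr.ndim}")
    wavelengths = desc.get("wavelengths_nm")
    if wavelengths is None:
        sidecar = path.with_name(path.name + ".wavelengths.txt")
        if not sidecar.exists():
            raise ValueError(
                f"no wavelength metadata: neither embedded JSON nor sidecar "
                f"{sidecar.name} found"
            )
        wavelengths = [float(line) for line in sidecar.read_text().split()]
    if nodata is not None and not math.isnan(nodata):
        arr = np.where(arr == nodata, np.nan, arr)
    return SpectralCube(
        reflectance=arr,
        wavelengths_nm=np.asarray(wavelengths, dtype=float),
        origin=origin,
        pixel_size=pixel_size,
        crs_label=str(desc.get("crs_label", "")),
    )


def band_nearest(cube: SpectralCube, target_nm: float) -> int:
    """Index of the band whose centre wavelength is nearest ``target_nm``.

    Ties are broken toward the lower index.  This resolves sensor-specific
    band numbering (e.g. "band 50" on one instrument) into a wavelength
    rule that transfers across sensors.
    """
    return int(np.argmin(np.abs(cube.wavelengths_nm - float(target_nm))))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_STEM_COLUMNS = ["stem_id", "x_pos", "y_pos", "stem_height_m", "stem_diameter_cm"]
_CROWN_COLUMNS = ["crown_id", "x_pos", "y_pos", "area_m2", "plot_id"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")


def read_stems(path: str | Path) -> list[StemRecord]:
    """Read stem records from CSV.

    Rows violating the type invariants (non-positive height or diameter,
    unparsable numbers) are dropped with a row-numbered warning; valid rows
    are returned.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _STEM_COLUMNS, path)
    records: list[StemRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is line 1
        try:
            records.append(
                StemRecord(
                    stem_id=str(row["stem_id"]),
                    x_pos=float(row["x_pos"]),
                    y_pos=float(row["y_pos"]),
                    stem_height_m=float(row["stem_height_m"]),
                    stem_diameter_cm=float(row["stem_diameter_cm"]),
                    species=None
                    if "species" not in df.columns or pd.isna(row["species"])
                    else str(row["species"]),
                    plot_id=None
                    if "plot_id" not in df.columns or pd.isna(row["plot_id"])
                    else str(row["plot_id"]),
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path.name} row {rowno}: rejected stem record ({exc})")
    return records


def write_stems(stems: Sequence[StemRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "stem_id": [s.stem_id for s in stems],
            "x_pos": [s.x_pos for s in stems],
            "y_pos": [s.y_pos for s in stems],
            "stem_height_m": [s.stem_height_m for s in stems],
            "stem_diameter_cm": [s.stem_diameter_cm for s in stems],
            "species": [s.species for s in stems],
            "plot_id": [s.plot_id for s in stems],
        }
    ).to_csv(path, index=False)


def read_crowns(path: str | Path) -> list[CrownRecord]:
    """Read crown records from CSV; invalid rows dropped with warnings."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _CROWN_COLUMNS, path)
    records: list[CrownRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2
        try:
            records.append(
                CrownRecord(
                    crown_id=str(row["crown_id"]),
                    x_pos=float(row["x_pos"]),
                    y_pos=float(row["y_pos"]),
                    area_m2=float(row["area_m2"]),
                    plot_id=str(row["plot_id"]),
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path.name} row {rowno}: rejected crown record ({exc})")
    return records


def write_crowns(crowns: Sequence[CrownRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "crown_id": [c.crown_id for c in crowns],
            "x_pos": [c.x_pos for c in crowns],
            "y_pos": [c.y_pos for c in crowns],
            "area_m2": [c.area_m2 for c in crowns],
            "plot_id": [c.plot_id for c in crowns],
        }
    ).to_csv(path, index=False)


def read_pixel_table(path: str | Path) -> list[PixelObservation]:
    """Read per-pixel crown observations from CSV.

    Required columns are ``crown_id`` and ``height_m``; every other column,
    in file order, is treated as one reflectance band.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["crown_id", "height_m"], path)
    band_cols = [c for c in df.columns if c not in ("crown_id", "height_m")]
    if not band_cols:
        raise ValueError(f"{path.name}: no reflectance columns found")
    records: list[PixelObservation] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2
        try:
            records.append(
                PixelObservation(
                    crown_id=str(row["crown_id"]),
                    height_m=float(row["height_m"]),
                    reflectances=row[band_cols].to_numpy(dtype=float),
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.warn(f"{path.name} row {rowno}: rejected pixel row ({exc})")
    return records


def write_pixel_table(pixels: Sequence[PixelObservation], path: str | Path) -> None:
    if not pixels:
        raise ValueError("cannot write an empty pixel table")
    n_bands = pixels[0].reflectances.size
    data = {
        "crown_id": [p.crown_id for p in pixels],
        "height_m": [p.height_m for p in pixels],
    }
    refl = np.vstack([p.reflectances for p in pixels])
    for b in range(n_bands):
        data[f"refl_{b + 1:04d}"] = refl[:, b]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Crown polygon I/O (GeoJSON)
# ---------------------------------------------------------------------------


def write_crown_polygons(polygons: Sequence[CrownPolygon], path: str | Path) -> None:
    """Write crown polygons to a GeoJSON FeatureCollection.

    A ``.shp`` extension is rejected: no shapefile driver is available, and
    GeoJSON is the supported vector format.
    """
    path = Path(path)
    if path.suffix.lower() == ".shp":
        raise ValueError(
            "shapefile output is not supported; use a .geojson/.json path"
        )
    features = []
    for p in polygons:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(v) for v in p.boundary]],
                },
                "properties": {
                    "crown_id": p.crown_id,
                    "area_m2": p.area_m2,
                    "apex_x": p.apex[0],
                    "apex_y": p.apex[1],
                },
            }
        )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_crown_polygons(path: str | Path) -> list[CrownPolygon]:
    """Read crown polygons back from a GeoJSON FeatureCollection."""
    data = json.loads(Path(path).read_text())
    polygons: list[CrownPolygon] = []
    for feat in data.get("features", []):
        props = feat["properties"]
        ring = [tuple(v) for v in feat["geometry"]["coordinates"][0]]
        polygons.append(
            CrownPolygon(
                crown_id=str(props["crown_id"]),
                boundary=ring,
                apex=(float(props["apex_x"]), float(props["apex_y"])),
                area_m2=float(props["area_m2"]),
            )
        )
    return polygons


def write_label_raster(
    labels: np.ndarray,
    origin: tuple[float, float],
    pixel_size: float,
    path: str | Path,
    crs_label: str = "",
) -> None:
    """Write an integer label grid as a georeferenced single-band GeoTIFF."""
    desc = json.dumps({"crs_label": crs_label})
    tifffile.imwrite(
        str(path),
        np.asarray(labels, dtype=np.int32),
        photometric="minisblack",
        description=desc,
        extratags=_geo_extratags(origin, pixel_size),
    )


def read_label_raster(
    path: str | Path,
) -> tuple[np.ndarray, tuple[float, float], float, str]:
    """Read an integer label grid; returns (labels, origin, pixel_size, crs)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        origin, pixel_size, desc, _ = _read_geo_tags(tif.pages[0])
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D label raster, got ndim={arr.ndim}")
    return (
        arr.astype(int),
        origin,
        pixel_size,
        str(desc.get("crs_label", "")),
    )


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top-level YAML structure must be a mapping")
    return data
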