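"""Individual tree crown delineation from a CHM plus a hyperspectral cube.

The stage runs in four steps:

1. NDVI is computed from the red and near-infrared bands of the cube and
   combined with a minimum canopy height into a vegetation mask, which
   removes ground cover while retaining canopy material.
2. Treetops are located as local height maxima of the masked CHM, using a
   search window whose radius grows linearly with canopy height
   (``radius = slope * height + intercept``): taller trees have wider
   crowns, so a taller pixel must dominate a wider neighbourhood to count
   as an apex.  Maxima below a minimum apex height are ignored.
3. A marker-controlled watershed floods the inverted CHM outward from the
   treetops, restricted to masked pixels above a (lower) crown-edge height
   floor, yielding one labelled crown per treetop.
4. Each labelled pixel set is traced into a vector polygon in projected
   coordinates.

Tie rules (plateau maxima, watershed ridges) are deterministic and stated
on each function; tests hold the implementation to independent brute-force
oracles under exactly these rules.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

from .io_core import CanopyHeightModel, CrownPolygon, SpectralCube, band_nearest

__all__ = [
    "SegmentationConfig",
    "TreeTop",
    "CrownLabelGrid",
    "compute_ndvi",
    "vegetation_mask",
    "window_radius",
    "find_treetops",
    "watershed_crowns",
    "polygonize",
    "segment_scene",
]

RED_NM_DEFAULT = 628.1
NIR_NM_DEFAULT = 728.3


@dataclass
class SegmentationConfig:
    """Tunables of the crown delineation stage.

    Attributes
    ----------
    ndvi_min:
        Minimum NDVI for a pixel to count as vegetation (default 0.5).
    top_min_height_m:
        Minimum canopy height for a treetop, m (default 5): maxima below
        this are ignored.
    crown_min_height_m:
        Minimum canopy height for a crown-edge pixel, m (default 3): crown
        edges may extend below the apex threshold but not below this floor.
    window_slope, window_intercept:
        Coefficients of the linear variable-window rule
        ``radius_m = window_slope * height_m + window_intercept``
        (defaults 0.25 and 1.2).
    """

    ndvi_min: float = 0.5
    top_min_height_m: float = 5.0
    crown_min_height_m: float = 3.0
    window_slope: float = 0.25
    window_intercept: float = 1.2

    def __post_init__(self) -> None:
        if not -1.0 < self.ndvi_min < 1.0:
            raise ValueError(f"ndvi_min must lie in (-1, 1), got {self.ndvi_min}")
        if not 0 < self.crown_min_height_m <= self.top_min_height_m:
            raise ValueError(
                "need 0 < crown_min_height_m <= top_min_height_m, got "
                f"{self.crown_min_height_m} and {self.top_min_height_m}"
            )
        if self.window_intercept <= 0 or self.window_slope < 0:
            raise ValueError(
                "window radius must be positive for all heights >= 0"
            )


@dataclass
class TreeTop:
    """A detected local maximum of the masked CHM (presumptive tree apex)."""

    row: int
    col: int
    height_m: float
    apex_xy: tuple[float, float]


@dataclass
class CrownLabelGrid:
    """Integer crown segmentation raster.

    ``labels[r, c] == 0`` means unassigned; ``k >= 1`` means the pixel
    belongs to the crown of ``treetops[k - 1]``.  A grid whose apexes are
    unknown (e.g. a hand-drawn reference segmentation) carries
    ``treetops=None``.
    """

    labels: np.ndarray
    treetops: list[TreeTop] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.treetops is not None:
            if self.labels.size and self.labels.max(initial=0) > len(self.treetops):
                raise ValueError("label exceeds the number of treetops")
            for k, top in enumerate(self.treetops, start=1):
                if self.labels[top.row, top.col] != k:
                    raise ValueError(
                        f"treetop {k} pixel ({top.row}, {top.col}) does not "
                        f"carry label {k}"
                    )

    @property
    def n_crowns(self) -> int:
        if self.treetops is not None:
            return len(self.treetops)
        return int(self.labels.max(initial=0))


def compute_ndvi(
    cube: SpectralCube,
    red_nm: float = RED_NM_DEFAULT,
    nir_nm: float = NIR_NM_DEFAULT,
) -> np.ndarray:
    """Per-pixel normalized difference vegetation index.

    NDVI = (NIR - RED) / (NIR + RED), with the red and near-infrared bands
    chosen by nearest centre wavelength.  Pixels where the denominator is
    zero or either band is NaN are NaN.
    """
    red = cube.reflectance[band_nearest(cube, red_nm)]
    nir = cube.reflectance[band_nearest(cube, nir_nm)]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
    ndvi[~np.isfinite(ndvi)] = np.nan
    return ndvi


def vegetation_mask(
    chm: CanopyHeightModel, ndvi: np.ndarray, cfg: SegmentationConfig
) -> np.ndarray:
    """Boolean mask of canopy pixels: NDVI and height thresholds, inclusive.

    True exactly where ``ndvi >= ndvi_min`` and ``height >=
    crown_min_height_m`` and both values are finite.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    if ndvi.shape != chm.shape:
        raise ValueError(f"NDVI grid {ndvi.shape} does not match CHM {chm.shape}")
    h = chm.heights
    with np.errstate(invalid="ignore"):
        return (
            np.isfinite(ndvi)
            & np.isfinite(h)
            & (ndvi >= cfg.ndvi_min)
            & (h >= cfg.crown_min_height_m)
        )


def window_radius(height_m: float, cfg: SegmentationConfig) -> float:
    """Search-window radius (m) for the local-maximum test at a given height."""
    if height_m < 0:
        raise ValueError(f"height must be >= 0, got {height_m}")
    return cfg.window_slope * height_m + cfg.window_intercept


def find_treetops(
    chm: CanopyHeightModel, mask: np.ndarray, cfg: SegmentationConfig
) -> list[TreeTop]:
    """Locate treetops as variable-window local maxima of the masked CHM.

    A masked pixel ``p`` of height ``h >= top_min_height_m`` is a treetop
    iff, among masked pixels whose centres lie within Euclidean distance
    ``window_radius(h)`` (inclusive) of ``p``'s centre, none is strictly
    higher and no equal-height pixel precedes ``p`` in row-major order.
    The tie rule guarantees exactly one top per flat plateau.

    Returned sorted by descending height, then row-major position.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != chm.shape:
        raise ValueError(f"mask {mask.shape} does not match CHM {chm.shape}")
    h = chm.heights
    s = chm.pixel_size
    n_rows, n_cols = chm.shape
    with np.errstate(invalid="ignore"):
        cand = mask & np.isfinite(h) & (h >= cfg.top_min_height_m)
    tops: list[TreeTop] = []
    for r, c in zip(*np.nonzero(cand)):
        radius = window_radius(float(h[r, c]), cfg)
        reach = int(np.floor(radius / s))
        r0, r1 = max(0, r - reach), min(n_rows, r + reach + 1)
        c0, c1 = max(0, c - reach), min(n_cols, c + reach + 1)
        sub = h[r0:r1, c0:c1]
        sub_mask = mask[r0:r1, c0:c1] & np.isfinite(sub)
        dr = (np.arange(r0, r1) - r)[:, None] * s
        dc = (np.arange(c0, c1) - c)[None, :] * s
        in_window = sub_mask & (dr**2 + dc**2 <= radius**2)
        if np.any(in_window & (sub > h[r, c])):
            continue
        equal = in_window & (sub == h[r, c])
        rows_eq, cols_eq = np.nonzero(equal)
        order_self = r * n_cols + c
        if np.any((rows_eq + r0) * n_cols + (cols_eq + c0) < order_self):
            continue
        tops.append(
            TreeTop(
                row=int(r),
                col=int(c),
                height_m=float(h[r, c]),
                apex_xy=chm.pixel_center(int(r), int(c)),
            )
        )
    tops.sort(key=lambda t: (-t.height_m, t.row, t.col))
    return tops


_NEIGHBOURS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def watershed_crowns(
    chm: CanopyHeightModel,
    mask: np.ndarray,
    tops: list[TreeTop],
    cfg: SegmentationConfig,
) -> CrownLabelGrid:
    """Marker-controlled watershed of the inverted CHM around the treetops.

    Flooding proceeds over the retained pixels (masked, finite, height at
    least ``crown_min_height_m``) by descending height with 4-connectivity;
    on equal heights, pixels discovered earlier are flooded first, so ridge
    ties go to the marker flooded first (markers are seeded in the given
    order, which is descending apex height when ``tops`` comes from
    :func:`find_treetops`).  Every retained pixel 4-connected to a marker
    receives exactly one label; all other pixels stay 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != chm.shape:
        raise ValueError(f"mask {mask.shape} does not match CHM {chm.shape}")
    h = chm.heights
    with np.errstate(invalid="ignore"):
        retained = mask & np.isfinite(h) & (h >= cfg.crown_min_height_m)
    labels = np.zeros(chm.shape, dtype=int)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for k, top in enumerate(tops, start=1):
        if not mask[top.row, top.col]:
            raise ValueError(
                f"treetop {k} at ({top.row}, {top.col}) is not on a masked pixel"
            )
        labels[top.row, top.col] = k
        heapq.heappush(heap, (-float(h[top.row, top.col]), counter, top.row, top.col))
        counter += 1
    n_rows, n_cols = chm.shape
    while heap:
        _, _, r, c = heapq.heappop(heap)
        lab = labels[r, c]
        for dr, dc in _NEIGHBOURS_4:
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols:
                if retained[nr, nc] and labels[nr, nc] == 0:
                    labels[nr, nc] = lab
                    heapq.heappush(heap, (-float(h[nr, nc]), counter, nr, nc))
                    counter += 1
    return CrownLabelGrid(labels=labels, treetops=list(tops))


def polygonize(
    labels: CrownLabelGrid, chm: CanopyHeightModel
) -> list[CrownPolygon]:
    """Trace each crown label into a vector polygon in projected metres.

    The polygon is the outer boundary of the union of the label's pixel
    squares (collinear vertices removed); its area is the pixel count times
    the pixel area, and its apex is the treetop's pixel centre.
    """
    if labels.treetops is None:
        raise ValueError("polygonize requires a label grid with known treetops")
    ox, oy = chm.origin
    s = chm.pixel_size
    polygons: list[CrownPolygon] = []
    for k, top in enumerate(labels.treetops, start=1):
        rows, cols = np.nonzero(labels.labels == k)
        if rows.size == 0:
            continue
        cells = [
            box(ox + c * s, oy - (r + 1) * s, ox + (c + 1) * s, oy - r * s)
            for r, c in zip(rows, cols)
        ]
        merged = unary_union(cells).simplify(0)
        if merged.geom_type != "Polygon":
            raise ValueError(
                f"label {k} pixels do not form a single connected region"
            )
        ring = [(float(x), float(y)) for x, y in merged.exterior.coords]
        polygons.append(
            CrownPolygon(
                crown_id=f"C{k:04d}",
                boundary=ring,
                apex=top.apex_xy,
                area_m2=float(rows.size) * s * s,
            )
        )
    return polygons


def segment_scene(
    chm: CanopyHeightModel,
    cube: SpectralCube,
    cfg: SegmentationConfig | None = None,
) -> tuple[CrownLabelGrid, list[CrownPolygon]]:
    """Run the full delineation stage: NDVI mask, treetops, watershed, polygons."""
    cfg = cfg or SegmentationConfig()
    cube.check_coregistered(chm)
    ndvi = compute_ndvi(cube)
    mask = vegetation_mask(chm, ndvi, cfg)
    tops = find_treetops(chm, mask, cfg)
    grid = watershed_crowns(chm, mask, tops, cfg)
    return grid, polygonize(grid, chm)
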