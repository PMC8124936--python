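"""Raster primitives: radiometric correction, vegetation indices, zonal summaries.

The grid model is deliberately minimal: a 2-D array of per-pixel values, a
boolean nodata mask, and a north-up affine georeference (top-left origin,
square pixels).  Cell membership in an areal unit is decided by the cell
*center* falling inside the unit polygon, the convention of common
zonal-statistics tools.  Nodata propagates through every arithmetic step;
division by zero yields nodata, never infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

__all__ = [
    "GridTransform",
    "BandGrid",
    "IndexGrid",
    "ClassGrid",
    "ZonalSummary",
    "toa_reflectance",
    "dark_object_subtract",
    "compute_index",
    "mask_non_vegetation",
    "zonal_mean",
    "percent_cover",
    "INDEX_NAMES",
]

INDEX_NAMES = ("NDVI", "EVI", "SAVI")

#: soil-brightness adjustment for SAVI (USGS Landsat-8 formulation)
SAVI_L = 0.5
#: EVI gain and band coefficients (USGS Landsat-8 formulation)
EVI_G, EVI_C1, EVI_C2, EVI_L = 2.5, 6.0, 7.5, 1.0


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference with square pixels.

    ``x0, y0`` locate the outer corner of the top-left pixel; x grows with
    columns, y shrinks with rows (image convention).
    """

    x0: float = 0.0
    y0: float = 0.0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates for every cell of a grid."""
        rows, cols = shape
        xs = self.x0 + (np.arange(cols) + 0.5) * self.pixel_size
        ys = self.y0 - (np.arange(rows) + 0.5) * self.pixel_size
        xx, yy = np.meshgrid(xs, ys)
        return xx, yy


@dataclass
class _Grid:
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]


@dataclass
class BandGrid(_Grid):
    """Single spectral band, raw digital numbers or reflectance."""

    band_label: str = "other"


@dataclass
class IndexGrid(_Grid):
    """A computed vegetation-index surface (NDVI, EVI or SAVI)."""

    index_name: str = "NDVI"


@dataclass
class ClassGrid:
    """Integer land-cover labels plus a legend mapping label -> class name."""

    values: np.ndarray
    legend: dict[int, str]
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        labels = np.unique(self.values[~self.nodata_mask])
        unknown = [int(v) for v in labels if int(v) not in self.legend]
        if unknown:
            raise ValueError(f"class labels {unknown} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ZonalSummary:
    """Per-unit summary statistic; missing units carry NaN, never silent zero."""

    measure: str
    values: dict[str, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"unit_id": list(self.values), "measure": self.measure,
             "value": list(self.values.values())}
        )


def _check_same_shape(*grids: _Grid) -> None:
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError(f"grids are not co-registered: shapes {sorted(shapes)}")


def toa_reflectance(dn: BandGrid, mult_factor: float, add_factor: float,
                    sun_elevation_deg: float) -> BandGrid:
    """Rescale digital numbers to top-of-atmosphere reflectance.

    Applies the gain/offset rescaling and corrects for the solar elevation
    angle: ``rho = (M * DN + A) / sin(elev)``.
    """
    if not 0 < sun_elevation_deg <= 90:
        raise ValueError(
            f"sun_elevation_deg must lie in (0, 90], got {sun_elevation_deg}")
    rho = (mult_factor * dn.values + add_factor) / np.sin(
        np.deg2rad(sun_elevation_deg))
    rho = np.where(dn.nodata_mask, np.nan, rho)
    return BandGrid(rho, dn.nodata_mask.copy(), dn.transform, dn.band_label)


def dark_object_subtract(band: BandGrid) -> BandGrid:
    """Haze correction: subtract the darkest valid pixel from every pixel.

    The output minimum over valid cells is exactly zero; relative differences
    are preserved, and the operation is idempotent.
    """
    valid = ~band.nodata_mask
    if not valid.any():
        raise ValueError("dark_object_subtract: grid has no valid cells")
    dark = band.values[valid].min()
    out = np.where(valid, band.values - dark, np.nan)
    return BandGrid(out, band.nodata_mask.copy(), band.transform, band.band_label)


def compute_index(red: BandGrid, nir: BandGrid, blue: BandGrid | None = None,
                  index_name: str = "NDVI", *, savi_l: float = SAVI_L,
                  evi_g: float = EVI_G, evi_c1: float = EVI_C1,
                  evi_c2: float = EVI_C2, evi_l: float = EVI_L) -> IndexGrid:
    """Compute NDVI, SAVI or EVI from co-registered reflectance bands.

    NDVI = (NIR-R)/(NIR+R); SAVI = (1+L)(NIR-R)/(NIR+R+L) with L=0.5;
    EVI = G(NIR-R)/(NIR + C1 R - C2 B + 1) with G=2.5, C1=6, C2=7.5.
    Constants are configurable; defaults follow the USGS Landsat-8 products.
    Zero-denominator cells become nodata.
    """
    if index_name not in INDEX_NAMES:
        raise ValueError(f"index_name must be one of {INDEX_NAMES}")
    if index_name == "EVI":
        if blue is None:
            raise ValueError("EVI requires a blue band")
        _check_same_shape(red, nir, blue)
    else:
        _check_same_shape(red, nir)

    r, n = red.values, nir.values
    num = n - r
    if index_name == "NDVI":
        den = n + r
        vals = num
    elif index_name == "SAVI":
        den = n + r + savi_l
        vals = (1.0 + savi_l) * num
    else:  # EVI
        den = n + evi_c1 * r - evi_c2 * blue.values + evi_l
        vals = evi_g * num

    mask = red.nodata_mask | nir.nodata_mask
    if index_name == "EVI":
        mask = mask | blue.nodata_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vals / den
    mask = mask | (den == 0) | ~np.isfinite(out)
    out = np.where(mask, np.nan, out)
    return IndexGrid(out, mask, red.transform, index_name)


def mask_non_vegetation(index: IndexGrid, ndvi: IndexGrid,
                        threshold: float = 0.0) -> IndexGrid:
    """Mask cells whose NDVI <= threshold (water, soil, built surfaces).

    Cells already nodata in the NDVI surface are masked as well; everything
    else passes through unchanged.
    """
    _check_same_shape(index, ndvi)
    low = (~ndvi.nodata_mask) & (ndvi.values <= threshold)
    mask = index.nodata_mask | ndvi.nodata_mask | low
    out = np.where(mask, np.nan, index.values)
    return IndexGrid(out, mask, index.transform, index.index_name)


def _membership(transform: GridTransform, shape: tuple[int, int], units) -> dict[str, np.ndarray]:
    """Boolean cell-membership (by cell center) per areal unit."""
    xx, yy = transform.cell_centers(shape)
    flat_x, flat_y = xx.ravel(), yy.ravel()
    out: dict[str, np.ndarray] = {}
    for uid, geom in zip(units.unit_ids, units.geometries):
        inside = shapely.contains_xy(geom, flat_x, flat_y)
        out[uid] = inside.reshape(shape)
    return out


def zonal_mean(index: IndexGrid, zones) -> ZonalSummary:
    """Arithmetic mean of valid index cells whose centers fall in each unit.

    Units with zero usable cells are flagged missing (NaN).  Raises if no
    unit intersects the grid at all.
    """
    members = _membership(index.transform, index.shape, zones)
    valid = ~index.nodata_mask
    values: dict[str, float] = {}
    any_cells = False
    for uid, inside in members.items():
        if inside.any():
            any_cells = True
        use = inside & valid
        values[uid] = float(index.values[use].mean()) if use.any() else float("nan")
    if not any_cells:
        raise ValueError("no areal unit intersects the raster extent")
    return ZonalSummary(measure=index.index_name, values=values)


def percent_cover(classes: ClassGrid, zones, target_class: str) -> ZonalSummary:
    """Percent of valid cells per unit carrying the target land-cover class."""
    inverse = {name: lab for lab, name in classes.legend.items()}
    if target_class not in inverse:
        raise ValueError(
            f"unknown class {target_class!r}; legend has {sorted(inverse)}")
    target = inverse[target_class]
    members = _membership(classes.transform, classes.shape, zones)
    valid = ~classes.nodata_mask
    values: dict[str, float] = {}
    for uid, inside in members.items():
        use = inside & valid
        total = int(use.sum())
        if total == 0:
            values[uid] = float("nan")
        else:
            values[uid] = 100.0 * float((classes.values[use] == target).sum()) / total
    return ZonalSummary(measure=f"pct_{target_class}", values=values)
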