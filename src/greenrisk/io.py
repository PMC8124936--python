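"""File formats: GeoJSON polygons, TIFF rasters, neighbor lists, CSV tables.

Rasters are written as plain TIFF (pixels) with a JSON sidecar carrying the
affine georeference and band label, so a raster round-trips without any GIS
stack.  Adjacency round-trips through a plain-text neighbor-list format
(``unit_id: n1 n2 ...``) so model runs are reproducible without geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .raster import BandGrid, GridTransform, IndexGrid, ZonalSummary
from .spatial import AreaUnitSet, WeightMatrix

__all__ = [
    "write_geojson", "read_geojson",
    "write_neighbors", "read_neighbors",
    "write_raster", "read_raster",
    "write_zonal_csv", "read_zonal_csv",
    "read_health_csv", "write_health_csv",
    "read_covariates_csv", "write_covariates_csv",
    "read_model_csv",
]


def write_geojson(units: AreaUnitSet, path: str | Path,
                  properties: pd.DataFrame | None = None) -> None:
    """Write units (and optional per-unit properties keyed by unit_id)."""
    props = {}
    if properties is not None:
        df = properties.set_index("unit_id") if "unit_id" in properties.columns \
            else properties
        props = df.to_dict(orient="index")
    features = []
    for uid, geom in zip(units.unit_ids, units.geometries):
        feat_props = {"unit_id": uid, **props.get(uid, {})}
        features.append({"type": "Feature", "properties": feat_props,
                         "geometry": mapping(geom)})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def read_geojson(path: str | Path) -> AreaUnitSet:
    data = json.loads(Path(path).read_text())
    ids, geoms = [], []
    for feat in data["features"]:
        ids.append(str(feat["properties"]["unit_id"]))
        geoms.append(shape(feat["geometry"]))
    return AreaUnitSet(unit_ids=ids, geometries=geoms)


def write_neighbors(units: AreaUnitSet, path: str | Path) -> None:
    if units.neighbors is None:
        raise ValueError("adjacency not built; nothing to write")
    lines = [f"{uid}: {' '.join(units.neighbors[uid])}"
             for uid in units.unit_ids]
    Path(path).write_text("\n".join(lines) + "\n")


def read_neighbors(path: str | Path) -> dict[str, list[str]]:
    neighbors: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        uid, _, rest = line.partition(":")
        neighbors[uid.strip()] = rest.split()
    ids = set(neighbors)
    for uid, nbrs in neighbors.items():
        for v in nbrs:
            if v not in ids:
                raise ValueError(f"neighbor {v!r} of {uid!r} has no own entry")
            if uid not in neighbors[v]:
                raise ValueError(f"asymmetric adjacency: {uid} -> {v}")
    return neighbors


def weights_from_neighbors(neighbors: dict[str, list[str]]) -> WeightMatrix:
    import scipy.sparse as sp

    ids = list(neighbors)
    idx = {u: i for i, u in enumerate(ids)}
    rows = [idx[u] for u, ns in neighbors.items() for _ in ns]
    cols = [idx[v] for ns in neighbors.values() for v in ns]
    w = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(len(ids), len(ids)))
    return WeightMatrix(w, style="binary", unit_ids=ids)


def write_raster(grid: BandGrid | IndexGrid, path: str | Path) -> None:
    """TIFF pixels (NaN = nodata) plus a .json sidecar for georeference."""
    import tifffile

    path = Path(path)
    vals = np.where(grid.nodata_mask, np.nan, grid.values).astype("float32")
    tifffile.imwrite(path, vals)
    meta = {
        "x0": grid.transform.x0, "y0": grid.transform.y0,
        "pixel_size": grid.transform.pixel_size,
        "kind": "index" if isinstance(grid, IndexGrid) else "band",
        "label": grid.index_name if isinstance(grid, IndexGrid)
        else grid.band_label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> BandGrid | IndexGrid:
    import tifffile

    path = Path(path)
    vals = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    tfm = GridTransform(meta.get("x0", 0.0), meta.get("y0", 0.0),
                        meta.get("pixel_size", 1.0))
    mask = ~np.isfinite(vals)
    if meta.get("kind") == "index":
        return IndexGrid(vals, mask, tfm, meta.get("label", "NDVI"))
    return BandGrid(vals, mask, tfm, meta.get("label", "other"))


def write_zonal_csv(summary: ZonalSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, index=False)


def read_zonal_csv(path: str | Path) -> ZonalSummary:
    df = pd.read_csv(path, dtype={"unit_id": str})
    measures = df["measure"].unique()
    if len(measures) != 1:
        raise ValueError(f"expected a single measure, found {list(measures)}")
    return ZonalSummary(measure=measures[0],
                        values=dict(zip(df["unit_id"], df["value"])))


def read_health_csv(path: str | Path) -> pd.DataFrame:
    from .standardize import validate_health_table

    return validate_health_table(pd.read_csv(path, dtype={"unit_id": str}))


def write_health_csv(health: pd.DataFrame, path: str | Path) -> None:
    health.to_csv(path, index=False)


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str}).set_index("unit_id")
    return df


def write_covariates_csv(cov: pd.DataFrame, path: str | Path) -> None:
    out = cov.copy()
    out.insert(0, "measure", out.attrs.get("measure", ""))
    out.to_csv(path)


def read_model_csv(path: str | Path, neighbors_path: str | Path):
    """Assemble ModelData from a unit_id,O,E,X1..X6 CSV and a neighbor list."""
    from .bym import ModelData

    df = pd.read_csv(path, dtype={"unit_id": str}).set_index("unit_id")
    neighbors = read_neighbors(neighbors_path)
    ids = list(neighbors)
    if set(ids) != set(df.index):
        raise ValueError("unit ids differ between model CSV and neighbor list")
    df = df.loc[ids]
    xcols = [c for c in df.columns if c.startswith("X")]
    wm = weights_from_neighbors(neighbors)
    return ModelData(df["O"].to_numpy(), df["E"].to_numpy(),
                     df[xcols].to_numpy(), wm, unit_ids=ids)
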