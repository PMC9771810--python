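"""File I/O: rasters (TIFF), GeoJSON polygons, CSV tables, HURDAT2 text.

Rasters travel as plain TIFF with an optional JSON sidecar for grid
metadata; class-code rasters use uint8 with codes 0 stable, 1 loss,
2 gain, 3 recovered, 255 no-data.  Polygons travel as GeoJSON
FeatureCollections.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape


def write_raster(path, array: np.ndarray, metadata: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array))
    if metadata:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata))


def read_raster(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_class_raster(path, classes: np.ndarray, metadata: dict | None = None) -> None:
    write_raster(path, classes.astype(np.uint8), metadata)


def write_geojson(path, polygons: dict[int, Polygon]) -> None:
    features = [
        {"type": "Feature", "properties": {"id": int(k)},
         "geometry": mapping(poly)}
        for k, poly in polygons.items()
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def read_geojson(path) -> dict[int, Polygon]:
    data = json.loads(Path(path).read_text())
    return {int(f["properties"]["id"]): shape(f["geometry"])
            for f in data["features"]}


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(Path(path), index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
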