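"""Readers and writers for the pipeline's interchange formats.

Rasters travel as TIFF with band names, affine transform and nodata
recorded as JSON in the image-description tag; tables as tidy CSV; fire
records as GeoJSON; fitted ensembles as JSON trees.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .boosting import BoostedEnsemble, GBTConfig, RegressionTree, _Node
from .core import Scene, SegmentMap, region_adjacency
from .features.objects import feature_group


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_scene(path, scene: Scene) -> None:
    names = scene.band_names
    stack = scene.stack(names).astype(np.float32)
    meta = {
        "bands": list(names),
        "transform": list(scene.transform),
        "nodata": "mask" if scene.nodata_mask.any() else None,
    }
    data = stack
    if scene.nodata_mask.any():
        data = np.concatenate(
            [stack, scene.nodata_mask[None].astype(np.float32)], axis=0
        )
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_scene(path) -> Scene:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    names = meta["bands"]
    nodata = None
    if meta.get("nodata") == "mask":
        nodata = data[-1].astype(bool)
        data = data[: len(names)]
    bands = {n: data[i].astype(float) for i, n in enumerate(names)}
    return Scene(
        bands=bands, transform=tuple(meta["transform"]), nodata_mask=nodata
    )


def write_raster(path, array: np.ndarray, transform=None) -> None:
    meta = {"transform": list(transform) if transform else None}
    tifffile.imwrite(path, np.asarray(array), description=json.dumps(meta))


def read_raster(path) -> np.ndarray:
    return tifffile.imread(path)


def write_segment_map(path, segment_map: SegmentMap, transform=None) -> None:
    write_raster(path, segment_map.labels.astype(np.int32), transform)


def read_segment_map(path) -> SegmentMap:
    labels = read_raster(path).astype(np.int32)
    return SegmentMap(
        labels=labels,
        n_objects=int(labels.max()),
        adjacency=region_adjacency(labels),
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_feature_table(path, table: pd.DataFrame) -> None:
    """Feature CSV plus a JSON manifest mapping feature name -> group."""
    path = Path(path)
    table.to_csv(path)
    manifest = {
        c: feature_group(c) for c in table.columns if c != "label"
    }
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="object_id")


def write_fire_geojson(path, records: pd.DataFrame) -> None:
    feats = []
    for _, r in records.iterrows():
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(r.get("x", 0.0)), float(r.get("y", 0.0))],
                },
                "properties": {
                    "object_id": int(r["object_id"]),
                    "date": str(r["date"]),
                    "year": int(r["year"]),
                    "area_ha": float(r["area_ha"]),
                    "duration_days": float(r["duration_days"]),
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def read_fire_geojson(path) -> pd.DataFrame:
    doc = json.loads(Path(path).read_text())
    rows = [f["properties"] for f in doc["features"]]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["object_id", "date", "year", "area_ha", "duration_days"]
        )
    return df


# ---------------------------------------------------------------------------
# fitted ensembles
# ---------------------------------------------------------------------------

def _node_to_dict(node: _Node) -> dict:
    if node.is_leaf:
        return {"value": node.value}
    d = {
        "feature": int(node.feature),
        "gain": node.gain,
        "default_left": node.default_left,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }
    if node.left_cats is not None:
        d["left_cats"] = sorted(node.left_cats)
        d["right_cats"] = sorted(getattr(node, "_right_cats", []))
    else:
        d["threshold"] = node.threshold
    return d


def _node_from_dict(d: dict) -> _Node:
    if "feature" not in d:
        return _Node(value=d["value"])
    node = _Node(
        feature=d["feature"],
        gain=d.get("gain", 0.0),
        default_left=d.get("default_left", True),
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )
    if "left_cats" in d:
        node.left_cats = frozenset(d["left_cats"])
        node._right_cats = list(d.get("right_cats", []))
        node.threshold = math.nan
    else:
        node.threshold = d["threshold"]
    return node


def write_model(path, model: BoostedEnsemble) -> None:
    doc = {
        "f0": model.f0,
        "learning_rate": model.learning_rate,
        "n_trees_optimal": model.n_trees_optimal,
        "feature_names": list(model.feature_names),
        "categorical_features": sorted(model.categorical_features),
        "trees": [
            None if t is None else {"n_leaves": t.n_leaves, "root": _node_to_dict(t.root)}
            for t in model.trees
        ],
        "per_iteration": model.per_iteration.to_dict(orient="list"),
        "config": None if model.config is None else vars(model.config),
    }
    Path(path).write_text(json.dumps(doc))


def read_model(path) -> BoostedEnsemble:
    doc = json.loads(Path(path).read_text())
    trees = [
        None
        if t is None
        else RegressionTree(root=_node_from_dict(t["root"]), n_leaves=t["n_leaves"])
        for t in doc["trees"]
    ]
    return BoostedEnsemble(
        f0=doc["f0"],
        trees=trees,
        learning_rate=doc["learning_rate"],
        n_trees_optimal=doc["n_trees_optimal"],
        per_iteration=pd.DataFrame(doc["per_iteration"]),
        feature_names=tuple(doc["feature_names"]),
        categorical_features=frozenset(doc["categorical_features"]),
        train_matrix=None,
        config=GBTConfig(**doc["config"]) if doc.get("config") else None,
    )
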