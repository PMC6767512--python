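"""Geometric features and assembly of the per-object feature table.

The full configuration yields 95 feature columns per object:

====================  =====================================================  ===
group                 columns                                                  n
====================  =====================================================  ===
spectral bands        mean/sd of Blue..SWIR2                                  12
spectral indices      mean/sd of the 11 index layers                          22
principal components  mean of PC1..PC6                                         6
texture               8 GLCM statistics x 6 bands                             48
geometric             area, compactness, asymmetry                             3
terrain               TWI/TPI/TRI means                                        3
ancillary             majority forest type                                     1
====================  =====================================================  ===

plus a ``label`` column (infested / healthy / unknown) carried alongside.
Standard deviations are population (divide by n) throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import BAND_NAMES, Scene, SegmentMap
from .spectral import INDEX_NAMES, SpectralIndexStack
from .texture import GLCM_STATS


def _per_object_mean_sd(
    layer: np.ndarray, labels: np.ndarray, n_obj: int
) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware per-object mean and population sd (index 0 unused)."""
    flat_l = labels.ravel()
    flat_v = layer.ravel()
    ok = (flat_l > 0) & np.isfinite(flat_v)
    n = np.bincount(flat_l[ok], minlength=n_obj + 1).astype(float)
    s = np.bincount(flat_l[ok], weights=flat_v[ok], minlength=n_obj + 1)
    s2 = np.bincount(flat_l[ok], weights=flat_v[ok] ** 2, minlength=n_obj + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / n, np.nan)
        var = np.where(n > 0, s2 / n - mean**2, np.nan)
    return mean, np.sqrt(np.maximum(var, 0.0))


def object_perimeters(labels: np.ndarray) -> np.ndarray:
    """Exposed pixel-edge counts per object (index 0 unused)."""
    n_obj = int(labels.max())
    perim = np.zeros(n_obj + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    for sl_a, sl_b in (
        ((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
        ((slice(None, -1), slice(None)), (slice(1, None), slice(None))),
    ):
        a, b = padded[sl_a], padded[sl_b]
        diff = a != b
        perim += np.bincount(a[diff & (a > 0)], minlength=n_obj + 1)
        perim += np.bincount(b[diff & (b > 0)], minlength=n_obj + 1)
    return perim


def compute_geometric_features(
    segment_map: SegmentMap, pixel_size: float = 30.0
) -> pd.DataFrame:
    """Area (map units), compactness and asymmetry per object.

    Compactness is perimeter / (4 * sqrt(pixel area)) — 1.0 for any
    square.  Asymmetry is 1 - minor/major axis ratio of the pixel
    coordinate covariance ellipse; a single pixel has asymmetry 0 by
    convention.
    """
    labels = segment_map.labels
    n_obj = segment_map.n_objects
    counts = np.bincount(labels.ravel(), minlength=n_obj + 1)
    perim = object_perimeters(labels)

    rr, cc = np.nonzero(labels > 0)
    ll = labels[rr, cc]
    sr = np.bincount(ll, weights=rr, minlength=n_obj + 1)
    sc = np.bincount(ll, weights=cc, minlength=n_obj + 1)
    srr = np.bincount(ll, weights=rr * rr.astype(float), minlength=n_obj + 1)
    scc = np.bincount(ll, weights=cc * cc.astype(float), minlength=n_obj + 1)
    src = np.bincount(ll, weights=rr * cc.astype(float), minlength=n_obj + 1)

    rows = []
    for o in range(1, n_obj + 1):
        n = counts[o]
        area = n * pixel_size**2
        compact = perim[o] / (4.0 * np.sqrt(n))
        mr, mc = sr[o] / n, sc[o] / n
        vrr = srr[o] / n - mr**2
        vcc = scc[o] / n - mc**2
        vrc = src[o] / n - mr * mc
        tr, det = vrr + vcc, vrr * vcc - vrc**2
        disc = max(tr**2 / 4.0 - det, 0.0)
        lam1 = tr / 2.0 + np.sqrt(disc)
        lam2 = max(tr / 2.0 - np.sqrt(disc), 0.0)
        asym = 0.0 if lam1 <= 0 else 1.0 - lam2 / lam1
        rows.append((o, area, compact, asym))
    df = pd.DataFrame(rows, columns=["object_id", "area", "compactness", "asymmetry"])
    return df.set_index("object_id")


def label_objects(
    segment_map: SegmentMap, label_raster: np.ndarray, threshold: float = 0.5
) -> pd.Series:
    """Assign infested/healthy to objects by majority of truth pixels.

    An object is "infested" when more than ``threshold`` of its pixels
    are marked infested (mirroring a >50% defoliation ground rule).
    """
    mean, _ = _per_object_mean_sd(
        label_raster.astype(float), segment_map.labels, segment_map.n_objects
    )
    ids = np.arange(1, segment_map.n_objects + 1)
    lab = np.where(mean[1:] > threshold, "infested", "healthy")
    return pd.Series(lab, index=pd.Index(ids, name="object_id"), name="label")


#: Feature-name prefix -> group used by the CSV manifest.
FEATURE_GROUPS = {
    "mean_": "spectral",
    "sd_": "spectral",
    "glcm_": "texture",
    "area": "geometric",
    "compactness": "geometric",
    "asymmetry": "geometric",
    "twi_mean": "ancillary",
    "tpi_mean": "ancillary",
    "tri_mean": "ancillary",
    "forest_type": "ancillary",
}


def feature_group(name: str) -> str:
    for prefix, group in FEATURE_GROUPS.items():
        if name == prefix or name.startswith(prefix):
            return group
    return "other"


def aggregate_objects(
    scene: Scene,
    index_stack: SpectralIndexStack,
    texture: dict[str, pd.DataFrame],
    geometric: pd.DataFrame,
    terrain: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    forest_type_raster: np.ndarray | None,
    segment_map: SegmentMap,
) -> pd.DataFrame:
    """Join all per-object statistics into one feature table.

    ``texture`` maps band name -> GLCM table.  Missing ancillary inputs
    simply drop their columns; with every input present the table has 95
    feature columns.  All rasters must share the scene grid.
    """
    labels = segment_map.labels
    if labels.shape != scene.shape:
        raise ValueError("segment map grid differs from scene grid")
    n_obj = segment_map.n_objects
    ids = pd.Index(np.arange(1, n_obj + 1), name="object_id")
    cols: dict[str, np.ndarray] = {}

    for name in BAND_NAMES:
        if name not in scene.bands:
            continue
        layer = np.where(scene.nodata_mask, np.nan, scene.bands[name])
        mean, sd = _per_object_mean_sd(layer, labels, n_obj)
        cols[f"mean_{name}"] = mean[1:]
        cols[f"sd_{name}"] = sd[1:]

    for name in INDEX_NAMES:
        if name not in index_stack.indices:
            continue
        mean, sd = _per_object_mean_sd(index_stack.indices[name], labels, n_obj)
        cols[f"mean_{name}"] = mean[1:]
        cols[f"sd_{name}"] = sd[1:]

    if index_stack.pc_scores is not None:
        for i in range(index_stack.pc_scores.shape[0]):
            mean, _ = _per_object_mean_sd(index_stack.pc_scores[i], labels, n_obj)
            cols[f"mean_PC{i + 1}"] = mean[1:]

    table = pd.DataFrame(cols, index=ids)

    for band, tdf in texture.items():
        renamed = tdf.rename(columns={s: f"glcm_{s}_{band}" for s in GLCM_STATS})
        if renamed.shape[0] != n_obj:
            raise ValueError(f"texture table for {band} does not cover all objects")
        table = table.join(renamed)

    table = table.join(geometric)

    if terrain is not None:
        for name, raster in zip(("twi", "tpi", "tri"), terrain):
            if raster.shape != labels.shape:
                raise ValueError(f"{name} raster grid differs from scene grid")
            mean, _ = _per_object_mean_sd(raster, labels, n_obj)
            table[f"{name}_mean"] = mean[1:]

    if forest_type_raster is not None:
        if forest_type_raster.shape != labels.shape:
            raise ValueError("forest type raster grid differs from scene grid")
        ft = np.zeros(n_obj, dtype=np.int64)
        flat_l, flat_f = labels.ravel(), forest_type_raster.ravel()
        frame = pd.DataFrame({"l": flat_l[flat_l > 0], "f": flat_f[flat_l > 0]})
        # majority, ties to the smallest category code
        maj = (
            frame.groupby(["l", "f"]).size().reset_index(name="n")
            .sort_values(["l", "n", "f"], ascending=[True, False, True])
            .drop_duplicates("l")
            .set_index("l")["f"]
        )
        ft = maj.reindex(np.arange(1, n_obj + 1)).to_numpy()
        table["forest_type"] = ft

    if table.columns.duplicated().any():
        raise ValueError("duplicate feature names in table")
    return table
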