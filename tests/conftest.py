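import numpy as np
import pandas as pd
import pytest

import geodefol as gd
from geodefol.core import Scene
from geodefol.features import (
    aggregate_objects,
    compute_geometric_features,
    compute_glcm_features,
    compute_pca,
    compute_spectral_indices,
    compute_terrain_features,
    label_objects,
)


@pytest.fixture(scope="session")
def small_scene():
    """64x64 synthetic scene with a handful of defoliated patches."""
    return gd.generate_scene(gd.SceneSpec(width=64, height=64, n_patches=4, seed=7))


@pytest.fixture(scope="session")
def small_segmentation(small_scene):
    scene, _, _ = small_scene
    return gd.segment(scene, gd.SegmentationConfig(scale=1.0))


@pytest.fixture(scope="session")
def labelled_feature_table(small_scene, small_segmentation):
    """Full 95-column feature table for the small scene."""
    scene, labels, ftype = small_scene
    sm = small_segmentation
    stack = compute_spectral_indices(scene)
    stack.pc_scores, stack.pc_loadings, stack.pc_variance_fraction = compute_pca(scene)
    texture = {
        b: compute_glcm_features(scene.bands[b], sm)
        for b in ("Blue", "Green", "Red", "NIR", "SWIR1", "SWIR2")
    }
    geometric = compute_geometric_features(sm)
    dem = gd.generate_dem(64, 64, 25.0, seed=8)
    terrain = compute_terrain_features(dem)
    table = aggregate_objects(scene, stack, texture, geometric, terrain, ftype, sm)
    table["label"] = label_objects(sm, labels)
    return table


@pytest.fixture(scope="session")
def default_panel():
    """Balanced N=19, T=8 panel with known coefficients."""
    tidy, panel, beta = gd.generate_climate_panel(gd.PanelSpec(seed=1))
    return tidy, panel, beta


def two_band_scene(values: np.ndarray) -> Scene:
    """Single-band helper scene (Red only) from a 2-D array."""
    return Scene(bands={"Red": np.asarray(values, dtype=float)})
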