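"""Spectral vegetation/water indices, tasseled-cap transforms and PCA.

All index formulas operate on surface reflectance in [0, 1].  Pixels with
an undefined value (zero denominator, nodata) are flagged NaN rather than
propagated as infinities.  The tasseled-cap brightness/greenness/wetness
use published Landsat-8 reflectance coefficients; the green vegetation
index (GVI) uses the Landsat-TM tasseled-cap greenness coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import BAND_NAMES, Scene

# Tasseled-cap coefficients, band order Blue..SWIR2.
# Landsat-8 OLI at-surface reflectance (Baig et al. 2014).
TC_BRIGHTNESS = np.array([0.3029, 0.2786, 0.4733, 0.5599, 0.5080, 0.1872])
TC_GREENNESS = np.array([-0.2941, -0.2430, -0.5424, 0.7276, 0.0713, -0.1608])
TC_WETNESS = np.array([0.1511, 0.1973, 0.3283, 0.3407, -0.7117, -0.4559])
# Landsat TM greenness (Crist & Cicone 1984) = classic GVI.
GVI_COEF = np.array([-0.2848, -0.2435, -0.5436, 0.7243, 0.0840, -0.1800])

#: Index layer names in canonical order.
INDEX_NAMES = (
    "NDVI",
    "NDWI",
    "GEMI",
    "IPVI",
    "ARVI",
    "EVI2",
    "GVI",
    "brightness",
    "greenness",
    "wetness",
    "max_diff",
)


@dataclass
class SpectralIndexStack:
    """Named 2-D index layers plus (optionally) principal components."""

    indices: dict[str, np.ndarray]
    pc_scores: np.ndarray | None = None  # (6, rows, cols), scaled to [0, 1]
    pc_loadings: np.ndarray | None = None  # rows = components, cols = bands
    pc_variance_fraction: np.ndarray | None = None

    def layers(self) -> dict[str, np.ndarray]:
        """All layers keyed by name (PCs as PC1..PC6 when present)."""
        out = dict(self.indices)
        if self.pc_scores is not None:
            for i in range(self.pc_scores.shape[0]):
                out[f"PC{i + 1}"] = self.pc_scores[i]
        return out


def _safe_div(num: np.ndarray, den: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = np.abs(den) > eps
    out[ok] = num[ok] / den[ok]
    return out


def compute_spectral_indices(scene: Scene) -> SpectralIndexStack:
    """Compute the eleven index layers used for object statistics.

    NDVI, IPVI and EVI2 contrast NIR against red; NDWI (Gao variant,
    NIR vs SWIR1) proxies canopy water content; ARVI corrects red with
    blue; GEMI is the nonlinear global environment monitoring index;
    GVI/brightness/greenness/wetness are fixed linear band combinations;
    max_diff is the per-pixel band range normalized by brightness.
    """
    required = {"Blue", "Red", "NIR", "SWIR1"}
    missing = required - set(scene.bands)
    if missing:
        raise ValueError(f"scene lacks required bands: {sorted(missing)}")

    nodata = scene.nodata_mask
    b = {k: np.where(nodata, np.nan, v.astype(float)) for k, v in scene.bands.items()}
    blue, red, nir, swir1 = b["Blue"], b["Red"], b["NIR"], b["SWIR1"]

    idx: dict[str, np.ndarray] = {}
    idx["NDVI"] = _safe_div(nir - red, nir + red)
    idx["NDWI"] = _safe_div(nir - swir1, nir + swir1)
    idx["IPVI"] = _safe_div(nir, nir + red)
    idx["EVI2"] = 2.5 * _safe_div(nir - red, nir + 2.4 * red + 1.0)
    idx["ARVI"] = _safe_div(nir - (2 * red - blue), nir + (2 * red - blue))
    eta = _safe_div(2 * (nir**2 - red**2) + 1.5 * nir + 0.5 * red, nir + red + 0.5)
    idx["GEMI"] = eta * (1 - 0.25 * eta) - _safe_div(red - 0.125, 1 - red)

    if all(n in scene.bands for n in BAND_NAMES):
        cube = np.stack([b[n] for n in BAND_NAMES])  # (6, h, w)
        idx["GVI"] = np.tensordot(GVI_COEF, cube, axes=1)
        bright = np.tensordot(TC_BRIGHTNESS, cube, axes=1)
        idx["brightness"] = bright
        idx["greenness"] = np.tensordot(TC_GREENNESS, cube, axes=1)
        idx["wetness"] = np.tensordot(TC_WETNESS, cube, axes=1)
        idx["max_diff"] = _safe_div(
            np.nanmax(cube, axis=0) - np.nanmin(cube, axis=0), bright
        )
    return SpectralIndexStack(indices=idx)


def compute_pca(
    scene: Scene, n_components: int = 6, rank_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components of the six-band pixel covariance.

    Returns ``(scores, loadings, variance_fractions)`` where scores are
    per-component min-max rescaled to [0, 1] over valid pixels (the scale
    on which partial-dependence thresholds like "PC2 above 0.70" are
    read), loadings rows are orthonormal eigenvectors with the
    largest-magnitude entry flipped positive, and variance fractions are
    eigenvalues over their sum.  Components beyond the numerical rank of
    the covariance are flagged NaN.
    """
    names = [n for n in BAND_NAMES if n in scene.bands]
    if len(names) < 2:
        raise ValueError("PCA needs at least two bands")
    cube = scene.stack(tuple(names))
    valid = ~scene.nodata_mask & np.isfinite(cube).all(axis=0)
    X = cube[:, valid].T  # (pixels, bands)
    if X.shape[0] < len(names):
        raise ValueError("not enough valid pixels for PCA")

    cov = np.cov(X, rowvar=False, bias=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]

    k = min(n_components, len(names))
    loadings = evecs[:, :k].T.copy()  # (k, bands)
    for i in range(k):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
    variance_fraction = evals[:k] / evals.sum() if evals.sum() > 0 else np.zeros(k)
    rank = int((evals > rank_tol * max(evals.max(), 1.0)).sum())

    centered = X - X.mean(axis=0)
    raw = centered @ loadings.T  # (pixels, k)
    scores = np.full((k,) + scene.shape, np.nan)
    for i in range(k):
        if i >= rank:
            continue  # beyond covariance rank: flagged missing
        s = raw[:, i]
        lo, hi = s.min(), s.max()
        plane = np.full(scene.shape, np.nan)
        plane[valid] = (s - lo) / (hi - lo) if hi > lo else 0.0
        scores[i] = plane
    return scores, loadings, variance_fraction
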