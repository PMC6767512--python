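"""Per-object gray-level co-occurrence (GLCM) texture statistics.

The co-occurrence matrix of an object counts quantized gray-level pairs
over pixel pairs that lie fully inside the object, accumulated over the
four distance-1 offsets (horizontal, vertical and both diagonals — "all
directions") and made symmetric by counting each pair in both orders.
Eight statistics are derived from the normalized matrix per object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import SegmentMap

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_STATS = (
    "homogeneity",
    "contrast",
    "dissimilarity",
    "entropy",
    "mean",
    "asm",
    "sd",
    "correlation",
)


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantization of a band to integer gray levels 0..levels-1."""
    finite = np.isfinite(band)
    out = np.zeros(band.shape, dtype=np.int64)
    if not finite.any():
        return out
    lo, hi = band[finite].min(), band[finite].max()
    if hi > lo:
        q = np.floor((band - lo) / (hi - lo) * levels)
        out[finite] = np.clip(q[finite], 0, levels - 1).astype(np.int64)
    return out


def compute_glcm_features(
    band: np.ndarray,
    segment_map: SegmentMap,
    levels: int = 32,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """GLCM statistics per object for one band.

    Returns a DataFrame indexed by object id with the eight
    :data:`GLCM_STATS` columns.  Objects with fewer than two co-occurring
    pixel pairs get NaN features (texture undefined).
    """
    labels = segment_map.labels
    if band.shape != labels.shape:
        raise ValueError("band and segment map shapes differ")
    q = quantize(band, levels)
    n_obj = segment_map.n_objects

    counts = np.zeros((n_obj + 1, levels, levels))
    h, w = labels.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        la = labels[r0:r1, c0:c1]
        lb = labels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        same = (la == lb) & (la > 0)
        obj = la[same]
        gi = q[r0:r1, c0:c1][same]
        gj = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][same]
        np.add.at(counts, (obj, gi, gj), 1.0)
        np.add.at(counts, (obj, gj, gi), 1.0)  # symmetric

    i = np.arange(levels, dtype=float)
    ii = i[:, None] * np.ones(levels)[None, :]
    jj = ii.T
    rows = {}
    for o in range(1, n_obj + 1):
        c = counts[o]
        total = c.sum()
        if total < 2:
            rows[o] = {s: np.nan for s in GLCM_STATS}
            continue
        p = c / total
        pi = p.sum(axis=1)  # marginal (= other marginal by symmetry)
        mu = float(i @ pi)
        var = float(((i - mu) ** 2) @ pi)
        sd = np.sqrt(var)
        pos = p > 0
        rows[o] = {
            "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
            "contrast": float((p * (ii - jj) ** 2).sum()),
            "dissimilarity": float((p * np.abs(ii - jj)).sum()),
            "entropy": float(-(p[pos] * np.log(p[pos])).sum()),
            "mean": mu,
            "asm": float((p**2).sum()),
            "sd": sd,
            "correlation": (
                float(((ii - mu) * (jj - mu) * p).sum() / var) if var > 0 else 0.0
            ),
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(GLCM_STATS))
    df.index.name = "object_id"
    return df
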