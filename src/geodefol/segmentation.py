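"""Multiresolution segmentation by pairwise region merging.

Image objects are grown bottom-up from single pixels.  A merge of two
adjacent regions is admissible while the weighted increase in
heterogeneity stays below the squared scale parameter:

    cost = w_shape * dh_shape + (1 - w_shape) * dh_color
    dh_color = sum_b w_b * [n_m * sigma_b(m) - n_a * sigma_b(a) - n_b * sigma_b(b)]
    dh_shape = w_cmpct * dh_compactness + (1 - w_cmpct) * dh_smoothness

where sigma is the population standard deviation of a band inside a
region, compactness is perimeter / sqrt(area) and smoothness is
perimeter / bounding-box perimeter (each weighted by region size in the
delta).  Merging proceeds in deterministic row-major passes with mutual
best-fit acceptance: a region merges with its cheapest neighbour only if
it is also that neighbour's cheapest partner; ties break to the smaller
label.  The process stops when no admissible merge remains.

With ``shape_weight = 0`` (the default here, matching an object-based
defoliation-mapping setup that weights red/NIR/SWIR bands highest) the
result is purely spectral and independent of the compactness weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Scene, SegmentMap, region_adjacency

__all__ = [
    "SegmentationConfig",
    "RegionStats",
    "heterogeneity_increase",
    "segment",
    "region_adjacency",
]

DEFAULT_BAND_WEIGHTS = {
    "Blue": 1.0,
    "Green": 1.0,
    "Red": 2.0,
    "NIR": 2.0,
    "SWIR1": 2.0,
    "SWIR2": 2.0,
    "Pan": 1.0,
}


@dataclass
class SegmentationConfig:
    """Scale and weighting of the region-merging criterion."""

    scale: float
    shape_weight: float = 0.0
    compactness_weight: float = 1.0
    band_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError("scale must be positive and finite")
        if not 0.0 <= self.shape_weight <= 1.0:
            raise ValueError("shape_weight must be in [0, 1]")
        if not 0.0 <= self.compactness_weight <= 1.0:
            raise ValueError("compactness_weight must be in [0, 1]")
        for b, w in self.band_weights.items():
            if w < 0 or not math.isfinite(w):
                raise ValueError(f"band weight for {b} must be finite and >= 0")


@dataclass
class RegionStats:
    """Sufficient statistics of one region.

    ``sums`` and ``sumsqs`` are per-band arrays; ``perimeter`` counts
    exposed pixel edges; ``bbox`` is (rmin, rmax, cmin, cmax) inclusive.
    """

    n: int
    sums: np.ndarray
    sumsqs: np.ndarray
    perimeter: int
    bbox: tuple[int, int, int, int]

    def sigma(self) -> np.ndarray:
        var = self.sumsqs / self.n - (self.sums / self.n) ** 2
        return np.sqrt(np.maximum(var, 0.0))


def _shape_h(n: int, perimeter: float, bbox, w_cmpct: float) -> float:
    b = 2.0 * (bbox[1] - bbox[0] + 1) + 2.0 * (bbox[3] - bbox[2] + 1)
    compact = perimeter / math.sqrt(n)
    smooth = perimeter / b
    return n * (w_cmpct * compact + (1.0 - w_cmpct) * smooth)


def heterogeneity_increase(
    region_a: RegionStats,
    region_b: RegionStats,
    config: SegmentationConfig,
    band_weights: np.ndarray | None = None,
    shared_boundary: int = 1,
) -> float:
    """Merge cost of two disjoint, adjacent regions (symmetric, >= 0).

    ``shared_boundary`` is the number of 4-neighbour pixel edges joining
    the two regions; zero means the regions are not adjacent, which is an
    error.  ``band_weights`` may pre-resolve the config weights to the
    band order of ``sums``; by default the config weights are applied in
    insertion order.
    """
    if shared_boundary < 1:
        raise ValueError("regions are not adjacent")
    if band_weights is None:
        band_weights = np.asarray(list(config.band_weights.values()))[
            : region_a.sums.size
        ]
        if band_weights.size < region_a.sums.size:
            band_weights = np.ones(region_a.sums.size)

    na, nb = region_a.n, region_b.n
    nm = na + nb
    sums = region_a.sums + region_b.sums
    sq = region_a.sumsqs + region_b.sumsqs
    var = sq / nm - (sums / nm) ** 2
    sig_m = np.sqrt(np.maximum(var, 0.0))
    dh_color = float(
        np.dot(
            band_weights,
            nm * sig_m - na * region_a.sigma() - nb * region_b.sigma(),
        )
    )
    dh_color = max(dh_color, 0.0)

    if config.shape_weight == 0.0:
        return dh_color

    bbox_m = (
        min(region_a.bbox[0], region_b.bbox[0]),
        max(region_a.bbox[1], region_b.bbox[1]),
        min(region_a.bbox[2], region_b.bbox[2]),
        max(region_a.bbox[3], region_b.bbox[3]),
    )
    perim_m = region_a.perimeter + region_b.perimeter - 2 * shared_boundary
    wc = config.compactness_weight
    dh_shape = (
        _shape_h(nm, perim_m, bbox_m, wc)
        - _shape_h(na, region_a.perimeter, region_a.bbox, wc)
        - _shape_h(nb, region_b.perimeter, region_b.bbox, wc)
    )
    dh_shape = max(dh_shape, 0.0)
    return config.shape_weight * dh_shape + (1.0 - config.shape_weight) * dh_color


class _Merger:
    """Mutual-best-fit merging engine over the region adjacency graph."""

    def __init__(self, scene: Scene, config: SegmentationConfig):
        self.config = config
        valid = ~scene.nodata_mask
        if not valid.any():
            raise ValueError("scene is entirely nodata")
        names = scene.band_names
        self.weights = np.array(
            [config.band_weights.get(n, 1.0) for n in names], dtype=float
        )
        h, w = scene.shape
        cube = scene.stack(names).reshape(len(names), -1)  # (B, P)

        lab = np.zeros(h * w, dtype=np.int64)
        lab[valid.ravel()] = np.arange(1, int(valid.sum()) + 1)
        self.init_labels = lab.reshape(h, w)

        npix = int(valid.sum())
        self.n = np.zeros(npix + 1, dtype=np.int64)
        self.n[1:] = 1
        vals = cube[:, valid.ravel()]  # (B, npix)
        self.sums = np.zeros((npix + 1, len(names)))
        self.sums[1:] = vals.T
        self.sumsqs = np.zeros_like(self.sums)
        self.sumsqs[1:] = (vals**2).T
        # cached weighted n*sigma per region (0 for single pixels)
        self.wnsig = np.zeros(npix + 1)
        self.alive = np.zeros(npix + 1, dtype=bool)
        self.alive[1:] = True

        rows, cols = np.nonzero(valid)
        self.bbox: dict[int, list[int]] = {}
        self.perim = np.zeros(npix + 1, dtype=np.int64)
        self.perim[1:] = 4
        for r, c, l in zip(rows.tolist(), cols.tolist(), lab.reshape(h, w)[valid].tolist()):
            self.bbox[l] = [r, r, c, c]

        # adjacency + shared boundary lengths
        self.neigh: dict[int, set[int]] = {l: set() for l in range(1, npix + 1)}
        self.blen: dict[tuple[int, int], int] = {}
        L = self.init_labels
        for a, b in (
            (L[:, :-1].ravel(), L[:, 1:].ravel()),
            (L[:-1, :].ravel(), L[1:, :].ravel()),
        ):
            ok = (a > 0) & (b > 0)
            for x, y in zip(a[ok].tolist(), b[ok].tolist()):
                if x == y:
                    continue
                k = (x, y) if x < y else (y, x)
                self.blen[k] = self.blen.get(k, 0) + 1
                self.neigh[x].add(y)
                self.neigh[y].add(x)
        self.parent = np.arange(npix + 1)

    # -- cost ---------------------------------------------------------
    def _cost(self, i: int, j: int) -> float:
        ni, nj = self.n[i], self.n[j]
        nm = ni + nj
        sums = self.sums[i] + self.sums[j]
        sq = self.sumsqs[i] + self.sumsqs[j]
        var = sq / nm - (sums / nm) ** 2
        np.maximum(var, 0.0, out=var)
        dh = nm * float(self.weights @ np.sqrt(var)) - self.wnsig[i] - self.wnsig[j]
        dh = max(dh, 0.0)
        cfg = self.config
        if cfg.shape_weight == 0.0:
            return dh
        bi, bj = self.bbox[i], self.bbox[j]
        bbox_m = (min(bi[0], bj[0]), max(bi[1], bj[1]), min(bi[2], bj[2]), max(bi[3], bj[3]))
        k = (i, j) if i < j else (j, i)
        perim_m = self.perim[i] + self.perim[j] - 2 * self.blen.get(k, 0)
        wc = cfg.compactness_weight
        dshape = (
            _shape_h(nm, perim_m, bbox_m, wc)
            - _shape_h(ni, self.perim[i], (bi[0], bi[1], bi[2], bi[3]), wc)
            - _shape_h(nj, self.perim[j], (bj[0], bj[1], bj[2], bj[3]), wc)
        )
        dshape = max(dshape, 0.0)
        return cfg.shape_weight * dshape + (1.0 - cfg.shape_weight) * dh

    def _best(self, i: int) -> tuple[int, float]:
        best_j, best_c = 0, math.inf
        for j in sorted(self.neigh[i]):
            c = self._cost(i, j)
            if c < best_c:  # strict: ties keep the smaller label
                best_j, best_c = j, c
        return best_j, best_c

    def _merge(self, keep: int, gone: int) -> None:
        self.n[keep] += self.n[gone]
        self.sums[keep] += self.sums[gone]
        self.sumsqs[keep] += self.sumsqs[gone]
        nm = self.n[keep]
        var = self.sumsqs[keep] / nm - (self.sums[keep] / nm) ** 2
        np.maximum(var, 0.0, out=var)
        self.wnsig[keep] = nm * float(self.weights @ np.sqrt(var))
        k = (keep, gone) if keep < gone else (gone, keep)
        shared = self.blen.pop(k, 0)
        self.perim[keep] = self.perim[keep] + self.perim[gone] - 2 * shared
        bk, bg = self.bbox[keep], self.bbox[gone]
        self.bbox[keep] = [
            min(bk[0], bg[0]), max(bk[1], bg[1]), min(bk[2], bg[2]), max(bk[3], bg[3]),
        ]
        del self.bbox[gone]
        for c in self.neigh[gone]:
            if c == keep:
                continue
            kc = (gone, c) if gone < c else (c, gone)
            ln = self.blen.pop(kc, 0)
            kk = (keep, c) if keep < c else (c, keep)
            self.blen[kk] = self.blen.get(kk, 0) + ln
            self.neigh[c].discard(gone)
            self.neigh[c].add(keep)
            self.neigh[keep].add(c)
        self.neigh[keep].discard(gone)
        del self.neigh[gone]
        self.alive[gone] = False
        self.parent[gone] = keep

    def run(self) -> np.ndarray:
        thresh = self.config.scale**2
        while True:
            merged_any = False
            for i in np.nonzero(self.alive)[0].tolist():
                if not self.alive[i] or not self.neigh[i]:
                    continue
                j, cij = self._best(i)
                if j == 0 or cij >= thresh:
                    continue
                i2, _ = self._best(j)
                if i2 != i:
                    continue  # not mutual best fit
                keep, gone = (i, j) if i < j else (j, i)
                self._merge(keep, gone)
                merged_any = True
            if not merged_any:
                break
        # resolve union-find chains
        root = self.parent.copy()
        changed = True
        while changed:
            nxt = root[root]
            changed = bool((nxt != root).any())
            root = nxt
        out = np.zeros_like(self.init_labels)
        pos = self.init_labels > 0
        out[pos] = root[self.init_labels[pos]]
        return out


def segment(scene: Scene, config: SegmentationConfig) -> SegmentMap:
    """Segment a scene into image objects by multiresolution merging.

    Deterministic for a given scene and configuration; object ids are
    renumbered 1..n in row-major order of each object's first pixel.
    """
    raw = _Merger(scene, config).run()
    # compact relabel in order of first occurrence
    flat = raw.ravel()
    pos = flat > 0
    uniq, first = np.unique(flat[pos], return_index=True)
    order = uniq[np.argsort(first)]
    remap = np.zeros(int(flat.max()) + 1, dtype=np.int32)
    remap[order] = np.arange(1, order.size + 1, dtype=np.int32)
    labels = remap[raw]
    return SegmentMap(
        labels=labels,
        n_objects=int(order.size),
        adjacency=region_adjacency(labels),
    )
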