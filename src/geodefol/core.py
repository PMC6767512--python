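"""Core containers shared across the pipeline.

A :class:`Scene` is a stack of co-registered reflectance bands with an
affine georeference and a nodata mask; a :class:`SegmentMap` is the
object layer produced by segmentation — an integer label raster plus the
region-adjacency relation.  Both are plain dataclasses: the heavy lifting
lives in the functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical band order for a six-band surface-reflectance scene.
BAND_NAMES = ("Blue", "Green", "Red", "NIR", "SWIR1", "SWIR2")

#: Bands a Scene may carry (the optional panchromatic channel included).
VALID_BANDS = BAND_NAMES + ("Pan",)

#: Identity affine: (a, b, c, d, e, f) mapping (col, row) -> (x, y) as
#: x = a*col + b*row + c ; y = d*col + e*row + f.
IDENTITY_TRANSFORM = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)


@dataclass
class Scene:
    """Georeferenced multiband reflectance raster.

    Parameters
    ----------
    bands
        Mapping band name -> 2-D float array of reflectance in [0, 1].
        Names must come from :data:`VALID_BANDS`.
    transform
        Six-tuple affine georeference (GDAL-style ordering rearranged to
        ``x = a*col + b*row + c``, ``y = d*col + e*row + f``).
    nodata_mask
        Boolean array, ``True`` where the pixel carries no data.
    """

    bands: dict[str, np.ndarray]
    transform: tuple[float, ...] = IDENTITY_TRANSFORM
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("Scene needs at least one band")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError(f"bands disagree on shape: {shapes}")
        unknown = set(self.bands) - set(VALID_BANDS)
        if unknown:
            raise ValueError(f"unknown band names: {sorted(unknown)}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        elif self.nodata_mask.shape != self.shape:
            raise ValueError("nodata_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def band_names(self) -> tuple[str, ...]:
        # canonical order first, extras (Pan) after
        ordered = [b for b in VALID_BANDS if b in self.bands]
        return tuple(ordered)

    def stack(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        """Return bands as a (n_bands, rows, cols) array in canonical order."""
        names = names or self.band_names
        return np.stack([self.bands[n] for n in names])


@dataclass
class SegmentMap:
    """Image-object layer: 1-based label raster (0 = nodata) + adjacency."""

    labels: np.ndarray
    n_objects: int
    adjacency: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D raster")
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)

    @property
    def object_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def region_adjacency(labels: np.ndarray) -> frozenset[tuple[int, int]]:
    """4-neighbour adjacency between distinct positive labels.

    Pairs are stored sorted ``(i, j), i < j``; label 0 (nodata) never
    participates.
    """
    labels = np.asarray(labels)
    pairs: set[tuple[int, int]] = set()
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[diff], b[diff])
        hi = np.maximum(a[diff], b[diff])
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return frozenset(pairs)
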