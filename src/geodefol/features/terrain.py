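"""Terrain metrics from a DEM: wetness (TWI), position (TPI), ruggedness (TRI).

* TWI = ln(a / tan(beta)) with D8 single-direction flow accumulation
  (contributing cells x cell area) and Horn-method slope, tan(beta)
  floored at 1e-6 so flat terrain never divides by zero.
* TPI = elevation minus the mean elevation in a square window (in-bounds
  cells only, so edges use truncated windows).
* TRI = mean absolute elevation difference to the 8 neighbours.
"""

from __future__ import annotations

import numpy as np

TAN_BETA_FLOOR = 1e-6

_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def horn_slope(dem: np.ndarray, cell_size: float) -> np.ndarray:
    """tan(slope) by Horn's third-order finite difference (edge-padded)."""
    z = np.pad(dem.astype(float), 1, mode="edge")
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h_, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size)
    dzdy = ((g + 2 * h_ + i) - (a + 2 * b + c)) / (8.0 * cell_size)
    return np.hypot(dzdx, dzdy)


def d8_flow_accumulation(dem: np.ndarray, cell_size: float) -> np.ndarray:
    """Contributing-cell counts (including the cell itself) by D8 routing.

    Each cell drains to the neighbour with the steepest distance-weighted
    drop; cells are processed in decreasing elevation so every upslope
    contribution is accumulated before being passed on.  Cells without a
    lower neighbour (pits, flats, edges without descent) keep their
    accumulation.
    """
    h, w = dem.shape
    acc = np.ones((h, w))
    order = np.argsort(dem, axis=None)[::-1]  # high to low
    dist = {off: np.hypot(off[0], off[1]) * cell_size for off in _D8}
    for flat in order.tolist():
        r, c = divmod(flat, w)
        best, best_slope = None, 0.0
        for (dr, dc) in _D8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                s = (dem[r, c] - dem[rr, cc]) / dist[(dr, dc)]
                if s > best_slope:
                    best, best_slope = (rr, cc), s
        if best is not None:
            acc[best] += acc[r, c]
    return acc


def _window_mean(z: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centered square window counting only in-bounds cells."""
    half = window // 2
    pad = np.pad(z.astype(float), half + 1, mode="constant")
    ones = np.pad(np.ones_like(z, dtype=float), half + 1, mode="constant")
    cs = pad.cumsum(0).cumsum(1)
    cn = ones.cumsum(0).cumsum(1)

    def boxsum(m):
        a = m[window:, window:] - m[:-window, window:] - m[window:, :-window] + m[:-window, :-window]
        return a[: z.shape[0], : z.shape[1]]

    return boxsum(cs) / boxsum(cn)


def compute_terrain_features(
    dem: np.ndarray, cell_size: float = 30.0, tpi_window: int = 9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (TWI, TPI, TRI) rasters for a gap-free DEM."""
    dem = np.asarray(dem, dtype=float)
    if not np.isfinite(dem).all():
        raise ValueError("DEM must not contain interior nodata holes")
    if tpi_window % 2 == 0 or tpi_window < 3:
        raise ValueError("tpi_window must be an odd integer >= 3")

    tan_beta = np.maximum(horn_slope(dem, cell_size), TAN_BETA_FLOOR)
    area = d8_flow_accumulation(dem, cell_size) * cell_size**2
    twi = np.log(area / tan_beta)

    tpi = dem - _window_mean(dem, tpi_window)

    h, w = dem.shape
    diff_sum = np.zeros((h, w))
    count = np.zeros((h, w))
    for dr, dc in _D8:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        d = np.abs(dem[r0:r1, c0:c1] - dem[r0 + dr : r1 + dr, c0 + dc : c1 + dc])
        diff_sum[r0:r1, c0:c1] += d
        count[r0:r1, c0:c1] += 1
    tri = diff_sum / count
    return twi, tpi, tri
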