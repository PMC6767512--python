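"""Synthetic scenes, terrain, climate panels and fire records with known truth.

Every downstream stage — segmentation, object features, boosted-tree
classification, hazard scoring, panel econometrics — is exercised on data
from this module, so each generator documents exactly what it emulates:

* :func:`generate_scene` builds a Landsat-like six-band reflectance image
  in which defoliated patches show the canonical stress signature —
  raised visible (green/red) reflectance, depressed NIR and SWIR, and a
  rougher texture — against a healthy broadleaf-forest background.
* :func:`generate_dem` builds a smooth correlated elevation surface.
* :func:`generate_climate_panel` builds monthly precipitation / maximum
  temperature / soil-moisture series per object and a balanced
  object × year response panel with a *known* linear coefficient vector,
  object random effects independent of the regressors, and i.i.d. noise.
* :func:`generate_fire_records` draws Poisson fire events with positive
  burned areas and durations.

All randomness flows from the single integer seed of each spec through
one ``numpy.random.default_rng`` instance, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

from .core import BAND_NAMES, IDENTITY_TRANSFORM, Scene

# Healthy broadleaf canopy reflectance (mean, sd) per band: high NIR
# plateau, moderate SWIR, dark visible bands.
DEFAULT_HEALTHY = {
    "Blue": (0.030, 0.006),
    "Green": (0.060, 0.008),
    "Red": (0.040, 0.008),
    "NIR": (0.350, 0.018),
    "SWIR1": (0.170, 0.014),
    "SWIR2": (0.090, 0.010),
}

# Additive reflectance shift inside defoliated patches: visible up,
# NIR/SWIR down (canopy loss exposes soil/branches and cuts leaf water).
DEFAULT_INFESTED_SHIFT = {
    "Blue": 0.010,
    "Green": 0.030,
    "Red": 0.050,
    "NIR": -0.120,
    "SWIR1": -0.030,
    "SWIR2": -0.015,
}


@dataclass
class SceneSpec:
    """Parameters of a synthetic defoliation scene."""

    width: int = 128
    height: int = 128
    n_patches: int = 6
    patch_radius_range: tuple[int, int] = (6, 14)
    healthy_reflectance: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HEALTHY)
    )
    infested_shift: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INFESTED_SHIFT)
    )
    texture_noise_sd: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 32 or self.height < 32:
            raise ValueError("scene must be at least 32x32 pixels")
        if self.n_patches < 0:
            raise ValueError("n_patches must be >= 0")
        rmin, rmax = self.patch_radius_range
        if rmax >= min(self.width, self.height) // 2:
            raise ValueError(
                f"patch radius {rmax} exceeds image extent "
                f"{self.width}x{self.height}"
            )
        if rmin < 1 or rmin > rmax:
            raise ValueError("invalid patch_radius_range")
        for b, shift in self.infested_shift.items():
            if b in ("Green", "Red") and shift < 0:
                raise ValueError(f"infested shift must raise {b}")
            if b in ("NIR", "SWIR1", "SWIR2") and shift > 0:
                raise ValueError(f"infested shift must lower {b}")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean unit-sd spatially correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_scene(spec: SceneSpec) -> tuple[Scene, np.ndarray, np.ndarray]:
    """Simulate a six-band scene with defoliated patches.

    Returns
    -------
    scene : Scene
        Reflectance clipped to [0, 1].
    label_raster : ndarray of uint8
        1 where the canopy is infested (defoliated), 0 where healthy.
    forest_type_raster : ndarray of uint8
        Categorical forest-type map with at least two classes (codes 1..3).
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    # --- infested patch mask: disc union with blurred, noisy boundary ---
    mask = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    rmin, rmax = spec.patch_radius_range
    for _ in range(spec.n_patches):
        r = rng.integers(rmin, rmax + 1)
        cy = rng.integers(r, spec.height - r)
        cx = rng.integers(r, spec.width - r)
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = 1.0
    if spec.n_patches > 0:
        wobble = 0.18 * _smooth_noise(rng, shape, 3.0)
        mask = ndimage.gaussian_filter(mask, 1.5, mode="reflect") + wobble
    infested = mask > 0.5

    # --- per-band reflectance: correlated background + shift + texture ---
    bands: dict[str, np.ndarray] = {}
    for name in BAND_NAMES:
        mean, sd = spec.healthy_reflectance[name]
        base = mean + sd * _smooth_noise(rng, shape, 4.0)
        base = base + spec.infested_shift.get(name, 0.0) * infested
        # defoliated canopy is texturally rougher: amplify the white-noise
        # component inside patches
        white = rng.standard_normal(shape)
        base = base + spec.texture_noise_sd * white * np.where(infested, 2.5, 1.0)
        bands[name] = np.clip(base, 0.0, 1.0)

    # --- forest types: smooth field quantiles, 3 classes ---
    tfield = _smooth_noise(rng, shape, 10.0)
    q1, q2 = np.quantile(tfield, [0.4, 0.75])
    forest_type = np.ones(shape, dtype=np.uint8)
    forest_type[tfield > q1] = 2
    forest_type[tfield > q2] = 3

    scene = Scene(bands=bands, transform=IDENTITY_TRANSFORM)
    return scene, infested.astype(np.uint8), forest_type


def generate_dem(
    width: int, height: int, roughness: float, seed: int, base_elevation: float = 500.0
) -> np.ndarray:
    """Correlated elevation surface; ``roughness`` scales relief in metres.

    ``roughness=0`` yields a perfectly flat (planar) surface, so every
    local-relief metric downstream is zero.
    """
    if roughness < 0:
        raise ValueError("roughness must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (height, width)
    dem = np.full(shape, base_elevation)
    if roughness > 0:
        dem = dem + roughness * _smooth_noise(rng, shape, 8.0)
        dem = dem + 0.05 * roughness * rng.standard_normal(shape)
    return dem


# ---------------------------------------------------------------------------
# climate panel with known regression structure
# ---------------------------------------------------------------------------

#: Regressor order for the infestation-response panel: previous-year fire
#: severity, then current/previous drought, maximum-temperature and
#: soil-moisture-deficit intensities.
PANEL_REGRESSORS = (
    "fire_l1",
    "drought_t",
    "drought_l1",
    "tmax_t",
    "tmax_l1",
    "soilm_t",
    "soilm_l1",
)

#: Default true coefficients (same order as PANEL_REGRESSORS): hot years
#: now and last year are strong triggers, drought and soil-moisture
#: deficit of the current year moderate, last year's moisture deficit
#: mildly protective, last year's fires a positive trigger.
DEFAULT_BETA = (0.19, 0.15, 0.05, 0.72, 0.32, 0.15, -0.13)
DEFAULT_INTERCEPT = 0.21


@dataclass
class PanelSpec:
    """Parameters of a synthetic balanced climate/response panel."""

    n_objects: int = 19
    years: tuple[int, int] = (1988, 2017)
    panel_years: tuple[int, int] = (2009, 2017)
    beta_true: tuple[float, ...] = DEFAULT_BETA
    intercept: float = DEFAULT_INTERCEPT
    sigma_alpha: float = 0.08
    sigma_eps: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_alpha < 0 or self.sigma_eps < 0:
            raise ValueError("sigma_alpha and sigma_eps must be >= 0")
        if self.years[1] - self.years[0] + 1 < 4:
            raise ValueError("years must span at least 4 years")
        if self.n_objects < 10:
            raise ValueError("need at least 10 objects")
        if len(self.beta_true) != len(PANEL_REGRESSORS):
            raise ValueError(
                f"beta_true needs {len(PANEL_REGRESSORS)} coefficients"
            )
        if not (
            self.years[0] <= self.panel_years[0] < self.panel_years[1] <= self.years[1]
        ):
            raise ValueError("panel_years must lie inside years")


def _monthly_series(
    rng: np.random.Generator, spec: PanelSpec
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Monthly precip / tmax / soil moisture per object.

    Returns the tidy frame plus (n_objects, n_months) arrays.
    """
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    n_months = years.size * 12
    month_of = np.tile(np.arange(1, 13), years.size)
    year_of = np.repeat(years, 12)

    # per-calendar-month gamma precipitation: wet winters, dry summers
    m = np.arange(1, 13)
    shape_m = 2.0 + 1.2 * np.cos(2 * np.pi * (m - 1) / 12)  # peak Jan
    scale_m = 30.0 + 18.0 * np.cos(2 * np.pi * (m - 1) / 12)
    # seasonal maximum temperature, peak July/August
    tmax_m = 20.0 + 13.0 * np.sin(2 * np.pi * (m - 7.5) / 12 + np.pi / 2)

    n = spec.n_objects
    wet_factor = np.exp(0.25 * rng.standard_normal(n))  # object wetness
    warm_offset = 1.5 * rng.standard_normal(n)  # object temperature

    precip = np.empty((n, n_months))
    tmax = np.empty((n, n_months))
    soilm = np.empty((n, n_months))
    for i in range(n):
        k = shape_m[month_of - 1]
        th = scale_m[month_of - 1] * wet_factor[i]
        precip[i] = rng.gamma(k, th)
        shock = np.empty(n_months)
        e = 0.0
        for t in range(n_months):
            e = 0.6 * e + rng.normal(0.0, 1.1)
            shock[t] = e
        trend = 0.02 * (year_of - y0)
        tmax[i] = tmax_m[month_of - 1] + warm_offset[i] + trend + shock
        # soil moisture: exponential memory of precipitation minus
        # evaporative demand from warm anomalies
        s = 60.0
        for t in range(n_months):
            demand = 0.8 * (tmax[i, t] - tmax_m[month_of[t] - 1])
            s = 0.7 * s + 0.3 * precip[i, t] - demand + rng.normal(0.0, 2.0)
            s = max(s, 0.0)
            soilm[i, t] = s

    frames = []
    for var, arr in (("precip", precip), ("tmax", tmax), ("soilm", soilm)):
        df = pd.DataFrame(
            {
                "object_id": np.repeat(np.arange(1, n + 1), n_months),
                "year": np.tile(year_of, n),
                "month": np.tile(month_of, n),
                "variable": var,
                "value": arr.ravel(),
            }
        )
        frames.append(df)
    tidy = pd.concat(frames, ignore_index=True)
    return tidy, precip, tmax, soilm


def _hydro_year_totals(
    arr: np.ndarray, years: np.ndarray, month_of: np.ndarray, year_of: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sum monthly values over hydrological years (Oct–Sep, labelled by
    the September end).  Returns (hydro_years, totals[n_obj, n_hy])."""
    hy = np.where(month_of >= 10, year_of + 1, year_of)
    hy_years = np.unique(hy)
    # keep only complete 12-month hydrological years
    complete = np.array([(hy == y).sum() == 12 for y in hy_years])
    hy_years = hy_years[complete]
    totals = np.stack([arr[:, hy == y].sum(axis=1) for y in hy_years], axis=1)
    return hy_years, totals


def generate_climate_panel(
    spec: PanelSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Monthly climate series plus a balanced response panel with known β.

    The yearly regressors are hazard-intensity-like scores in (0, 1):
    pooled z-scores of hydrological-year aggregates pushed through the
    normal CDF, signed so that *high* values mean drought (precipitation
    deficit), heat (Tmax excess) and soil-moisture deficit.  Previous-year
    fire severity is exogenous Beta noise.  The response is

        y_it = a + beta' x_it + alpha_i + eps_it

    with ``alpha_i ~ N(0, sigma_alpha^2)`` independent of every regressor
    and ``eps_it ~ N(0, sigma_eps^2)``, so panel estimators can be
    validated against ``beta_true``.
    """
    rng = np.random.default_rng(spec.seed)
    tidy, precip, tmax, soilm = _monthly_series(rng, spec)

    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    month_of = np.tile(np.arange(1, 13), years.size)
    year_of = np.repeat(years, 12)

    hy_years, p_tot = _hydro_year_totals(precip, years, month_of, year_of)
    _, t_tot = _hydro_year_totals(tmax, years, month_of, year_of)
    _, s_tot = _hydro_year_totals(soilm, years, month_of, year_of)

    def pooled_cdf(x: np.ndarray, sign: float) -> np.ndarray:
        z = (x - x.mean()) / x.std()
        return ndtr(sign * z)

    drought = pooled_cdf(p_tot, -1.0)  # precipitation deficit
    heat = pooled_cdf(t_tot, +1.0)  # Tmax excess
    smdef = pooled_cdf(s_tot, -1.0)  # soil-moisture deficit
    fire = rng.beta(2.0, 5.0, size=drought.shape)  # exogenous severity

    alpha = rng.normal(0.0, spec.sigma_alpha, size=spec.n_objects)

    p0, p1 = spec.panel_years
    rows = []
    beta = np.asarray(spec.beta_true)
    for i in range(spec.n_objects):
        for yr in range(p0 + 1, p1 + 1):
            j = np.searchsorted(hy_years, yr)
            if j >= hy_years.size or hy_years[j] != yr or yr - 1 < hy_years[0]:
                raise ValueError(f"panel year {yr} lacks hydrological coverage")
            x = np.array(
                [
                    fire[i, j - 1],
                    drought[i, j],
                    drought[i, j - 1],
                    heat[i, j],
                    heat[i, j - 1],
                    smdef[i, j],
                    smdef[i, j - 1],
                ]
            )
            eps = rng.normal(0.0, spec.sigma_eps) if spec.sigma_eps > 0 else 0.0
            y = spec.intercept + float(beta @ x) + alpha[i] + eps
            rows.append((i + 1, yr, y, *x))

    panel = pd.DataFrame(
        rows, columns=["object_id", "year", "infestation", *PANEL_REGRESSORS]
    )
    return tidy, panel, beta.copy()


def generate_fire_records(
    n_objects: int, years: tuple[int, int], rate: float, seed: int
) -> pd.DataFrame:
    """Poisson fire events per object and fire season (June–September).

    Returns a frame with columns ``object_id, date, year, area_ha,
    duration_days``; empty (zero rows) when ``rate`` is 0.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for obj in range(1, n_objects + 1):
        for yr in range(years[0], years[1] + 1):
            for _ in range(rng.poisson(rate)):
                month = rng.integers(6, 10)
                day = rng.integers(1, 29)
                area = float(np.round(rng.lognormal(0.5, 0.9), 3))
                duration = int(1 + rng.poisson(1.2))
                rows.append(
                    (obj, f"{yr:04d}-{month:02d}-{day:02d}", yr, area, duration)
                )
    return pd.DataFrame(
        rows, columns=["object_id", "date", "year", "area_ha", "duration_days"]
    )
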