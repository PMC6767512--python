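"""Yearly hazard-intensity indices from monthly anomaly dimensions.

The scoring chain is: monthly series -> standardized anomalies (or SPI
for precipitation) -> yearly exceedance dimensions (severity, frequency,
duration) -> fuzzy memberships in [0, 1] -> fuzzy-gamma overlay.  The
same machinery scores drought, maximum-temperature and soil-moisture
hazards from climate series, canopy water deficit from NDWI anomalies,
and ground-based fire severity from event frequency / burned area /
burn duration.

Time-series frames are tidy: columns ``object_id, year, month, value``
(monthly cubes) or ``object_id, year`` plus value columns (yearly
tables).  Hydrological years run October–September and are labelled by
the calendar year of the September end; the growing-season basis keeps
April–September of one calendar year.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammainc, ndtri

logger = logging.getLogger(__name__)

SPI_CLIP = 3.09  # +-3.09 ~ the 0.001/0.999 normal quantiles


# ---------------------------------------------------------------------------
# anomalies and SPI
# ---------------------------------------------------------------------------

def monthly_anomalies(
    cube: pd.DataFrame, baseline: tuple[int, int]
) -> pd.DataFrame:
    """Per-object, per-calendar-month z-scores against a baseline period.

    z_{m,y} = (x_{m,y} - mu_m) / sigma_m with mu_m, sigma_m taken over
    the baseline years of calendar month m for that object.  Months with
    zero baseline spread yield NaN (flagged, not inflated); a month
    absent from the baseline is an error.
    """
    b0, b1 = baseline
    if b1 - b0 + 1 < 10:
        raise ValueError("baseline must span at least 10 years")
    out = cube.copy()
    base = cube[(cube["year"] >= b0) & (cube["year"] <= b1)]
    months = base.groupby("object_id")["month"].nunique()
    if (months < 12).any():
        missing = months[months < 12].index.tolist()
        raise ValueError(f"baseline lacks some calendar months for objects {missing}")
    stats = base.groupby(["object_id", "month"])["value"].agg(["mean", "std"])
    stats["std"] = stats["std"].where(stats["std"] > 0)
    merged = out.merge(stats, left_on=["object_id", "month"], right_index=True)
    dev = merged["value"] - merged["mean"]
    z = dev / merged["std"]
    # a month with zero baseline spread is flagged NaN unless the value
    # sits exactly on the (degenerate) climatology, which is no anomaly
    z[dev.abs() < 1e-12] = 0.0
    out["value"] = z
    return out


def _thom_gamma_params(x: np.ndarray) -> tuple[float, float]:
    """Gamma shape/scale by Thom's maximum-likelihood approximation."""
    mean = x.mean()
    a = np.log(mean) - np.mean(np.log(x))
    if a <= 0:  # nearly constant series: fall back to method of moments
        var = x.var()
        shape = mean**2 / var if var > 0 else 1e6
    else:
        shape = (1.0 + np.sqrt(1.0 + 4.0 * a / 3.0)) / (4.0 * a)
    return shape, mean / shape


def compute_spi(
    precip_cube: pd.DataFrame,
    timescale_months: int = 12,
    baseline: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Standardized precipitation index on rolling ``timescale`` sums.

    Per object and calendar month, a gamma distribution (Thom fit, zero
    totals as a mixed point mass) is fitted to the baseline rolling sums;
    SPI is the standard-normal quantile of the fitted CDF, clipped to
    +-3.09.  A month whose baseline totals are all zero gets SPI 0 with
    a warning.
    """
    if (precip_cube["value"] < 0).any():
        raise ValueError("precipitation must be non-negative")
    frames = []
    for obj, grp in precip_cube.groupby("object_id"):
        g = grp.sort_values(["year", "month"]).reset_index(drop=True)
        roll = g["value"].rolling(timescale_months).sum()
        g = g.assign(total=roll).dropna(subset=["total"])
        if baseline is None:
            b0, b1 = int(g["year"].min()), int(g["year"].max())
        else:
            b0, b1 = baseline
        spi = np.full(len(g), np.nan)
        for m, sub in g.groupby("month"):
            base = sub[(sub["year"] >= b0) & (sub["year"] <= b1)]["total"].to_numpy()
            vals = sub["total"].to_numpy()
            pos = base[base > 0]
            q_zero = 1.0 - pos.size / base.size if base.size else 0.0
            if pos.size == 0:
                warnings.warn(
                    f"object {obj} month {m}: all-zero baseline totals, SPI set to 0"
                )
                spi[g.index.get_indexer(sub.index)] = 0.0
                continue
            shape, scale = _thom_gamma_params(pos)
            cdf = q_zero + (1.0 - q_zero) * gammainc(shape, vals / scale)
            cdf = np.clip(cdf, 1e-6, 1 - 1e-6)
            spi[g.index.get_indexer(sub.index)] = np.clip(
                ndtri(cdf), -SPI_CLIP, SPI_CLIP
            )
        frames.append(
            pd.DataFrame(
                {
                    "object_id": obj,
                    "year": g["year"].to_numpy(),
                    "month": g["month"].to_numpy(),
                    "value": spi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# yearly exceedance dimensions
# ---------------------------------------------------------------------------

def assign_year(year: np.ndarray, month: np.ndarray, basis: str) -> np.ndarray:
    """Map calendar (year, month) to the scoring year of the given basis."""
    if basis == "hydrological":
        return np.where(month >= 10, year + 1, year)
    if basis == "growing":
        return np.asarray(year)
    raise ValueError(f"unknown year_basis {basis!r}")


def yearly_dimensions(
    z_cube: pd.DataFrame,
    direction: str = "deficit",
    threshold: float = 1.0,
    year_basis: str = "hydrological",
) -> pd.DataFrame:
    """Severity / frequency / duration of anomaly exceedances per year.

    ``deficit`` counts months with z < -threshold (water-content, SPI,
    soil-moisture deficits); ``excess`` counts z > +threshold (heat).
    Severity sums |z| over exceedance months, frequency counts them and
    duration is the longest consecutive run.  With the growing-season
    basis only April–September months are scored.
    """
    if direction not in ("deficit", "excess"):
        raise ValueError("direction must be 'deficit' or 'excess'")
    df = z_cube.copy()
    df["score_year"] = assign_year(
        df["year"].to_numpy(), df["month"].to_numpy(), year_basis
    )
    if year_basis == "growing":
        df = df[(df["month"] >= 4) & (df["month"] <= 9)]

    rows = []
    for (obj, yr), grp in df.groupby(["object_id", "score_year"]):
        g = grp.sort_values(["year", "month"])
        z = g["value"].to_numpy()
        exceed = (z < -threshold) if direction == "deficit" else (z > threshold)
        exceed = exceed & np.isfinite(z)
        severity = float(np.abs(z[exceed]).sum())
        frequency = int(exceed.sum())
        duration = run = 0
        for e in exceed:
            run = run + 1 if e else 0
            duration = max(duration, run)
        rows.append((obj, int(yr), severity, frequency, duration))
    return pd.DataFrame(
        rows, columns=["object_id", "year", "severity", "frequency", "duration"]
    )


# ---------------------------------------------------------------------------
# fuzzy operators
# ---------------------------------------------------------------------------

def fuzzy_linear(values, lo: float, hi: float) -> np.ndarray:
    """Linear membership: 0 at/below lo, 1 at/above hi, linear between."""
    if lo >= hi:
        raise ValueError("fuzzy_linear needs lo < hi")
    v = np.asarray(values, dtype=float)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def fuzzy_large(values, midpoint: float, spread: float) -> np.ndarray:
    """'Large' membership 1 / (1 + (v/f1)^(-f2)); 0.5 at the midpoint."""
    if midpoint <= 0 or spread <= 0:
        raise ValueError("fuzzy_large needs positive midpoint and spread")
    v = np.asarray(values, dtype=float)
    out = np.zeros(v.shape)
    pos = v > 0
    out[pos] = 1.0 / (1.0 + (v[pos] / midpoint) ** (-spread))
    return out


def fuzzy_gamma(memberships, gamma: float) -> np.ndarray:
    """Fuzzy-gamma overlay of membership layers.

    mu = (1 - prod(1 - mu_i))^gamma * (prod mu_i)^(1 - gamma):
    gamma=0 is the pessimistic product, gamma=1 the optimistic algebraic
    sum, intermediate values trade the two off.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    mu = np.asarray(memberships, dtype=float)
    if mu.ndim == 1:
        mu = mu[:, None]
    if np.nanmin(mu) < 0 or np.nanmax(mu) > 1:
        raise ValueError("memberships must lie in [0, 1]")
    alg_sum = 1.0 - np.prod(1.0 - mu, axis=0)
    product = np.prod(mu, axis=0)
    # 0^0 := 1 at the boundary gammas
    with np.errstate(invalid="ignore"):
        left = np.where((alg_sum == 0) & (gamma == 0), 1.0, alg_sum**gamma)
        right = np.where((product == 0) & (gamma == 1), 1.0, product ** (1.0 - gamma))
    return left * right


# ---------------------------------------------------------------------------
# hazard indices
# ---------------------------------------------------------------------------

DimensionMembership = dict[str, tuple]  # name -> ("linear", lo, hi) | ("large", f1, f2)


def _membership(values: np.ndarray, spec: tuple) -> np.ndarray:
    kind = spec[0]
    if kind == "linear":
        return fuzzy_linear(values, spec[1], spec[2])
    if kind == "large":
        return fuzzy_large(values, spec[1], spec[2])
    raise ValueError(f"unknown membership kind {kind!r}")


def default_membership_config(dimensions: pd.DataFrame) -> DimensionMembership:
    """Linear anchors at each dimension's observed min/max."""
    cfg: DimensionMembership = {}
    for c in ("severity", "frequency", "duration"):
        lo, hi = float(dimensions[c].min()), float(dimensions[c].max())
        if hi <= lo:
            hi = lo + 1.0  # degenerate column: all-zero memberships
        cfg[c] = ("linear", lo, hi)
    return cfg


def hazard_index(
    dimensions: pd.DataFrame,
    membership_config: DimensionMembership | None = None,
    gamma: float = 0.9,
) -> pd.DataFrame:
    """Combine yearly dimensions into an object x year intensity in [0, 1]."""
    cfg = membership_config or default_membership_config(dimensions)
    mus = np.stack(
        [
            _membership(dimensions[c].to_numpy(dtype=float), cfg[c])
            for c in ("severity", "frequency", "duration")
        ]
    )
    out = dimensions[["object_id", "year"]].copy()
    out["index"] = fuzzy_gamma(mus, gamma)
    return out


def fire_severity(
    records: pd.DataFrame,
    object_ids,
    seasons,
    membership_config: DimensionMembership | None = None,
    gamma: float = 0.9,
) -> pd.DataFrame:
    """Ground-based fire severity per object and fire season.

    Dimensions per object-season: frequency (event count), size (total
    burned area, ha) and duration (total burn days), standardized by
    fuzzy-linear memberships (anchors from config or the observed
    min/max) and overlaid with the fuzzy-gamma operator.  Records whose
    object id is unknown are logged and skipped; object-seasons without
    fires score 0.
    """
    object_ids = list(object_ids)
    seasons = list(seasons)
    known = records["object_id"].isin(object_ids)
    if (~known).any():
        logger.warning(
            "%d fire record(s) outside all objects were skipped", int((~known).sum())
        )
    rec = records[known]

    grid = pd.MultiIndex.from_product(
        [object_ids, seasons], names=["object_id", "year"]
    ).to_frame(index=False)
    agg = (
        rec.groupby(["object_id", "year"])
        .agg(
            frequency=("object_id", "size"),
            size=("area_ha", "sum"),
            duration=("duration_days", "sum"),
        )
        .reset_index()
    )
    dims = grid.merge(agg, on=["object_id", "year"], how="left").fillna(0.0)

    if membership_config is None:
        membership_config = {}
        for c in ("frequency", "size", "duration"):
            lo, hi = 0.0, float(dims[c].max())
            if hi <= lo:
                hi = 1.0
            membership_config[c] = ("linear", lo, hi)
    mus = np.stack(
        [
            _membership(dims[c].to_numpy(dtype=float), membership_config[c])
            for c in ("frequency", "size", "duration")
        ]
    )
    out = dims[["object_id", "year"]].copy()
    out["index"] = fuzzy_gamma(mus, gamma)
    return out
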