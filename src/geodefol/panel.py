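"""Balanced-panel regression: pooled OLS, fixed effects, random effects,
with Chow poolability and Hausman specification tests.

The data model is y_it = beta' x_it + z_i alpha + eps_it for objects
i = 1..N observed in years t = 1..T.  Pooled ("common effects") OLS uses
one intercept; the fixed-effects (within) estimator absorbs an intercept
per object by demeaning; the random-effects GLS estimator quasi-demeans
with the Swamy–Arora shrinkage theta = 1 - sqrt(s2_eps / (s2_eps + T *
s2_alpha)).  The Chow F test compares pooled vs fixed effects (also
reported in the (N-1)*F chi-square form with df = N-1, the convention
some software prints); the Hausman test contrasts FE and RE slopes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Regressor sets: infestation response (7 regressors) and fire response (8).
PANEL_SPECS = {
    "infestation": {
        "response": "infestation",
        "regressors": (
            ("fire", 1),
            ("drought", 0),
            ("drought", 1),
            ("tmax", 0),
            ("tmax", 1),
            ("soilm", 0),
            ("soilm", 1),
        ),
    },
    "fire": {
        "response": "fire",
        "regressors": (
            ("infestation", 0),
            ("infestation", 1),
            ("drought", 0),
            ("drought", 1),
            ("tmax", 0),
            ("tmax", 1),
            ("soilm", 0),
            ("soilm", 1),
        ),
    },
}


def build_panel(indices: dict[str, pd.DataFrame], spec: str = "infestation") -> pd.DataFrame:
    """Assemble the lagged regressor panel from yearly hazard indices.

    ``indices`` maps variable name (infestation, fire, drought, tmax,
    soilm) to a tidy frame with columns object_id, year, index (or
    value).  The first available year is consumed by the lags.  An
    unbalanced source (an object missing a year) is an error listing the
    gaps.
    """
    if spec not in PANEL_SPECS:
        raise ValueError(f"spec must be one of {sorted(PANEL_SPECS)}")
    cfg = PANEL_SPECS[spec]
    wide = {}
    for name, df in indices.items():
        value_col = "index" if "index" in df.columns else "value"
        w = df.pivot(index="object_id", columns="year", values=value_col)
        gaps = [
            (int(o), int(y))
            for o in w.index
            for y in w.columns[w.loc[o].isna()]
        ]
        if gaps:
            raise ValueError(f"unbalanced index {name!r}: missing object-years {gaps}")
        wide[name] = w

    needed = {cfg["response"]} | {v for v, _ in cfg["regressors"]}
    missing = needed - set(wide)
    if missing:
        raise ValueError(f"missing index variables: {sorted(missing)}")

    years = sorted(set.intersection(*(set(w.columns) for w in wide.values())))
    objects = sorted(set.intersection(*(set(w.index) for w in wide.values())))
    rows = []
    for obj in objects:
        for yr in years[1:]:  # first year consumed by the lag
            row = {"object_id": obj, "year": yr,
                   cfg["response"]: wide[cfg["response"]].loc[obj, yr]}
            for var, lag in cfg["regressors"]:
                row[f"{var}_t" if lag == 0 else f"{var}_l{lag}"] = (
                    wide[var].loc[obj, yr - lag]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def panel_regressors(panel: pd.DataFrame, response: str) -> list[str]:
    return [c for c in panel.columns if c not in ("object_id", "year", response)]


@dataclass
class FitResult:
    """Estimates of one panel specification."""

    model: str  # common | fixed | random
    beta: pd.Series  # slopes
    intercept: float | None
    alpha_i: pd.Series | None  # per-object intercepts (fixed effects)
    cov: pd.DataFrame  # covariance of the slopes
    sigma2_eps: float
    sigma2_alpha: float
    theta: float
    r2: float
    residuals: np.ndarray = field(repr=False, default=None)
    rss: float = 0.0
    nobs: int = 0
    n_objects: int = 0
    n_periods: int = 0
    df_resid: int = 0

    @property
    def std_errors(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.beta.index)

    def p_values(self) -> pd.Series:
        """Two-sided normal-approximation p-values of the slopes."""
        z = self.beta / self.std_errors
        return pd.Series(2.0 * sps.norm.sf(np.abs(z)), index=self.beta.index)


def _check_balanced(panel: pd.DataFrame) -> tuple[int, int]:
    counts = panel.groupby("object_id")["year"].count()
    if counts.nunique() != 1:
        raise ValueError("panel is unbalanced across objects")
    if panel.duplicated(["object_id", "year"]).any():
        raise ValueError("duplicate object-year rows")
    return int(counts.size), int(counts.iloc[0])


def _solve_ols(X: np.ndarray, y: np.ndarray, names: list[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"singular design; collinear column(s): {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def fit_pooled(panel: pd.DataFrame, response: str = "infestation") -> FitResult:
    """Common-effects model: OLS of y on an intercept and the regressors."""
    N, T = _check_balanced(panel)
    regs = panel_regressors(panel, response)
    y = panel[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(panel)), panel[regs].to_numpy(dtype=float)])
    if len(panel) <= len(regs) + 1:
        raise ValueError("not enough observations")
    beta, resid = _solve_ols(X, y, ["const"] + regs)
    rss = float(resid @ resid)
    df = len(panel) - len(regs) - 1
    s2 = rss / df
    cov_full = s2 * np.linalg.inv(X.T @ X)
    tss = float(((y - y.mean()) ** 2).sum())
    return FitResult(
        model="common",
        beta=pd.Series(beta[1:], index=regs),
        intercept=float(beta[0]),
        alpha_i=None,
        cov=pd.DataFrame(cov_full[1:, 1:], index=regs, columns=regs),
        sigma2_eps=s2,
        sigma2_alpha=0.0,
        theta=0.0,
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        residuals=resid,
        rss=rss,
        nobs=len(panel),
        n_objects=N,
        n_periods=T,
        df_resid=df,
    )


def _within_transform(panel, response, regs):
    g = panel.groupby("object_id")
    y = panel[response].to_numpy(dtype=float)
    X = panel[regs].to_numpy(dtype=float)
    ybar = g[response].transform("mean").to_numpy()
    Xbar = g[regs].transform("mean").to_numpy()
    return y - ybar, X - Xbar, ybar, Xbar


def fit_fixed_effects(panel: pd.DataFrame, response: str = "infestation") -> FitResult:
    """Within (demeaned-by-object) estimator with recovered object intercepts."""
    N, T = _check_balanced(panel)
    if N < 2:
        raise ValueError("fixed effects need at least 2 objects")
    regs = panel_regressors(panel, response)
    yw, Xw, _, _ = _within_transform(panel, response, regs)
    within_sd = Xw.std(axis=0)
    dead = [r for r, s in zip(regs, within_sd) if s < 1e-12]
    if dead:
        raise ValueError(f"time-invariant regressor(s) absorbed by fixed effects: {dead}")
    beta, resid = _solve_ols(Xw, yw, regs)
    rss = float(resid @ resid)
    df = len(panel) - N - len(regs)
    s2 = rss / df
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    tssw = float((yw**2).sum())

    means = panel.groupby("object_id").mean(numeric_only=True)
    alpha_i = means[response] - means[regs].to_numpy() @ beta
    return FitResult(
        model="fixed",
        beta=pd.Series(beta, index=regs),
        intercept=None,
        alpha_i=alpha_i.rename("alpha_i"),
        cov=pd.DataFrame(cov, index=regs, columns=regs),
        sigma2_eps=s2,
        sigma2_alpha=float("nan"),
        theta=1.0,
        r2=1.0 - rss / tssw if tssw > 0 else 1.0,
        residuals=resid,
        rss=rss,
        nobs=len(panel),
        n_objects=N,
        n_periods=T,
        df_resid=df,
    )


def fit_random_effects(panel: pd.DataFrame, response: str = "infestation") -> FitResult:
    """Swamy–Arora GLS: quasi-demeaned OLS with estimated variance components."""
    N, T = _check_balanced(panel)
    regs = panel_regressors(panel, response)
    k = len(regs)

    fe = fit_fixed_effects(panel, response)
    s2_eps = fe.sigma2_eps  # within residual variance, df = NT - N - k

    # between regression on object means
    means = panel.groupby("object_id").mean(numeric_only=True)
    yb = means[response].to_numpy(dtype=float)
    Xb = np.column_stack([np.ones(N), means[regs].to_numpy(dtype=float)])
    if N <= k + 1:
        raise ValueError("too few objects for the between regression")
    bb, rb = _solve_ols(Xb, yb, ["const"] + regs)
    s2_between = float(rb @ rb) / (N - k - 1)
    s2_alpha = max(0.0, s2_between - s2_eps / T)
    theta = 1.0 - math.sqrt(s2_eps / (s2_eps + T * s2_alpha))

    g = panel.groupby("object_id")
    y = panel[response].to_numpy(dtype=float)
    X = panel[regs].to_numpy(dtype=float)
    ybar = g[response].transform("mean").to_numpy()
    Xbar = g[regs].transform("mean").to_numpy()
    ystar = y - theta * ybar
    Xstar = np.column_stack([np.full(len(panel), 1.0 - theta), X - theta * Xbar])
    beta, resid = _solve_ols(Xstar, ystar, ["const"] + regs)
    rss = float(resid @ resid)
    # transformed disturbances have variance sigma2_eps under the model
    cov_full = s2_eps * np.linalg.inv(Xstar.T @ Xstar)
    tss = float(((ystar - ystar.mean()) ** 2).sum())
    return FitResult(
        model="random",
        beta=pd.Series(beta[1:], index=regs),
        intercept=float(beta[0]),
        alpha_i=None,
        cov=pd.DataFrame(cov_full[1:, 1:], index=regs, columns=regs),
        sigma2_eps=s2_eps,
        sigma2_alpha=s2_alpha,
        theta=theta,
        r2=1.0 - rss / tss if tss > 0 else 1.0,
        residuals=resid,
        rss=rss,
        nobs=len(panel),
        n_objects=N,
        n_periods=T,
        df_resid=len(panel) - k - 1,
    )


# ---------------------------------------------------------------------------
# specification tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    name: str
    statistic: float
    df: int
    p_value: float
    statistic_f: float | None = None
    p_value_f: float | None = None
    flagged: bool = False


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability Q(df/2, x/2).

    Regularized upper incomplete gamma evaluated by its power series for
    small arguments and by a Lentz continued fraction otherwise;
    absolute accuracy about 1e-8 over the reported range.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    a = df / 2.0
    z = x / 2.0
    if z == 0.0:
        return 1.0
    if z < a + 1.0:
        # series for the lower regularized gamma P(a, z)
        term = 1.0 / a
        total = term
        n = 0
        while True:
            n += 1
            term *= z / (a + n)
            total += term
            if abs(term) < abs(total) * 1e-15 or n > 10_000:
                break
        p = total * math.exp(-z + a * math.log(z) - math.lgamma(a))
        return 1.0 - p
    # Lentz continued fraction for Q(a, z)
    tiny = 1e-300
    b = z + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 10_000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        d = tiny if abs(d) < tiny else d
        c = b + an / c
        c = tiny if abs(c) < tiny else c
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-15:
            break
    return h * math.exp(-z + a * math.log(z) - math.lgamma(a))


def chow_test(
    pooled_fit: FitResult, fe_fit: FitResult, panel: pd.DataFrame
) -> TestResult:
    """Poolability F test of fixed vs common effects.

    F = [(RSS_pooled - RSS_FE) / (N-1)] / [RSS_FE / (NT - N - k)];
    the chi-square form (N-1)*F with df = N-1 is reported as the main
    statistic to mirror the X2 convention, the F form alongside.
    """
    if pooled_fit.nobs != fe_fit.nobs:
        raise ValueError("fits are not on the same panel")
    N = fe_fit.n_objects
    k = len(fe_fit.beta)
    df1, df2 = N - 1, fe_fit.nobs - N - k
    if fe_fit.rss <= 1e-12 * max(1.0, pooled_fit.rss):
        if pooled_fit.rss <= 1e-12 * max(1.0, float(np.abs(panel.select_dtypes("number")).to_numpy().max())):
            # both models fit perfectly: no evidence of individual effects
            return TestResult("chow", 0.0, df1, 1.0, 0.0, 1.0)
        return TestResult("chow", float("inf"), df1, 0.0, float("inf"), 0.0)
    F = ((pooled_fit.rss - fe_fit.rss) / df1) / (fe_fit.rss / df2)
    F = max(F, 0.0)
    chi2 = df1 * F
    return TestResult(
        name="chow",
        statistic=chi2,
        df=df1,
        p_value=chi2_sf(chi2, df1),
        statistic_f=F,
        p_value_f=float(sps.f.sf(F, df1, df2)),
    )


def hausman_test(fe_fit: FitResult, re_fit: FitResult) -> TestResult:
    """Hausman contrast of FE and RE slopes.

    H = q' (V_FE - V_RE)^-1 q with q the slope difference; df = k.  A
    non-positive-definite covariance difference falls back to the
    pseudo-inverse (flagged); a negative statistic is clipped at zero.
    """
    if list(fe_fit.beta.index) != list(re_fit.beta.index):
        raise ValueError("fits have different slope sets")
    q = (fe_fit.beta - re_fit.beta).to_numpy()
    V = fe_fit.cov.to_numpy() - re_fit.cov.to_numpy()
    k = q.size
    flagged = False
    try:
        evals = np.linalg.eigvalsh(V)
        if evals.min() <= 0:
            raise np.linalg.LinAlgError
        H = float(q @ np.linalg.solve(V, q))
    except np.linalg.LinAlgError:
        H = float(q @ np.linalg.pinv(V) @ q)
        flagged = True
    if H < 0:
        logger.warning("negative Hausman statistic %.3g clipped to 0", H)
        H = 0.0
    return TestResult(
        name="hausman", statistic=H, df=k, p_value=chi2_sf(H, k), flagged=flagged
    )


def summarize_fits(fits: list[FitResult], response: str) -> pd.DataFrame:
    """Coefficient table across models with significance stars (0.05 / 0.01)."""
    rows = {}
    for fit in fits:
        p = fit.p_values()
        cells = {}
        if fit.intercept is not None:
            cells["constant"] = f"{fit.intercept:.3f}"
        elif fit.alpha_i is not None:
            cells["constant"] = f"{fit.alpha_i.mean():.3f} (mean alpha_i)"
        for name in fit.beta.index:
            stars = "**" if p[name] < 0.01 else ("*" if p[name] < 0.05 else " ns")
            cells[name] = f"{fit.beta[name]:.3f}{stars}"
        cells["R2"] = f"{fit.r2:.3f}"
        rows[fit.model] = cells
    return pd.DataFrame(rows).T
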