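"""Panel estimators, specification tests and the chi-square tail."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import geodefol as gd
from geodefol.panel import (
    build_panel,
    chi2_sf,
    chow_test,
    fit_fixed_effects,
    fit_pooled,
    fit_random_effects,
    hausman_test,
    panel_regressors,
)


def random_panel(N=19, T=7, k=3, sigma_alpha=0.5, sigma_eps=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((N * T, k))
    alpha = np.repeat(rng.normal(0, sigma_alpha, N), T)
    beta = rng.uniform(-1, 1, k)
    y = 1.0 + X @ beta + alpha + rng.normal(0, sigma_eps, N * T)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(k)])
    df.insert(0, "object_id", np.repeat(np.arange(1, N + 1), T))
    df.insert(1, "year", np.tile(np.arange(2011, 2011 + T), N))
    df["infestation"] = y
    return df, beta


def yearly_index(values, objects, years):
    rows = [
        (o, y, values[i, j])
        for i, o in enumerate(objects)
        for j, y in enumerate(years)
    ]
    return pd.DataFrame(rows, columns=["object_id", "year", "index"])


class TestBuildPanel:
    def _indices(self, n_obj=2, years=range(2010, 2018), seed=0):
        rng = np.random.default_rng(seed)
        years = list(years)
        objs = list(range(1, n_obj + 1))
        return {
            name: yearly_index(rng.uniform(0, 1, (n_obj, len(years))), objs, years)
            for name in ("infestation", "fire", "drought", "tmax", "soilm")
        }

    def test_lag_consumes_first_year(self):
        panel = build_panel(self._indices(), "infestation")
        assert len(panel) == 2 * 7
        assert panel["year"].min() == 2011

    def test_lag_alignment(self):
        idx = self._indices()
        panel = build_panel(idx, "infestation")
        d = idx["drought"].set_index(["object_id", "year"])["index"]
        row = panel[(panel["object_id"] == 1) & (panel["year"] == 2012)].iloc[0]
        assert row["drought_l1"] == pytest.approx(d.loc[(1, 2011)])
        assert row["drought_t"] == pytest.approx(d.loc[(1, 2012)])

    def test_regressor_counts_by_spec(self):
        idx = self._indices()
        infest = build_panel(idx, "infestation")
        fire = build_panel(idx, "fire")
        assert len(panel_regressors(infest, "infestation")) == 7
        assert len(panel_regressors(fire, "fire")) == 8

    def test_unbalanced_source_lists_gaps(self):
        idx = self._indices()
        idx["tmax"] = idx["tmax"].drop(idx["tmax"].index[3])
        with pytest.raises(ValueError, match="unbalanced"):
            build_panel(idx, "infestation")


class TestPooled:
    def test_exact_linear_fit(self):
        df = pd.DataFrame(
            {
                "object_id": np.repeat([1, 2], 4),
                "year": np.tile(np.arange(4), 2),
                "x": np.arange(8, dtype=float),
            }
        )
        df["infestation"] = 2.0 * df["x"]
        fit = fit_pooled(df)
        assert fit.beta["x"] == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_orthogonal_noise_gives_zero_slope(self):
        x = np.array([1.0, -1.0] * 6)
        e = np.array([1.0, 1.0, -1.0, -1.0] * 3)  # orthogonal to x and constant
        df = pd.DataFrame(
            {
                "object_id": np.repeat([1, 2, 3], 4),
                "year": np.tile(np.arange(4), 3),
                "x": x,
                "infestation": e,
            }
        )
        fit = fit_pooled(df)
        assert fit.beta["x"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_on_12_rows(self):
        df, _ = random_panel(N=3, T=4, k=2, seed=5)
        fit = fit_pooled(df)
        X = np.column_stack([np.ones(12), df[["x0", "x1"]].to_numpy()])
        y = df["infestation"].to_numpy()
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(ref[0], abs=1e-10)
        np.testing.assert_allclose(fit.beta.to_numpy(), ref[1:], atol=1e-10)

    def test_singular_design_names_columns(self):
        df, _ = random_panel(N=4, T=4, k=2, seed=6)
        df["x_dup"] = df["x0"] * 2.0
        with pytest.raises(ValueError, match="x_dup"):
            fit_pooled(df)


class TestFixedEffects:
    def test_object_offsets_absorbed_exactly(self):
        rng = np.random.default_rng(7)
        N, T = 5, 6
        x = rng.standard_normal(N * T)
        offsets = np.repeat(rng.uniform(-5, 5, N), T)
        df = pd.DataFrame(
            {
                "object_id": np.repeat(np.arange(1, N + 1), T),
                "year": np.tile(np.arange(T), N),
                "x": x,
                "infestation": x + offsets,
            }
        )
        fit = fit_fixed_effects(df)
        assert fit.beta["x"] == pytest.approx(1.0, abs=1e-10)

    def test_equals_lsdv_and_alpha_identity(self):
        df, _ = random_panel(seed=8)
        fit = fit_fixed_effects(df)
        regs = panel_regressors(df, "infestation")
        dummies = pd.get_dummies(df["object_id"], dtype=float)
        X = np.column_stack([df[regs].to_numpy(), dummies.to_numpy()])
        coef, *_ = np.linalg.lstsq(X, df["infestation"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.beta.to_numpy(), coef[: len(regs)], atol=1e-10)
        means = df.groupby("object_id").mean(numeric_only=True)
        expected_alpha = means["infestation"] - means[regs].to_numpy() @ fit.beta.to_numpy()
        np.testing.assert_allclose(fit.alpha_i.to_numpy(), expected_alpha, atol=1e-10)

    def test_invariant_to_object_constant_shift(self):
        df, _ = random_panel(seed=9)
        fit1 = fit_fixed_effects(df)
        shifted = df.copy()
        shifted["x0"] = shifted["x0"] + shifted["object_id"] * 3.0
        fit2 = fit_fixed_effects(shifted)
        np.testing.assert_allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(), atol=1e-10)

    def test_time_invariant_regressor_rejected(self):
        df, _ = random_panel(seed=10)
        df["constant_reg"] = np.repeat(np.arange(19, dtype=float), 7)
        with pytest.raises(ValueError, match="constant_reg"):
            fit_fixed_effects(df)

    def test_single_object_rejected(self):
        df, _ = random_panel(seed=10)
        with pytest.raises(ValueError):
            fit_fixed_effects(df[df["object_id"] == 1])


class TestRandomEffects:
    def test_zero_alpha_variance_reduces_to_pooled(self):
        df, _ = random_panel(N=20, T=8, sigma_alpha=0.0, sigma_eps=0.4, seed=11)
        re = fit_random_effects(df)
        if re.sigma2_alpha == 0.0:
            po = fit_pooled(df)
            np.testing.assert_allclose(re.beta.to_numpy(), po.beta.to_numpy(), atol=1e-10)
            assert re.theta == 0.0

    def test_approaches_fixed_effects_as_alpha_dominates(self):
        df, _ = random_panel(N=30, T=10, sigma_alpha=50.0, sigma_eps=0.1, seed=12)
        re = fit_random_effects(df)
        fe = fit_fixed_effects(df)
        assert re.theta > 0.98
        np.testing.assert_allclose(re.beta.to_numpy(), fe.beta.to_numpy(), atol=5e-3)

    def test_within_between_decomposition(self):
        df, _ = random_panel(seed=13)
        y = df["infestation"]
        total = ((y - y.mean()) ** 2).sum()
        ybar = df.groupby("object_id")["infestation"].transform("mean")
        within = ((y - ybar) ** 2).sum()
        between = ((ybar - y.mean()) ** 2).sum()
        assert within + between == pytest.approx(total, rel=1e-12)


class TestEstimatorOracles:
    """Slopes match established/independent implementations on 5 fixtures."""

    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_pooled_and_fe_match_statsmodels(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        df, _ = random_panel(N=19, T=7, seed=seed)
        regs = panel_regressors(df, "infestation")
        po = fit_pooled(df)
        X = sm.add_constant(df[regs].to_numpy())
        ref = sm.OLS(df["infestation"].to_numpy(), X).fit()
        np.testing.assert_allclose(po.beta.to_numpy(), ref.params[1:], atol=1e-6)
        fe = fit_fixed_effects(df)
        dummies = pd.get_dummies(df["object_id"], dtype=float)
        Xl = np.column_stack([df[regs].to_numpy(), dummies.to_numpy()])
        lsdv = sm.OLS(df["infestation"].to_numpy(), Xl).fit()
        np.testing.assert_allclose(fe.beta.to_numpy(), lsdv.params[: len(regs)], atol=1e-10)

    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_re_matches_explicit_gls(self, seed):
        """Quasi-demeaned RE equals a full-matrix GLS solve with the same
        variance components (independent computational route)."""
        df, _ = random_panel(N=19, T=7, seed=seed)
        re = fit_random_effects(df)
        regs = panel_regressors(df, "infestation")
        N, T = 19, 7
        omega_block = re.sigma2_eps * np.eye(T) + re.sigma2_alpha * np.ones((T, T))
        omega_inv_block = np.linalg.inv(omega_block)
        X = np.column_stack([np.ones(N * T), df[regs].to_numpy()])
        y = df["infestation"].to_numpy()
        XtOX = np.zeros((X.shape[1], X.shape[1]))
        XtOy = np.zeros(X.shape[1])
        for i in range(N):
            sl = slice(i * T, (i + 1) * T)
            XtOX += X[sl].T @ omega_inv_block @ X[sl]
            XtOy += X[sl].T @ omega_inv_block @ y[sl]
        ref = np.linalg.solve(XtOX, XtOy)
        np.testing.assert_allclose(re.beta.to_numpy(), ref[1:], atol=1e-6)


class TestChow:
    def test_no_effects_noise_free_accepts_pooling(self):
        df = pd.DataFrame(
            {
                "object_id": np.repeat([1, 2, 3], 4),
                "year": np.tile(np.arange(4), 3),
                "x": np.arange(12, dtype=float),
            }
        )
        df["infestation"] = 1.0 + 0.5 * df["x"]
        res = chow_test(fit_pooled(df), fit_fixed_effects(df), df)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_strong_offsets_rejected(self):
        df, _ = random_panel(sigma_alpha=3.0, sigma_eps=0.2, seed=14)
        res = chow_test(fit_pooled(df), fit_fixed_effects(df), df)
        assert res.p_value < 0.01

    def test_df_is_objects_minus_one(self):
        df, _ = random_panel(N=19, T=7, seed=15)
        res = chow_test(fit_pooled(df), fit_fixed_effects(df), df)
        assert res.df == 18


class TestHausman:
    def test_identical_slopes_give_zero(self):
        from geodefol.panel import FitResult

        beta = pd.Series([1.0, 2.0], index=["a", "b"])
        cov_fe = pd.DataFrame(np.eye(2) * 2.0, index=["a", "b"], columns=["a", "b"])
        cov_re = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        mk = lambda m, c: FitResult(
            model=m, beta=beta.copy(), intercept=0.0, alpha_i=None, cov=c,
            sigma2_eps=1.0, sigma2_alpha=0.0, theta=0.0, r2=0.5,
        )
        res = hausman_test(mk("fixed", cov_fe), mk("random", cov_re))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_df_matches_regressor_count(self, default_panel):
        _, panel, _ = default_panel
        res = hausman_test(fit_fixed_effects(panel), fit_random_effects(panel))
        assert res.df == 7
        assert res.statistic >= 0.0

    def test_mismatched_slopes_rejected(self):
        df, _ = random_panel(seed=16)
        fe = fit_fixed_effects(df)
        re = fit_random_effects(df)
        re.beta = re.beta.rename({"x0": "other"})
        with pytest.raises(ValueError):
            hausman_test(fe, re)


class TestChi2Sf:
    def test_zero_statistic_is_one(self):
        for k in (1, 5, 18):
            assert chi2_sf(0.0, k) == 1.0

    @pytest.mark.parametrize(
        "x,df,expected",
        [(11.87, 7, 0.105), (6.72, 8, 0.567), (37.39, 18, 0.005)],
    )
    def test_reference_tail_probabilities(self, x, df, expected):
        assert round(chi2_sf(x, df), 3) == pytest.approx(expected, abs=1e-9)

    def test_matches_scipy_over_grid(self):
        for df in (1, 2, 7, 8, 18, 40):
            for x in (0.1, 1.0, 5.0, 20.0, 75.0):
                assert chi2_sf(x, df) == pytest.approx(sps.chi2.sf(x, df), abs=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chi2_sf(-1.0, 3)
        with pytest.raises(ValueError):
            chi2_sf(1.0, 0)
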