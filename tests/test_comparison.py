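"""Unpenalized arm: OLS rank handling, VIF closed forms, nonlinearity check."""

import numpy as np
import pandas as pd
import pytest

from costdrivers import sgl, synthetic
from costdrivers.comparison import (fit_ols, nonlinearity_check, share_path,
                                    side_by_side, vif)
from costdrivers.preprocess import fit_design
from costdrivers.roster import PredictorSpec

from conftest import design_from_matrix, small_config, small_roster


def _standardize(X):
    X = X - X.mean(axis=0)
    return X / X.std(axis=0, ddof=0)


def _exact_corr_design(rho, n=50, seed=0):
    """Two standardized columns whose sample correlation is exactly rho."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std(ddof=0)
    b -= b.mean()
    b -= a * (a @ b) / n  # exactly decorrelate
    b /= b.std(ddof=0)
    x2 = rho * a + np.sqrt(1 - rho**2) * b
    X = np.column_stack([a, x2])
    return design_from_matrix(X, [1, 1], names=["u", "v"], standardized=True)


class TestVIF:
    def test_orthogonal_columns_give_exactly_one(self):
        d = _exact_corr_design(0.0)
        assert np.allclose(vif(d), 1.0, atol=1e-10)

    @pytest.mark.parametrize("rho", [0.5, 0.9, 0.99])
    def test_closed_form_for_constructed_correlation(self, rho):
        d = _exact_corr_design(rho)
        expect = 1.0 / (1.0 - rho**2)
        assert np.allclose(vif(d), expect, rtol=1e-6)

    def test_duplicated_column_flagged_infinite(self, rng):
        a = _standardize(rng.standard_normal((40, 3)))
        X = np.column_stack([a, a[:, 0]])
        d = design_from_matrix(X, [1, 1, 1, 1], standardized=True)
        v = vif(d)
        assert np.isinf(v[0]) and np.isinf(v[3])
        assert np.isfinite(v[1]) and np.isfinite(v[2])

    def test_agrees_with_statsmodels_on_random_design(self, rng):
        sm = pytest.importorskip("statsmodels.stats.outliers_influence")
        X = _standardize(rng.standard_normal((80, 5)) @ rng.standard_normal((5, 5)))
        d = design_from_matrix(X, [1] * 5, standardized=True)
        mine = vif(d)
        theirs = [sm.variance_inflation_factor(X, k) for k in range(5)]
        assert np.allclose(mine, theirs, rtol=1e-6)

    def test_single_column_rejected(self, rng):
        d = design_from_matrix(_standardize(rng.standard_normal((10, 1))), [1],
                               standardized=True)
        with pytest.raises(ValueError, match="two columns"):
            vif(d)


class TestOLS:
    def test_orthonormal_design_coefficients(self, rng):
        X = rng.standard_normal((100, 4))
        X -= X.mean(axis=0)
        q, _ = np.linalg.qr(X)
        X = q * np.sqrt(100)  # X'X/n = I
        d = design_from_matrix(X, [2, 2], names=["a", "b"],
                               orthogonalized=True, standardized=True)
        roster = [PredictorSpec("a", "continuous", None, True),
                  PredictorSpec("b", "continuous", None, False)]
        y = rng.standard_normal(100)
        rep = fit_ols(d, y, roster)
        yc = y - y.mean()
        assert np.allclose(rep.coefficients, X.T @ yc / 100, atol=1e-10)
        assert rep.not_estimated == []

    def test_full_rank_matches_normal_equations(self, rng):
        X = _standardize(rng.standard_normal((60, 5)))
        d = design_from_matrix(X, [3, 2], names=["a", "b"], standardized=True)
        roster = [PredictorSpec("a", "continuous", None, True),
                  PredictorSpec("b", "continuous", None, False)]
        y = rng.standard_normal(60)
        rep = fit_ols(d, y, roster)
        oracle = np.linalg.solve(X.T @ X, X.T @ (y - y.mean()))
        assert np.allclose(rep.coefficients, oracle, atol=1e-8)

    def test_duplicated_column_driver_reported_not_estimated(self, rng):
        a = _standardize(rng.standard_normal((50, 3)))
        X = np.column_stack([a, a[:, 0]])
        d = design_from_matrix(X, [3, 1], names=["big", "dup"], standardized=True)
        roster = [PredictorSpec("big", "continuous", None, True),
                  PredictorSpec("dup", "continuous", None, False)]
        rep = fit_ols(d, rng.standard_normal(50), roster)
        # the singleton duplicating a column of the larger group loses
        assert rep.not_estimated == ["dup"]
        assert not rep.estimable[3]
        assert np.isnan(rep.coefficients[3])

    def test_derived_flag_not_estimated_but_sgl_stays_certified(self):
        # casemix-derived binary: exact collinearity breaks OLS, not the
        # penalized fit
        cfg = small_config(
            400, seed=5,
            roster=small_roster() + [PredictorSpec("derived", "binary", [0, 1], True)],
            signal_groups=["procedure", "age", "flag", "derived"],
            collinear_pairs=[synthetic.CollinearPair("procedure", "derived", 0.4)])
        ds = synthetic.generate(cfg)
        design, _ = fit_design(ds.records, cfg.roster, retain=1.0)
        y = ds.records["cost"].to_numpy(float)
        ols = fit_ols(design, y, cfg.roster)
        assert "derived" in ols.not_estimated
        lam = 0.1 * sgl.lambda_max(design, y, 0.15)
        fr = sgl.fit(design, y, sgl.PenaltyConfig(lam, 0.15), tol=1e-8)
        assert np.all(np.isfinite(fr.beta))
        assert fr.converged and sgl.kkt_check(fr, design, y) <= 1e-4


class TestSideBySide:
    def test_near_zero_lambda_path_point_matches_ols_shares(self):
        ds = synthetic.generate(small_config(300, seed=7))
        design, _ = fit_design(ds.records, ds.config.roster, retain=1.0)
        y = ds.records["cost"].to_numpy(float)
        roster = ds.config.roster
        ols = fit_ols(design, y, roster)
        lmax = sgl.lambda_max(design, y, 0.15)
        path = share_path(design, y, roster, 0.15, [lmax * 1.05, 0.0], tol=1e-10)
        lasso_rep = ols.aggregate_report
        table = side_by_side(lasso_rep, ols, path=path)
        assert table["share_ols_pct"].sum() == pytest.approx(100.0)
        # lambda above lambda_max: null model, NaN shares
        assert path[path.columns[0]].isna().all()
        # lambda = 0 equals the OLS decomposition
        for d in lasso_rep.drivers:
            assert path[0.0][d.name] == pytest.approx(d.share, abs=1e-6)

    def test_roster_mismatch_rejected(self):
        ds = synthetic.generate(small_config(100, seed=1))
        design, _ = fit_design(ds.records, ds.config.roster, retain=1.0)
        y = ds.records["cost"].to_numpy(float)
        ols = fit_ols(design, y, ds.config.roster)
        other = fit_ols(design, y, ds.config.roster)
        other.aggregate_report.drivers = other.aggregate_report.drivers[:-1]
        with pytest.raises(ValueError, match="different driver rosters"):
            side_by_side(other.aggregate_report, ols)


def _dominant_driver_instance(seed, n=400):
    """A dominant casemix-like group of many thin coefficients, a correlated
    ward satellite, and one strong singleton driver."""
    rng = np.random.default_rng(seed)
    la = 30
    w = (np.arange(la) + 1.0) ** -0.8
    a = rng.choice(la, n, p=w / w.sum())
    eff_a = rng.normal(0, 0.15, la)
    b = a % 8
    relabel = rng.random(n) < 0.3
    b[relabel] = rng.integers(0, 8, relabel.sum())
    eff_b = rng.normal(0, 0.3, 8)
    z = rng.standard_normal(n)
    eta = eff_a[a] + eff_b[b] + 0.8 * z
    cost = np.exp(8 + eta + 0.5 * rng.standard_normal(n))
    df = pd.DataFrame({"casemix": [f"A{i:02d}" for i in a],
                       "ward": [f"B{i}" for i in b], "idx": z, "cost": cost})
    roster = [PredictorSpec("casemix", "categorical",
                            [f"A{i:02d}" for i in range(la)], True),
              PredictorSpec("ward", "categorical",
                            [f"B{i}" for i in range(8)], False),
              PredictorSpec("idx", "continuous", None, True)]
    return df, roster


def test_dominant_driver_share_shrinks_under_the_penalty():
    """At the CV-selected penalty the dominant multi-level driver's share of
    variability sits below its OLS share in the majority of seeded runs —
    the per-coefficient penalty shaves a group of many thin coefficients
    proportionally harder than fat singleton drivers."""
    from costdrivers.aggregate import aggregate_coefficients
    from costdrivers.selection import cross_validate

    wins = 0
    for seed in range(10):
        df, roster = _dominant_driver_instance(seed)
        cv = cross_validate(df, roster, retain=1.0, alpha_grid=[0.15],
                            n_lambda=15, k=5, seed=seed + 50, tol=1e-6)
        design, _ = fit_design(df, roster, retain=1.0)
        y = df["cost"].to_numpy(float)
        fr = sgl.fit(design, y, sgl.PenaltyConfig(cv.best[1], 0.15),
                     tol=1e-7, record_objective=False)
        rep = aggregate_coefficients(fr.beta, design, roster)
        ols = fit_ols(design, y, roster)
        wins += (rep.driver("casemix").share
                 < ols.aggregate_report.driver("casemix").share)
    assert wins > 5


class TestNonlinearity:
    def _baseline_ci(self, ds, target, penalty, width=0.5):
        """CI centered on the full-data linear-fit aggregate."""
        from costdrivers.aggregate import aggregate_coefficients

        design, _ = fit_design(ds.records, ds.config.roster, retain=1.0)
        y = ds.records["cost"].to_numpy(float)
        fr = sgl.fit(design, y, penalty, tol=1e-7, record_objective=False)
        agg = aggregate_coefficients(fr.beta, design, ds.config.roster).driver(target).aggregate
        return {target: (agg * (1 - width), agg * (1 + width))}

    def test_linear_truth_passes_and_quadratic_truth_fails(self):
        ds = synthetic.generate(small_config(3000, seed=21))
        pen = sgl.PenaltyConfig(1.0, 0.15)
        ci = self._baseline_ci(ds, "age", pen)
        rep = nonlinearity_check(ds.records, ds.config.roster, ["age"], pen,
                                 baseline_ci=ci, retain=1.0, fraction=0.2,
                                 repeats=3, seed=4)
        assert rep.per_target["age"]["verdict"] == "linearity adequate"

        bent = ds.records.copy()
        z = np.clip((bent["age"] - 50.0) / 20.0, -2.5, 2.5)
        bent["cost"] = bent["cost"] * np.exp(0.3 * z**2)
        ci_b = self._baseline_ci(
            synthetic.SyntheticDataset(bent, ds.truth, ds.config), "age", pen)
        rep_b = nonlinearity_check(bent, ds.config.roster, ["age"], pen,
                                   baseline_ci=ci_b, retain=1.0, fraction=0.25,
                                   repeats=3, seed=4)
        assert rep_b.per_target["age"]["verdict"] == "nonlinearity detected"

    def test_same_seed_reproduces_subsamples(self):
        ds = synthetic.generate(small_config(500, seed=2))
        pen = sgl.PenaltyConfig(1.0, 0.15)
        ci = {"age": (0.0, 1e9)}
        a = nonlinearity_check(ds.records, ds.config.roster, ["age"], pen,
                               baseline_ci=ci, retain=1.0, repeats=2, seed=8)
        b = nonlinearity_check(ds.records, ds.config.roster, ["age"], pen,
                               baseline_ci=ci, retain=1.0, repeats=2, seed=8)
        assert a.per_target == b.per_target

    def test_non_numeric_target_rejected(self):
        ds = synthetic.generate(small_config(100, seed=2))
        with pytest.raises(ValueError, match="continuous/ordinal"):
            nonlinearity_check(ds.records, ds.config.roster, ["procedure"],
                               sgl.PenaltyConfig(1.0, 0.15),
                               baseline_ci={"procedure": (0, 1)})
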