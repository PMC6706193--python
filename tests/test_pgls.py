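"""PGLS engine: GLS algebra, lambda profiling, helpers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pglspath as pp
from pglspath.pgls import CollinearityError, InsufficientDataError
from pglspath.traits import TraitTable


def _random_instance(rng, n=30, p=2):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    beta = rng.normal(size=p + 1)
    y = X @ beta + rng.standard_normal(n)
    return y, X


class TestFitGLS:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identity_covariance_equals_ols(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        y, X = _random_instance(rng)
        res = pp.fit_gls(y, X, np.eye(len(y)))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(res.params, ols.params, atol=1e-8)
        assert np.allclose(res.bse, ols.bse, atol=1e-8)
        assert np.allclose(res.tvalues, ols.tvalues, atol=1e-8)
        assert np.allclose(res.pvalues, ols.pvalues, atol=1e-8)

    def test_perfect_fit_flagged(self):
        n = 12
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = X @ np.array([1.0, 2.0])
        res = pp.fit_gls(y, X, np.eye(n))
        assert res.perfect_fit
        assert np.allclose(res.pvalues, 0.0)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_whitening_oracle_on_random_covariance(self, seed):
        # independent route: explicit Cholesky whitening then plain OLS
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = 8
        A = rng.standard_normal((n, n))
        V = A @ A.T + n * np.eye(n)
        y, X = _random_instance(rng, n=n, p=1)
        res = pp.fit_gls(y, X, V)
        L = np.linalg.cholesky(V)
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, X)
        ols = sm.OLS(yw, Xw).fit()
        assert np.allclose(res.params, ols.params, atol=1e-8)
        assert np.allclose(res.bse, ols.bse, atol=1e-8)

    def test_collinear_design_raises_naming_columns(self):
        rng = np.random.default_rng(0)
        n = 20
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = rng.standard_normal(n)
        with pytest.raises(CollinearityError):
            pp.fit_gls(y, X, np.eye(n), names=["const", "a", "b"])

    def test_non_psd_covariance_raises(self):
        n = 5
        V = -np.eye(n)
        with pytest.raises(np.linalg.LinAlgError):
            pp.fit_gls(np.ones(n), np.ones((n, 1)), V)


class TestProfileLambda:
    def test_two_point_grid_returns_endpoint_argmax(self, small_tree):
        rng = np.random.default_rng(7)
        n = small_tree.n_tips
        lat = pp.simulate_traits(
            small_tree,
            pp.CausalDAG(edges=[], vertices=("Y",)),
            {},
            {"Y": 1.0},
            seed=7,
        )
        y = lat["Y"].to_numpy()
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        model = pp.PGLS(y, X, tree=small_tree)
        res = model.fit(grid_size=2, refine=False)
        assert res.lambda_hat in (0.0, 1.0)
        ll0, ll1 = model.loglik_lambda(0.0), model.loglik_lambda(1.0)
        assert res.lambda_hat == (1.0 if ll1 >= ll0 else 0.0)

    def test_profiled_likelihood_dominates_endpoints(self, small_tree, rng):
        n = small_tree.n_tips
        lat = pp.simulate_traits(
            small_tree,
            pp.CausalDAG(edges=[("X", "Y")], vertices=("X", "Y")),
            {("X", "Y"): 0.4},
            {"X": 0.5, "Y": 0.5},
            seed=3,
        )
        X = np.column_stack([np.ones(n), lat["X"].to_numpy()])
        model = pp.PGLS(lat["Y"].to_numpy(), X, tree=small_tree)
        res = model.fit(grid_size=101)
        assert res.llf >= model.loglik_lambda(0.0) - 1e-9
        assert res.llf >= model.loglik_lambda(1.0) - 1e-9

    def test_random_grid_deterministic_under_seed(self, small_tree):
        rng = np.random.default_rng(9)
        n = small_tree.n_tips
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        r1 = pp.profile_lambda(y, X, small_tree, grid_size=50, seed=5, grid="random")
        r2 = pp.profile_lambda(y, X, small_tree, grid_size=50, seed=5, grid="random")
        assert r1.lambda_hat == r2.lambda_hat
        assert r1.llf == r2.llf

    def test_pvalue_matches_survival_function(self, small_tree, rng):
        n = small_tree.n_tips
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        res = pp.PGLS(y, X, tree=small_tree).fit(lam=0.3)
        expected = 2 * (1 - stats.t.cdf(np.abs(res.tvalues), res.df_resid))
        assert np.allclose(res.pvalues, expected, atol=1e-12)


class TestStandardizedFit:
    def test_response_equal_to_predictor_gives_unit_slope(self, study_fixture):
        tab = study_fixture.table
        df = tab.data.copy()
        df["echo"] = df["clutch_size"]
        tab2 = TraitTable(df, transforms={"clutch_size": "log", "echo": "log"})
        res = pp.standardized_fit(tab2, "echo", ["clutch_size"], study_fixture.tree)
        assert res.params[1] == pytest.approx(1.0, abs=1e-6)

    def test_missingness_bookkeeping(self, study_fixture):
        res = pp.standardized_fit(
            study_fixture.table, "aggression", ["hunting_success"], study_fixture.tree
        )
        assert res.nobs == 40
        assert res.df_resid == 38

    def test_insufficient_data_error(self, study_fixture):
        df = study_fixture.table.data.copy()
        df["sparse"] = np.nan
        df.iloc[:2, df.columns.get_loc("sparse")] = 1.0
        tab = TraitTable(df, transforms={})
        with pytest.raises(InsufficientDataError):
            pp.standardized_fit(tab, "aggression", ["sparse"], study_fixture.tree)

    def test_slope_recovery_on_fixture(self, study_fixture):
        # the generating model links aggression negatively to provisioning
        res = pp.standardized_fit(
            study_fixture.table, "aggression", ["provisioning_rate"], study_fixture.tree
        )
        assert res.nobs == 65
        assert res.params[1] < 0


class TestWeightedFit:
    def _data(self, tree, seed=0):
        rng = np.random.default_rng(seed)
        n = tree.n_tips
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        return y, X

    def test_equal_effort_matches_unweighted_slope(self, small_tree):
        y, X = self._data(small_tree)
        effort = np.full(small_tree.n_tips, 10)
        wres = pp.weighted_fit(y, X, small_tree, effort)
        ures = pp.PGLS(y, X, tree=small_tree).fit()
        # equal diagonal inflation cannot change the GLS slope much
        assert wres.params[1] == pytest.approx(ures.params[1], abs=0.05)

    def test_large_effort_limit_recovers_unweighted(self, small_tree):
        y, X = self._data(small_tree, seed=1)
        effort = np.full(small_tree.n_tips, 10**6)
        wres = pp.weighted_fit(y, X, small_tree, effort)
        ures = pp.PGLS(y, X, tree=small_tree).fit()
        assert np.allclose(wres.params, ures.params, atol=1e-3)

    def test_nonpositive_effort_rejected(self, small_tree):
        y, X = self._data(small_tree)
        with pytest.raises(ValueError):
            pp.weighted_fit(y, X, small_tree, np.zeros(small_tree.n_tips))

    def test_low_effort_species_loses_leverage(self, small_tree):
        # hat-matrix diagonal under V vs V + diag(c/effort): the noisy
        # species' leverage must strictly decrease
        y, X = self._data(small_tree, seed=2)
        n = small_tree.n_tips
        V = pp.vcv_matrix(small_tree).matrix
        effort = np.full(n, 100.0)
        effort[0] = 1.0

        def hat_diag(M):
            Mi = np.linalg.inv(M)
            H = X @ np.linalg.inv(X.T @ Mi @ X) @ X.T @ Mi
            return np.diag(H)

        h0 = hat_diag(V)
        h1 = hat_diag(V + np.diag(1.0 / effort))
        assert h1[0] < h0[0]


def test_pgls_matches_r_nlme_oracle(tmp_path):
    """Independent cross-check: coefficients, SEs and logLik at a fixed
    lambda must match R's nlme::gls with ape::corPagel (ML)."""
    import subprocess

    tree = pp.simulate_tree(20, seed=3)
    lat = pp.simulate_traits(
        tree, pp.CausalDAG(edges=[("X", "Y")], vertices=("X", "Y")),
        {("X", "Y"): 0.5}, {"X": 0.8, "Y": 0.8}, seed=5,
    )
    tree.write_newick(tmp_path / "t.nwk")
    lat.to_csv(tmp_path / "d.csv")
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages({library(ape); library(nlme)})\n"
        f'tr <- read.tree("{tmp_path}/t.nwk")\n'
        f'd <- read.csv("{tmp_path}/d.csv", row.names=1)\n'
        "d <- d[tr$tip.label,]\n"
        'fit <- gls(Y ~ X, data=d, correlation=corPagel(0.5, phy=tr, fixed=TRUE),'
        ' method="ML")\n'
        'cat(coef(fit), sqrt(diag(vcov(fit))), logLik(fit), sep="\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    b0, b1, se0, se1, llf = (float(v) for v in out.stdout.strip().split("\n"))

    cov = pp.vcv_matrix(tree)
    y = lat.loc[cov.species_order, "Y"].to_numpy()
    X = np.column_stack([np.ones(20), lat.loc[cov.species_order, "X"].to_numpy()])
    res = pp.PGLS(y, X, cov=cov).fit(lam=0.5)
    assert res.params == pytest.approx([b0, b1], rel=1e-5)
    assert res.bse == pytest.approx([se0, se1], rel=1e-5)
    assert res.llf == pytest.approx(llf, abs=1e-4)


class TestSpearman:
    def test_monotone_pairs(self):
        up = pp.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        down = pp.spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        res = pp.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pp.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        n = 40
        t = np.arange(n)
        X = np.column_stack(
            [np.ones(n), np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)]
        )
        v = pp.vif(X, names=["const", "c", "s"])
        assert np.allclose(v.values, 1.0, atol=1e-10)

    @pytest.mark.parametrize("r", [0.3, 0.6, 0.9])
    def test_two_predictor_closed_form(self, r):
        rng = np.random.default_rng(0)
        n = 5000
        z = rng.standard_normal((n, 2))
        x1 = z[:, 0]
        x2 = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1]
        X = np.column_stack([np.ones(n), x1, x2])
        v = pp.vif(X, names=["const", "x1", "x2"])
        r_emp = np.corrcoef(x1, x2)[0, 1]
        expected = 1.0 / (1.0 - r_emp**2)
        assert np.allclose(v.values, expected, rtol=1e-10)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        X = np.column_stack([np.ones(30), x, x])
        v = pp.vif(X, names=["const", "a", "b"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])
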