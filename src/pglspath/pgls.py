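"""Phylogenetic generalized least squares with profiled Pagel's lambda.

The model is y = X b + e with e ~ N(0, sigma^2 * V(lambda)), where V(lambda)
is the Brownian-motion covariance of the phylogeny with its off-diagonal
multiplied by Pagel's lambda.  Coefficients are the GLS solution
b = (X' V^-1 X)^-1 X' V^-1 y; sigma^2 is estimated by maximum likelihood
(residual quadratic form / n) for the reported log-likelihood, and by the
unbiased n - p denominator for standard errors so that V = I reduces exactly
to ordinary least squares.  lambda is profiled: the fit is repeated over a
grid on [0, 1] and the grid maximizer is polished by bounded golden-section
search.

Usage follows the statsmodels convention::

    model = PGLS(y, X, tree=tree, names=["const", "clutch"])
    res = model.fit()          # profiles lambda
    res = model.fit(lam=0.5)   # fixed lambda
    print(res.summary())
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trees import PhyloCovariance, PhyloTree, lambda_transform, vcv_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PGLS",
    "PGLSResults",
    "CorrelationResult",
    "fit_gls",
    "profile_lambda",
    "standardized_fit",
    "weighted_fit",
    "spearman",
    "vif",
]

_PERFECT_FIT_TOL = 1e-10


class CollinearityError(np.linalg.LinAlgError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class CorrelationResult:
    """Spearman rank correlation with its t-approximation p-value."""

    rho: float
    p_value: float
    n: int


@dataclass
class PGLSResults:
    """Estimates and diagnostics from a single PGLS fit.

    ``params`` are on the scale of the (possibly standardized) design; ``K``
    counts estimated parameters for AICc as coefficients + 1 for the residual
    variance (lambda is profiled, not counted, matching the information-
    theoretic bookkeeping of the comparative literature).
    """

    params: np.ndarray
    bse: np.ndarray
    df_resid: int
    nobs: int
    lambda_hat: float
    llf: float
    sigma2_ml: float
    exog_names: list[str]
    perfect_fit: bool = False
    fitted_values: np.ndarray | None = None
    resid: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        if self.perfect_fit:
            return np.zeros_like(self.params)
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    @property
    def nparams(self) -> int:
        return len(self.params)

    @property
    def K(self) -> int:
        return self.nparams + 1

    @property
    def aicc(self) -> float:
        n, K = self.nobs, self.K
        if n - K - 1 <= 0:
            raise ValueError(f"AICc undefined: n={n} <= K+1={K + 1}")
        return -2.0 * self.llf + 2 * K + 2 * K * (K + 1) / (n - K - 1)

    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.exog_names)

    def summary(self) -> str:
        rows = []
        t = self.tvalues
        p = self.pvalues
        for j, name in enumerate(self.exog_names):
            rows.append(
                f"{name:>20s} {self.params[j]: 10.4f} {self.bse[j]: 10.4f} "
                f"{t[j]: 9.3f} {p[j]: 9.4f}"
            )
        head = (
            f"PGLS fit: n={self.nobs}, df={self.df_resid}, "
            f"lambda={self.lambda_hat:.3f}, logLik={self.llf:.3f}, AICc={self.aicc:.3f}\n"
            f"{'':>20s} {'coef':>10s} {'SE':>10s} {'t':>9s} {'p':>9s}"
        )
        return head + "\n" + "\n".join(rows)


def _check_design(X: np.ndarray, names: list[str], XtViX: np.ndarray) -> None:
    cond = np.linalg.cond(XtViX)
    if not np.isfinite(cond) or cond > 1e12:
        # identify dependent columns via QR with column pivoting on X
        _, R, piv = _qr_pivot(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps * 100
        bad = [names[piv[k]] for k in range(len(diag)) if diag[k] < tol] or list(names)
        raise CollinearityError(f"singular design (X'V^-1X): dependent columns {bad}")


def _qr_pivot(X):
    import scipy.linalg as sla

    Q, R, piv = sla.qr(X, pivoting=True, mode="economic")
    return Q, R, piv


def _gls_core(y: np.ndarray, X: np.ndarray, L: np.ndarray, logdet: float, names: list[str]):
    """Whitened GLS given the Cholesky factor L of the covariance."""
    import scipy.linalg as sla

    yw = sla.solve_triangular(L, y, lower=True)
    Xw = sla.solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    _check_design(Xw, names, XtX)
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    return beta, rss, XtX, Xw, yw


def _loglik(rss: float, logdet: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)


def fit_gls(
    y: np.ndarray,
    X: np.ndarray,
    V: PhyloCovariance | np.ndarray,
    names: list[str] | None = None,
    lambda_hat: float = 1.0,
) -> PGLSResults:
    """GLS fit with a fixed covariance matrix.

    ``V`` may be a PhyloCovariance (its species order is assumed to match the
    row order of y and X; alignment happens upstream) or a plain ndarray.
    """
    import scipy.linalg as sla

    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    M = V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    try:
        L = sla.cholesky(M, lower=True)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"covariance matrix not positive definite: {exc}")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    beta, rss, XtX, Xw, yw = _gls_core(y, X, L, logdet, names)
    llf = _loglik(rss, logdet, n)
    df_resid = n - p
    perfect = rss < _PERFECT_FIT_TOL * max(1.0, float(yw @ yw))
    if perfect:
        logger.warning("perfect linear fit: residuals ~ 0, t statistics unbounded")
    scale = rss / df_resid if df_resid > 0 else np.nan
    bse = np.sqrt(np.maximum(np.diag(scale * np.linalg.inv(XtX)), 0.0))
    fitted = X @ beta
    return PGLSResults(
        params=beta,
        bse=bse,
        df_resid=df_resid,
        nobs=n,
        lambda_hat=lambda_hat,
        llf=llf,
        sigma2_ml=rss / n,
        exog_names=list(names),
        perfect_fit=perfect,
        fitted_values=fitted,
        resid=y - fitted,
    )


class PGLS:
    """Phylogenetic GLS model for one response and a design matrix.

    Parameters
    ----------
    endog : (n,) response vector, aligned to ``species``.
    exog : (n, p) design matrix including the intercept column.
    tree : PhyloTree, optional — used to build the Brownian covariance.
    cov : PhyloCovariance, optional — pre-built covariance (alternative to tree).
    species : tip labels giving the row order; defaults to the covariance order.
    names : design column names.
    """

    def __init__(self, endog, exog, tree: PhyloTree | None = None,
                 cov: PhyloCovariance | None = None, species: list[str] | None = None,
                 names: list[str] | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if cov is None:
            if tree is None:
                raise ValueError("provide either tree or cov")
            cov = vcv_matrix(tree)
        if species is not None:
            cov = cov.reorder(list(species))
        if cov.n != self.endog.shape[0]:
            raise ValueError("covariance dimension does not match data")
        self.cov = cov
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]
        self._prepare_eig()

    # -- lambda machinery ---------------------------------------------------
    def _prepare_eig(self) -> None:
        """Fast profiling path when the covariance diagonal is constant.

        On an ultrametric tree diag(V) = depth * 1, so V(lambda) =
        lambda V + (1 - lambda) c I shares V's eigenvectors; one symmetric
        eigendecomposition then makes every grid evaluation O(n p^2).
        """
        M = self.cov.matrix
        d = np.diag(M)
        self._const_diag = bool(np.allclose(d, d[0], rtol=1e-10, atol=1e-12)) and d[0] > 0
        if self._const_diag:
            w, U = np.linalg.eigh(M)
            self._eig_w = np.maximum(w, 0.0)
            self._c = float(d[0])
            self._yr = U.T @ self.endog
            self._Xr = U.T @ self.exog

    def _fit_lambda_fast(self, lam: float) -> tuple[np.ndarray, float, float, np.ndarray]:
        dvals = lam * self._eig_w + (1.0 - lam) * self._c
        dvals = np.maximum(dvals, 1e-12)
        wts = 1.0 / dvals
        Xs = self._Xr * wts[:, None]
        XtX = self._Xr.T @ Xs  # X' V(lambda)^-1 X
        Xty = self._Xr.T @ (wts * self._yr)
        beta = np.linalg.solve(XtX, Xty)
        resid = self._yr - self._Xr @ beta
        rss = float(np.sum(wts * resid * resid))
        logdet = float(np.sum(np.log(dvals)))
        return beta, rss, logdet, XtX

    def loglik_lambda(self, lam: float) -> float:
        n = self.endog.shape[0]
        if self._const_diag:
            try:
                _, rss, logdet, _ = self._fit_lambda_fast(lam)
            except np.linalg.LinAlgError:
                return -np.inf
            return _loglik(rss, logdet, n)
        res = self.fit(lam=lam)
        return res.llf

    def fit(self, lam: float | None = None, grid_size: int = 500,
            grid: str = "deterministic", seed: int | None = None,
            refine: bool = True) -> PGLSResults:
        """Fit the model; profile lambda when ``lam`` is None.

        ``grid='deterministic'`` evaluates ``grid_size`` equally spaced points
        on [0, 1] (endpoints included) and polishes the best one with bounded
        golden-section search; ``grid='random'`` draws ``grid_size`` uniform
        points (plus both endpoints) from a seeded generator, mirroring the
        randomized profile procedure of the comparative literature.
        """
        if lam is not None:
            if not (0.0 <= lam <= 1.0):
                raise ValueError("lambda must lie in [0, 1]")
            Vl = lambda_transform(self.cov, lam)
            return fit_gls(self.endog, self.exog, Vl, names=self.names, lambda_hat=lam)
        return self._profile(grid_size=grid_size, grid=grid, seed=seed, refine=refine)

    def _profile(self, grid_size: int, grid: str, seed: int | None, refine: bool) -> PGLSResults:
        if grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if grid == "deterministic":
            lams = np.linspace(0.0, 1.0, grid_size)
        elif grid == "random":
            rng = np.random.default_rng(seed)
            lams = np.concatenate([[0.0, 1.0], rng.uniform(0.0, 1.0, size=grid_size)])
            lams.sort()
        else:
            raise ValueError(f"unknown grid mode {grid!r}")
        lls = np.array([self.loglik_lambda(l) for l in lams])
        if not np.any(np.isfinite(lls)):
            raise np.linalg.LinAlgError("likelihood undefined at every lambda")
        best = int(np.nanargmax(lls))
        lam_best = float(lams[best])
        if np.nanmax(lls) - np.nanmin(lls) < 1e-12:
            logger.warning("flat lambda profile; reporting boundary lambda=%g", lam_best)
        elif refine and 0 < best < len(lams) - 1:
            lo, hi = float(lams[best - 1]), float(lams[best + 1])
            opt = optimize.minimize_scalar(
                lambda l: -self.loglik_lambda(l), bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if np.isfinite(opt.fun) and -opt.fun >= lls[best]:
                lam_best = float(opt.x)
        return self.fit(lam=lam_best)


# -- functional wrappers ----------------------------------------------------

def profile_lambda(y, X, tree: PhyloTree, grid_size: int = 500,
                   seed: int | None = None, grid: str = "deterministic",
                   names: list[str] | None = None) -> PGLSResults:
    """Profile Pagel's lambda and return the maximum-likelihood fit."""
    model = PGLS(y, X, tree=tree, names=names)
    return model.fit(grid_size=grid_size, grid=grid, seed=seed)


def standardized_fit(table, response: str, predictors: list[str], tree: PhyloTree,
                     grid_size: int = 500, seed: int | None = None,
                     standardize_after_deletion: bool = True) -> PGLSResults:
    """Transform, Z-standardize, listwise-delete and profile-fit a trait model.

    ``table`` is a :class:`pglspath.traits.TraitTable`.  Transforms declared on
    the table (log / logit) are applied first; standardization uses the
    analysis subset after listwise deletion by default (switchable, since
    standardizing on the full table before deletion is an equally defensible
    convention).
    """
    from .traits import TraitTable

    if not isinstance(table, TraitTable):
        raise TypeError("table must be a TraitTable")
    cols = [response] + list(predictors)
    df = table.transformed(cols)
    if not standardize_after_deletion:
        df = (df - df.mean()) / df.std(ddof=1)
    df = df.dropna()
    common = [s for s in df.index if s in set(tree.tip_labels)]
    n_dropped = len(df) - len(common)
    if n_dropped:
        logger.warning("dropping %d species absent from the tree", n_dropped)
    df = df.loc[common]
    if len(df) < 3:
        raise InsufficientDataError(f"only {len(df)} complete cases for {cols}")
    if standardize_after_deletion:
        df = (df - df.mean()) / df.std(ddof=1)
    # pruning + covariance construction dominate repeated fits on the same
    # species subset (model selection, path analysis); memoize per tree
    cache = tree.__dict__.setdefault("_subset_cov_cache", {})
    key = tuple(sorted(df.index))
    if key not in cache:
        sub = tree.prune_to(list(df.index))
        cache[key] = vcv_matrix(sub)
    cov = cache[key]
    df = df.loc[cov.species_order]
    y = df[response].to_numpy()
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy() for p in predictors])
    model = PGLS(y, X, cov=cov, names=["const"] + list(predictors))
    res = model.fit(grid_size=grid_size, seed=seed)
    res.extra["response"] = response
    res.extra["species"] = list(df.index)
    return res


def weighted_fit(y, X, tree: PhyloTree, effort, names: list[str] | None = None,
                 grid_size: int = 500) -> PGLSResults:
    """Sampling-effort-weighted PGLS.

    Within-species sampling noise is modelled by inflating the diagonal:
    V_eff = V(lambda) + (c / effort) I, with lambda profiled at c = 0 first
    and the scale c >= 0 then estimated by maximum likelihood.  Species
    observed over more broods therefore carry more weight.  The returned
    log-likelihood is AICc-comparable with the unweighted fit.
    """
    effort = np.asarray(effort, dtype=float)
    if np.any(effort < 1) or np.any(effort != np.round(effort)):
        raise ValueError("effort must be integers >= 1 per species")
    base = PGLS(y, X, tree=tree, names=names)
    unweighted = base.fit(grid_size=grid_size)
    lam = unweighted.lambda_hat
    Vl = lambda_transform(base.cov, lam).matrix

    def negll(log_c: float) -> float:
        c = math.exp(log_c)
        M = Vl + np.diag(c / effort)
        try:
            res = fit_gls(y, X, M, names=names, lambda_hat=lam)
        except np.linalg.LinAlgError:
            return np.inf
        return -res.llf

    opt = optimize.minimize_scalar(negll, bounds=(-12.0, 12.0), method="bounded")
    c_hat = math.exp(float(opt.x))
    if -opt.fun <= unweighted.llf + 1e-9:
        c_hat = 0.0
        res = unweighted
    else:
        res = fit_gls(y, X, Vl + np.diag(c_hat / effort), names=names, lambda_hat=lam)
    res.extra["c_hat"] = c_hat
    res.extra["effort"] = effort
    return res


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (midrank ties, t-approximation p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InsufficientDataError("need at least 3 paired complete observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=int(x.size))


def vif(X: np.ndarray, names: list[str] | None = None,
        has_intercept: bool = True) -> pd.Series:
    """Variance inflation factors for each non-intercept predictor.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing predictor j on
    the remaining predictors (plus intercept).  Pass the lambda-whitened
    design to obtain VIFs in the GLS geometry.  Perfect collinearity yields
    ``inf``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if has_intercept:
        P = X[:, 1:]
        pnames = names[1:] if names else [f"x{j}" for j in range(1, X.shape[1])]
    else:
        P = X
        pnames = names if names else [f"x{j}" for j in range(X.shape[1])]
    if P.shape[1] < 2:
        raise ValueError("VIF requires at least 2 predictors")
    out = {}
    n = P.shape[0]
    ones = np.ones((n, 1))
    for j, name in enumerate(pnames):
        yj = P[:, j]
        Z = np.hstack([ones, np.delete(P, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        rss = float(resid @ resid)
        if tss <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - rss / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
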