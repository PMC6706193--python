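"""AICc multimodel inference: candidate sets, ranking, nested-model filtering,
evidence ratios and model averaging with partial-SD standardization.

The workflow mirrors standard information-theoretic practice for comparative
regressions: enumerate an a-priori candidate set of predictor combinations,
rank by AICc, keep the plausible subset (delta AICc < 10), drop models that
are merely more complex versions of better-supported nested models ("truly
competing" filter, after Anderson/Arnold), recalculate Akaike weights over
the survivors, and average coefficients across that subset substituting zero
where a predictor is absent.  Coefficients are standardized by their partial
standard deviations (Cade 2015), which deflate each predictor's SD by the
square root of its variance inflation factor so that collinear predictors are
not over-credited in the averaged ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pgls import PGLSResults, vif

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateModel",
    "ModelSelectionResult",
    "enumerate_candidates",
    "aicc",
    "akaike_weights",
    "truly_competing_filter",
    "evidence_ratio",
    "partial_sd_standardize",
    "model_average",
    "ModelSelection",
]


@dataclass
class CandidateModel:
    """One fitted candidate: a predictor set with its AICc bookkeeping."""

    predictors: tuple
    aicc: float
    K: int
    fit: PGLSResults | None = None
    delta_aicc: float = float("nan")
    rel_likelihood: float = float("nan")
    weight: float = float("nan")
    std_estimates: dict = field(default_factory=dict)
    std_errors: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return " + ".join(self.predictors) if self.predictors else "Null"


@dataclass
class ModelSelectionResult:
    """Ranked candidates, the truly competing subset, and averaged estimates."""

    models: list  # all candidates, ranked by AICc
    competitive: list  # truly competing subset with recalculated weights
    averaged: pd.DataFrame  # beta, SE, importance per predictor

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "predictors": m.name,
                "K": m.K,
                "AICc": m.aicc,
                "dAICc": m.delta_aicc,
                "L": m.rel_likelihood,
                "weight": m.weight,
            }
            for m in self.models
        ]
        return pd.DataFrame(rows)

    def competitive_table(self) -> pd.DataFrame:
        rows = [
            {
                "predictors": m.name,
                "K": m.K,
                "AICc": m.aicc,
                "dAICc": m.delta_aicc,
                "weight": m.weight,
            }
            for m in self.competitive
        ]
        return pd.DataFrame(rows)


def enumerate_candidates(
    predictors: list[str],
    min_size: int = 1,
    max_size: int | None = None,
    forbidden_pair_with_others: tuple[str, str] | None = None,
    include_null: bool = True,
) -> list[tuple]:
    """Enumerate predictor subsets within size bounds.

    ``forbidden_pair_with_others`` excludes every subset containing both
    members of the pair together with at least one additional predictor (the
    bare pair itself stays in the set).  The null (empty) model is appended
    when ``include_null``.
    """
    predictors = list(predictors)
    if len(set(predictors)) != len(predictors):
        raise ValueError("predictors must be unique")
    if forbidden_pair_with_others is not None:
        a, b = forbidden_pair_with_others
        if a not in predictors or b not in predictors:
            raise ValueError(f"forbidden pair {forbidden_pair_with_others} not among predictors")
    if max_size is None:
        max_size = len(predictors)
    out: list[tuple] = []
    lo = max(min_size, 1)
    for size in range(lo, max_size + 1):
        for combo in combinations(predictors, size):
            if forbidden_pair_with_others is not None:
                a, b = forbidden_pair_with_others
                if a in combo and b in combo and size > 2:
                    continue
            out.append(combo)
    if include_null or min_size == 0:
        out.append(())
    return out


def aicc(logLik: float, K: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n - K - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, K={K} (need n > K + 1)")
    return -2.0 * logLik + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i / 2) normalized to sum 1."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def rank_models(models: list[CandidateModel]) -> list[CandidateModel]:
    """Sort by AICc and fill delta, relative likelihood and weight columns."""
    ranked = sorted(models, key=lambda m: (m.aicc, len(m.predictors)))
    best = ranked[0].aicc
    weights = akaike_weights([m.aicc for m in ranked])
    for m, w in zip(ranked, weights):
        m.delta_aicc = m.aicc - best
        m.rel_likelihood = math.exp(-m.delta_aicc / 2.0)
        m.weight = float(w)
    return ranked


def truly_competing_filter(
    models: list[CandidateModel], delta_threshold: float = 10.0
) -> list[CandidateModel]:
    """Plausible subset with more-complex nested versions removed.

    A model survives if its delta AICc is below the threshold and its
    predictor set is not a strict superset of any already-retained model with
    lower (or tied — parsimony breaks ties) AICc.  Weights are recalculated
    over the survivors.
    """
    ranked = rank_models(list(models))
    top = [m for m in ranked if m.aicc - ranked[0].aicc < delta_threshold]
    kept: list[CandidateModel] = []
    for m in top:
        mset = set(m.predictors)
        if any(set(k.predictors) < mset for k in kept):
            continue
        kept.append(m)
    weights = akaike_weights([m.aicc for m in kept])
    out = []
    for m, w in zip(kept, weights):
        m2 = CandidateModel(
            predictors=m.predictors,
            aicc=m.aicc,
            K=m.K,
            fit=m.fit,
            delta_aicc=m.aicc - kept[0].aicc,
            rel_likelihood=math.exp(-(m.aicc - kept[0].aicc) / 2.0),
            weight=float(w),
            std_estimates=dict(m.std_estimates),
            std_errors=dict(m.std_errors),
        )
        out.append(m2)
    return out


def evidence_ratio(model_a: CandidateModel | float, model_b: CandidateModel | float) -> float:
    """Evidence ratio in favour of model a: exp((AICc_b - AICc_a) / 2)."""
    a = model_a.aicc if isinstance(model_a, CandidateModel) else float(model_a)
    b = model_b.aicc if isinstance(model_b, CandidateModel) else float(model_b)
    return math.exp((b - a) / 2.0)


def partial_sd_standardize(
    fit: PGLSResults, X: np.ndarray, y: np.ndarray, names: list[str] | None = None
) -> tuple[dict, dict]:
    """Standardize slopes (and SEs) by partial standard deviations.

    s*_j = s_{x_j} * VIF_j^{-1/2} * sqrt((n - 1) / (n - p)), and
    beta*_j = beta_j * s*_j / s_y, with p the number of coefficients
    (intercept included).  With a single predictor VIF_j = 1.  Infinite VIFs
    (perfect collinearity) make the standardized estimate undefined (NaN).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if names is None:
        names = fit.exog_names
    s_y = float(np.std(y, ddof=1))
    n_pred = p - 1  # excluding the intercept
    if n_pred >= 2:
        vifs = vif(X, names=names, has_intercept=True)
    else:
        vifs = pd.Series({names[1]: 1.0}) if n_pred == 1 else pd.Series(dtype=float)
    est, err = {}, {}
    for j in range(1, p):
        name = names[j]
        v = float(vifs[name])
        s_x = float(np.std(X[:, j], ddof=1))
        if not np.isfinite(v):
            logger.warning("infinite VIF for %s: standardized estimate undefined", name)
            est[name] = float("nan")
            err[name] = float("nan")
            continue
        s_star = s_x / math.sqrt(v) * math.sqrt((n - 1) / (n - p))
        est[name] = fit.params[j] * s_star / s_y
        err[name] = fit.bse[j] * s_star / s_y
    return est, err


def model_average(competitive: list[CandidateModel], predictors: list[str] | None = None) -> pd.DataFrame:
    """Average standardized estimates over a competing subset.

    Estimates (and errors) are substituted by zero in models where a
    predictor is absent; importance is the magnitude of each averaged
    estimate relative to the largest one.
    """
    if not competitive:
        raise ValueError("competitive subset is empty")
    if predictors is None:
        seen: list[str] = []
        for m in competitive:
            for p in m.predictors:
                if p not in seen:
                    seen.append(p)
        predictors = seen
    w = np.array([m.weight for m in competitive], dtype=float)
    w = w / w.sum()
    beta_bar, se_bar = {}, {}
    for p in predictors:
        b = np.array([m.std_estimates.get(p, 0.0) for m in competitive], dtype=float)
        s = np.array([m.std_errors.get(p, 0.0) for m in competitive], dtype=float)
        beta_bar[p] = float(np.sum(w * b))
        se_bar[p] = float(np.sum(w * s))
    mags = {p: abs(v) for p, v in beta_bar.items()}
    max_mag = max(mags.values()) if mags else 0.0
    importance = {
        p: (mags[p] / max_mag if max_mag > 0 else 0.0) for p in predictors
    }
    return pd.DataFrame(
        {
            "beta": pd.Series(beta_bar),
            "SE": pd.Series(se_bar),
            "importance": pd.Series(importance),
        }
    ).loc[predictors]


class ModelSelection:
    """IT-based model selection over PGLS fits of a trait table.

    Statsmodels-style: construct with the data and candidate specification,
    call :meth:`fit` to obtain a :class:`ModelSelectionResult`.
    """

    def __init__(
        self,
        table,
        response: str,
        predictors: list[str],
        tree,
        min_size: int = 1,
        max_size: int | None = None,
        forbidden_pair: tuple[str, str] | None = None,
        include_null: bool = True,
        delta_threshold: float = 10.0,
        grid_size: int = 500,
    ):
        self.table = table
        self.response = response
        self.predictors = list(predictors)
        self.tree = tree
        self.candidates = enumerate_candidates(
            self.predictors,
            min_size=min_size,
            max_size=max_size,
            forbidden_pair_with_others=forbidden_pair,
            include_null=include_null,
        )
        self.delta_threshold = delta_threshold
        self.grid_size = grid_size

    def fit(self) -> ModelSelectionResult:
        from .pgls import standardized_fit

        fitted: list[CandidateModel] = []
        for combo in self.candidates:
            res = standardized_fit(
                self.table, self.response, list(combo), self.tree, grid_size=self.grid_size
            )
            n = res.nobs
            K = res.K
            a = aicc(res.llf, K, n)
            cm = CandidateModel(predictors=tuple(combo), aicc=a, K=K, fit=res)
            if combo:
                sp = res.extra["species"]
                df = self.table.transformed([self.response] + list(combo)).loc[sp]
                df = (df - df.mean()) / df.std(ddof=1)
                X = np.column_stack(
                    [np.ones(len(df))] + [df[p].to_numpy() for p in combo]
                )
                y = df[self.response].to_numpy()
                est, err = partial_sd_standardize(res, X, y, names=["const"] + list(combo))
                cm.std_estimates, cm.std_errors = est, err
            fitted.append(cm)
        ranked = rank_models(fitted)
        competitive = truly_competing_filter(ranked, self.delta_threshold)
        averaged = model_average(competitive, predictors=self.predictors)
        return ModelSelectionResult(models=ranked, competitive=competitive, averaged=averaged)
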