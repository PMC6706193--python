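"""End-to-end study pipeline: fit, select, average, path-analyze, report.

Reproduces the table structure of a comparative analysis of broodmate
aggression: pairwise PGLS fits among behaviour and life-history traits,
IT-based model selection over life-history predictors (with the collinear
body-mass / nestling-period pair barred from entering together with other
predictors), ecological predictor screening with redundancy pruning,
combined ecological + life-history selection, and confirmatory path analysis
over the three evolutionary scenarios.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .model_selection import ModelSelection, aicc
from .path_analysis import PathAnalysis, scenario_layouts
from .pgls import spearman, standardized_fit
from .traits import TraitTable, transform_pipeline
from .trees import PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["StudyReport", "run_study", "redundancy_prune", "path_table"]

#: pairwise models mirroring the structure of the trait-correlation table
PAIRWISE_MODELS = [
    ("aggression", ["provisioning_rate"]),
    ("aggression", ["body_mass"]),
    ("aggression", ["clutch_size"]),
    ("aggression", ["nestling_period"]),
    ("aggression", ["feeding_method"]),
    ("aggression", ["provisioning_rate", "body_mass"]),
    ("aggression", ["clutch_size", "body_mass"]),
    ("aggression", ["nestling_period", "body_mass"]),
    ("provisioning_rate", ["body_mass"]),
    ("provisioning_rate", ["clutch_size"]),
    ("provisioning_rate", ["nestling_period"]),
    ("provisioning_rate", ["feeding_method"]),
    ("provisioning_rate", ["clutch_size", "body_mass"]),
    ("provisioning_rate", ["nestling_period", "body_mass"]),
    ("feeding_method", ["body_mass"]),
    ("feeding_method", ["clutch_size"]),
    ("feeding_method", ["nestling_period"]),
    ("clutch_size", ["body_mass"]),
    ("clutch_size", ["nestling_period"]),
    ("nestling_period", ["body_mass"]),
]

LIFE_HISTORY_PREDICTORS = [
    "clutch_size", "provisioning_rate", "feeding_method", "body_mass", "nestling_period",
]

ECOLOGICAL_PREDICTORS = [
    "breeding_months", "migration", "max_altitude",
    "agile_prey", "warm_blooded_prey", "diet_breadth",
    "mean_gpp", "min_gpp", "max_gpp", "mean_gpp_breeding",
    "annual_range_gpp", "annual_sd_gpp", "sd_min_gpp", "sd_max_gpp",
    "sd_gpp_all", "sd_gpp_breeding",
]


@dataclass
class StudyReport:
    """All result tables of one pipeline run plus reproducibility metadata."""

    pairwise: pd.DataFrame
    life_history_selection: pd.DataFrame
    life_history_competitive: pd.DataFrame
    life_history_averaged: pd.DataFrame
    ecological_screen: pd.DataFrame
    ecological_selection: pd.DataFrame | None
    ecological_averaged: pd.DataFrame | None
    path_models: pd.DataFrame | None
    path_averaged: pd.DataFrame | None
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "pairwise.tsv": self.pairwise,
            "life_history_selection.tsv": self.life_history_selection,
            "life_history_competitive.tsv": self.life_history_competitive,
            "life_history_averaged.tsv": self.life_history_averaged,
            "ecological_screen.tsv": self.ecological_screen,
            "ecological_selection.tsv": self.ecological_selection,
            "ecological_averaged.tsv": self.ecological_averaged,
            "path_models.tsv": self.path_models,
            "path_averaged.tsv": self.path_averaged,
        }
        for name, df in tables.items():
            if df is None:
                continue
            df.round(3).to_csv(out / name, sep="\t")
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def path_table(table: TraitTable) -> TraitTable:
    """Derive the standardized path-analysis variables from observables.

    BM = log body mass, CS = log clutch size, NP = log nestling period,
    PR = log circadian provisioning rate, AG = aggression score (numeric).
    """
    d = table.data
    out = pd.DataFrame(index=d.index)
    out["BM"] = transform_pipeline(d["body_mass"], "log")
    out["CS"] = transform_pipeline(d["clutch_size"], "log")
    out["NP"] = transform_pipeline(d["nestling_period"], "log")
    out["PR"] = transform_pipeline(d["provisioning_rate"] * 24.0, "log")
    out["AG"] = d["aggression"].astype(float)
    return TraitTable(out, transforms={})


def redundancy_prune(table: TraitTable, tree: PhyloTree, variables: list[str],
                     response: str = "aggression", threshold: float = 0.7,
                     grid_size: int = 500) -> list[str]:
    """Keep one representative per group of highly correlated predictors.

    Variables whose pairwise |Spearman rho| >= threshold are grouped
    (transitively); within each group the variable whose single-predictor
    PGLS of the response has the lowest AICc is retained.
    """
    variables = [v for v in variables if v in table.data.columns]
    if not variables:
        return []
    parent = {v: v for v in variables}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            sub = table.data[[a, b]].dropna()
            if len(sub) < 3:
                continue
            try:
                rho = spearman(sub[a], sub[b]).rho
            except ValueError:
                continue
            if abs(rho) >= threshold:
                parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for v in variables:
        groups.setdefault(find(v), []).append(v)
    kept = []
    for members in groups.values():
        if len(members) == 1:
            kept.append(members[0])
            continue
        scores = {}
        for v in members:
            res = standardized_fit(table, response, [v], tree, grid_size=grid_size)
            scores[v] = aicc(res.llf, res.K, res.nobs)
        winner = min(scores, key=scores.get)
        dropped = sorted(set(members) - {winner})
        logger.info("redundancy prune: keeping %s, dropping %s", winner, dropped)
        kept.append(winner)
    return sorted(kept, key=variables.index)


def _pairwise_table(table: TraitTable, tree: PhyloTree, grid_size: int) -> pd.DataFrame:
    rows = []
    for response, predictors in PAIRWISE_MODELS:
        if response not in table.data.columns or any(
            p not in table.data.columns for p in predictors
        ):
            continue
        res = standardized_fit(table, response, predictors, tree, grid_size=grid_size)
        row = {
            "model": f"{response} ~ " + " + ".join(predictors),
            "lambda": res.lambda_hat,
            "beta": res.params[1],
            "SE": res.bse[1],
            "t": res.tvalues[1],
            "df": res.df_resid,
            "p": res.pvalues[1],
            "n": res.nobs,
        }
        if len(predictors) == 1:
            sub = table.data[[response, predictors[0]]].dropna()
            corr = spearman(sub[response], sub[predictors[0]])
            row["spearman"] = corr.rho
            row["spearman_p"] = corr.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def _ecological_screen(table: TraitTable, tree: PhyloTree, eco: list[str],
                       grid_size: int) -> pd.DataFrame:
    rows = []
    for response in ("aggression", "provisioning_rate", "clutch_size", "feeding_method"):
        if response not in table.data.columns:
            continue
        for var in eco:
            try:
                res = standardized_fit(table, response, [var], tree, grid_size=grid_size)
            except Exception as exc:
                logger.warning("screen %s ~ %s failed: %s", response, var, exc)
                continue
            rows.append(
                {
                    "response": response,
                    "predictor": var,
                    "lambda": res.lambda_hat,
                    "beta": res.params[1],
                    "SE": res.bse[1],
                    "p": res.pvalues[1],
                    "n": res.nobs,
                }
            )
    return pd.DataFrame(rows)


def attach_gpp_summaries(table: TraitTable, gpp: dict) -> TraitTable:
    """Merge per-species GPP summary variables into the trait table."""
    from .traits import gpp_summaries

    rows = {sp: gpp_summaries(series) for sp, series in gpp.items()}
    summ = pd.DataFrame.from_dict(rows, orient="index")
    merged = table.data.join(summ, how="left")
    return TraitTable(merged, transforms=dict(table.transforms))


def run_study(tree: PhyloTree, table: TraitTable, gpp: dict | None = None,
              config: dict | None = None) -> StudyReport:
    """Execute the full comparative pipeline and collect all report tables.

    ``config`` keys (all optional): ``lambda_grid`` (default 500),
    ``delta_threshold`` (10), ``redundancy_threshold`` (0.7), ``seed`` (0),
    ``run_ecological_selection`` (True), ``run_path_analysis`` (True),
    ``life_history_predictors``, ``ecological_predictors``, ``path_dags``.
    """
    cfg = dict(config or {})
    grid = int(cfg.get("lambda_grid", 500))
    delta = float(cfg.get("delta_threshold", 10.0))
    seed = int(cfg.get("seed", 0))
    overlap = set(tree.tip_labels) & set(table.species)
    if len(overlap) < 3:
        raise ValueError("fewer than 3 species shared between tree and trait table")

    if gpp:
        table = attach_gpp_summaries(table, gpp)

    metadata = {
        "seed": seed,
        "version": __version__,
        "n_species_table": len(table.species),
        "n_species_tree": tree.n_tips,
        "lambda_grid": grid,
    }

    pairwise = _pairwise_table(table, tree, grid)

    lh_predictors = list(
        cfg.get("life_history_predictors", LIFE_HISTORY_PREDICTORS)
    )
    lh_predictors = [p for p in lh_predictors if p in table.data.columns]
    forbidden = None
    if "body_mass" in lh_predictors and "nestling_period" in lh_predictors:
        forbidden = ("body_mass", "nestling_period")
    sel = ModelSelection(
        table, "aggression", lh_predictors, tree,
        min_size=1, max_size=min(4, len(lh_predictors)),
        forbidden_pair=forbidden, include_null=True,
        delta_threshold=delta, grid_size=grid,
    ).fit()
    metadata["n_life_history_models"] = len(sel.models)
    metadata["n_life_history_competitive"] = len(sel.competitive)

    eco_all = list(cfg.get("ecological_predictors", ECOLOGICAL_PREDICTORS))
    eco_all = [v for v in eco_all if v in table.data.columns]
    screen = _ecological_screen(table, tree, eco_all, grid)

    eco_sel_table = None
    eco_avg = None
    if cfg.get("run_ecological_selection", True) and eco_all:
        pruned = redundancy_prune(
            table, tree, eco_all,
            threshold=float(cfg.get("redundancy_threshold", 0.7)), grid_size=grid,
        )
        metadata["ecological_predictors_pruned"] = pruned
        combined = pruned + [
            p for p in ("clutch_size", "provisioning_rate") if p in table.data.columns
        ]
        eco_result = ModelSelection(
            table, "aggression", combined, tree,
            min_size=1, max_size=len(combined), include_null=True,
            delta_threshold=delta, grid_size=grid,
        ).fit()
        eco_sel_table = eco_result.summary_table()
        eco_avg = eco_result.averaged
        metadata["n_ecological_models"] = len(eco_result.models)

    path_models_table = None
    path_avg = None
    if cfg.get("run_path_analysis", True):
        ptable = path_table(table)
        dags = cfg.get("path_dags")
        if dags is None:
            dags = []
            for root in ("PR", "BM", "CS"):
                dags.extend(scenario_layouts(root))
            # deduplicate identical edge sets arising from different roots
            seen, unique = set(), []
            for d in dags:
                if d.edge_key() in seen:
                    continue
                seen.add(d.edge_key())
                unique.append(d)
            dags = unique
        fitted = PathAnalysis(
            ptable, tree, dags, delta_threshold=delta, grid_size=grid
        ).fit()
        path_models_table = fitted.summary_table()
        path_avg = fitted.averaged
        metadata["n_path_models"] = len(fitted.results)
        metadata["n_path_competitive"] = len(fitted.competitive)

    return StudyReport(
        pairwise=pairwise,
        life_history_selection=sel.summary_table(),
        life_history_competitive=sel.competitive_table(),
        life_history_averaged=sel.averaged,
        ecological_screen=screen,
        ecological_selection=eco_sel_table,
        ecological_averaged=eco_avg,
        path_models=path_models_table,
        path_averaged=path_avg,
        metadata=metadata,
    )
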