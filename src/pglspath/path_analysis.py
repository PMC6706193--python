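"""Phylogenetic confirmatory path analysis via d-separation.

A causal hypothesis about a set of species traits is a directed acyclic graph
(DAG).  Its testable content is the basis set of conditional independencies:
one claim per non-adjacent vertex pair (X, Y), conditioning on the union of
their parents.  Each claim is tested by a PGLS regression (lambda profiled)
of the topologically later vertex on the earlier one plus the conditioning
set; the two-sided p-value of the earlier vertex's slope measures the claim.
Fisher's C = -2 sum(ln p_i) aggregates the k claims and is chi-squared with
2k degrees of freedom when the DAG is correct.  Competing DAGs are compared
by the C-statistic information criterion CICc = C + 2 q n / (n - 1 - q),
where q counts parameters (edges + vertices), with nested-model filtering and
CICc weights exactly as in AICc-based model selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model_selection import akaike_weights
from .pgls import standardized_fit
from .trees import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "CausalDAG",
    "IndependenceClaim",
    "PathAnalysisResult",
    "basis_set",
    "test_claims",
    "fisher_c",
    "cicc",
    "compare_path_models",
    "average_paths",
    "scenario_layouts",
    "PathAnalysis",
]

#: vertices of the life-history path models: body mass, clutch size,
#: nestling period, provisioning rate and aggression intensity
LIFE_HISTORY_VERTICES = ("BM", "CS", "NP", "PR", "AG")


@dataclass
class CausalDAG:
    """Directed acyclic trait model with aggression (AG) as a pure sink."""

    edges: list[tuple[str, str]]
    vertices: tuple = LIFE_HISTORY_VERTICES
    name: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.vertices)
        self.graph.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError(f"graph {self.name or self.edges} contains a cycle")
        if "AG" in self.vertices and self.graph.out_degree("AG") > 0:
            raise ValueError("AG must be a sink (never a causal predictor)")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def q(self) -> int:
        """Parameter count for CICc: edges + vertices."""
        return self.graph.number_of_edges() + len(self.vertices)

    def topological_order(self) -> list[str]:
        # deterministic: lexicographic among ties
        return list(nx.lexicographical_topological_sort(self.graph))

    def edge_key(self) -> frozenset:
        return frozenset(self.edges)

    @classmethod
    def from_edge_text(cls, text: str, name: str = "", scenario: str = "") -> "CausalDAG":
        """Parse an edge-list block with one 'A -> B' per line."""
        edges = []
        verts = set()
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, arrow, b = line.split()
            if arrow != "->":
                raise ValueError(f"bad edge line {line!r}")
            edges.append((a, b))
            verts.update((a, b))
        vertices = tuple(v for v in LIFE_HISTORY_VERTICES if v in verts) or tuple(sorted(verts))
        return cls(edges=edges, vertices=vertices, name=name, scenario=scenario)

    def to_edge_text(self) -> str:
        return "\n".join(f"{a} -> {b}" for a, b in sorted(self.edges))


@dataclass
class IndependenceClaim:
    """A conditional-independence claim (X _||_ Y | Z) implied by a DAG."""

    x: str  # topologically earlier vertex
    y: str  # topologically later vertex (regression response)
    conditioning: tuple
    p_value: float = float("nan")
    fit: object = None


@dataclass
class PathAnalysisResult:
    """Fisher's C test and CICc bookkeeping for one path model."""

    dag: CausalDAG
    claims: list
    C: float
    k: int
    df: int
    p_value: float
    q: int
    CICc: float
    delta_CICc: float = float("nan")
    rel_likelihood: float = float("nan")
    weight: float = float("nan")
    path_coefficients: dict = field(default_factory=dict)
    path_errors: dict = field(default_factory=dict)


def basis_set(dag: CausalDAG) -> list[IndependenceClaim]:
    """d-separation basis set: one claim per non-adjacent vertex pair.

    The conditioning set is the union of the parents of both vertices
    (excluding the pair itself); the earlier vertex in topological order is
    the tested predictor, the later one the regression response.  Claims are
    ordered canonically (topological, then lexicographic).
    """
    order = dag.topological_order()
    pos = {v: i for i, v in enumerate(order)}
    adjacent = {frozenset(e) for e in dag.edges}
    claims = []
    for x, y in combinations(order, 2):
        if frozenset((x, y)) in adjacent:
            continue
        parents = set(dag.graph.predecessors(x)) | set(dag.graph.predecessors(y))
        parents -= {x, y}
        claims.append(
            IndependenceClaim(x=x, y=y, conditioning=tuple(sorted(parents, key=pos.get)))
        )
    return claims


def test_claims(claims: list[IndependenceClaim], table, tree: PhyloTree,
                grid_size: int = 500, cache: dict | None = None) -> list[IndependenceClaim]:
    """Attach PGLS p-values to each independence claim.

    Each claim regresses the later vertex on the earlier plus the
    conditioning set, profiling lambda per regression; the p-value is the
    two-sided t-test of the earlier vertex's slope.  Identical claims recur
    across candidate DAGs, so an optional ``cache`` dict memoizes them.
    """
    out = []
    for claim in claims:
        key = (claim.x, claim.y, claim.conditioning)
        if cache is not None and key in cache:
            p, res = cache[key]
        else:
            predictors = [claim.x] + list(claim.conditioning)
            try:
                res = standardized_fit(table, claim.y, predictors, tree, grid_size=grid_size)
            except Exception as exc:
                raise RuntimeError(
                    f"cannot test claim ({claim.x} _||_ {claim.y} | {claim.conditioning}): {exc}"
                ) from exc
            j = res.exog_names.index(claim.x)
            p = float(res.pvalues[j])
            if cache is not None:
                cache[key] = (p, res)
        out.append(
            IndependenceClaim(
                x=claim.x, y=claim.y, conditioning=claim.conditioning,
                p_value=p, fit=res,
            )
        )
    return out


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C statistic: C = -2 sum(ln p), chi-squared with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if np.any(p == 0):
        logger.warning("claim p-value of 0: Fisher's C infinite (decisive rejection)")
        return float("inf"), 2 * k, 0.0
    C = -2.0 * float(np.sum(np.log(p)))
    df = 2 * k
    pv = float(stats.chi2.sf(C, df)) if k > 0 else 1.0
    return C, df, pv


def cicc(C: float, q: int, n: int) -> float:
    """C-statistic information criterion, small-sample corrected."""
    if n - 1 - q <= 0:
        raise ValueError(f"CICc undefined for q={q}, n={n} (need q < n - 1)")
    return C + 2.0 * q * n / (n - 1 - q)


def _evaluate_dag(dag: CausalDAG, table, tree: PhyloTree, n: int,
                  grid_size: int = 500, claim_cache: dict | None = None,
                  coef_cache: dict | None = None) -> PathAnalysisResult:
    claims = test_claims(basis_set(dag), table, tree, grid_size=grid_size, cache=claim_cache)
    C, df, p = fisher_c([c.p_value for c in claims])
    ci = cicc(C, dag.q, n)
    coeffs, errs = _edge_coefficients(dag, table, tree, grid_size=grid_size, cache=coef_cache)
    return PathAnalysisResult(
        dag=dag, claims=claims, C=C, k=len(claims), df=df, p_value=p,
        q=dag.q, CICc=ci, path_coefficients=coeffs, path_errors=errs,
    )


def _edge_coefficients(dag: CausalDAG, table, tree: PhyloTree,
                       grid_size: int = 500, cache: dict | None = None) -> tuple[dict, dict]:
    """Partial-SD-standardized PGLS coefficient for every edge of the DAG.

    Each child is regressed on all of its parents; the coefficient for edge
    (parent -> child) is the parent's standardized slope in that regression.
    The same child/parent-set regression recurs across DAGs and is memoized
    through ``cache`` when given.
    """
    from .model_selection import partial_sd_standardize

    coeffs: dict = {}
    errs: dict = {}
    for child in dag.vertices:
        parents = sorted(dag.graph.predecessors(child))
        if not parents:
            continue
        key = (child, tuple(parents))
        if cache is not None and key in cache:
            est, err = cache[key]
        else:
            res = standardized_fit(table, child, parents, tree, grid_size=grid_size)
            sp = res.extra["species"]
            df = table.transformed([child] + parents).loc[sp]
            df = (df - df.mean()) / df.std(ddof=1)
            X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy() for p in parents])
            y = df[child].to_numpy()
            est, err = partial_sd_standardize(res, X, y, names=["const"] + parents)
            if cache is not None:
                cache[key] = (est, err)
        for p in parents:
            coeffs[(p, child)] = est[p]
            errs[(p, child)] = err[p]
    return coeffs, errs


def compare_path_models(dags: list[CausalDAG], table, tree: PhyloTree,
                        alpha: float = 0.05, delta_threshold: float = 10.0,
                        grid_size: int = 500) -> tuple[list, list]:
    """Rank path models by CICc and select the truly competing subset.

    Plausible models have a nonsignificant C statistic (p > alpha); among
    those within the CICc threshold, models whose edge set is a strict
    superset of a better-supported retained model are removed, and CICc
    weights are recalculated over the survivors.

    Returns ``(all_results, competitive_results)``.
    """
    if not dags:
        raise ValueError("need at least one DAG")
    n = _common_n(dags, table, tree)
    claim_cache: dict = {}
    coef_cache: dict = {}
    results = [
        _evaluate_dag(d, table, tree, n, grid_size=grid_size,
                      claim_cache=claim_cache, coef_cache=coef_cache)
        for d in dags
    ]
    results.sort(key=lambda r: (r.CICc, r.dag.n_edges))
    best = results[0].CICc
    for r in results:
        r.delta_CICc = r.CICc - best
        r.rel_likelihood = math.exp(-r.delta_CICc / 2.0)
    competitive = select_competitive(results, alpha=alpha, delta_threshold=delta_threshold)
    return results, competitive


def select_competitive(results: list[PathAnalysisResult], alpha: float = 0.05,
                       delta_threshold: float = 10.0) -> list[PathAnalysisResult]:
    """Apply the plausibility + nested-model filter and recalculate weights."""
    ordered = sorted(results, key=lambda r: (r.CICc, r.dag.n_edges))
    plausible = [r for r in ordered if r.p_value > alpha]
    if not plausible:
        return []
    best = plausible[0].CICc
    top = [r for r in plausible if r.CICc - best < delta_threshold]
    kept: list[PathAnalysisResult] = []
    for r in top:
        eset = set(r.dag.edges)
        if any(set(k.dag.edges) < eset for k in kept):
            continue
        kept.append(r)
    weights = akaike_weights([r.CICc for r in kept])
    for r, w in zip(kept, weights):
        r.delta_CICc = r.CICc - kept[0].CICc
        r.rel_likelihood = math.exp(-r.delta_CICc / 2.0)
        r.weight = float(w)
    return kept


def average_paths(competitive: list[PathAnalysisResult]) -> pd.DataFrame:
    """CICc-weight-averaged standardized path coefficients per edge.

    Edges absent from a model contribute zero (estimate and error), mirroring
    the zero-substitution convention of AICc model averaging.
    """
    if not competitive:
        raise ValueError("competitive subset is empty")
    w = np.array([r.weight for r in competitive], dtype=float)
    w = w / w.sum()
    edges: list[tuple[str, str]] = []
    for r in competitive:
        for e in r.dag.edges:
            if e not in edges:
                edges.append(e)
    rows = []
    for e in edges:
        b = np.array([r.path_coefficients.get(e, 0.0) for r in competitive])
        s = np.array([r.path_errors.get(e, 0.0) for r in competitive])
        rows.append(
            {
                "edge": f"{e[0]} -> {e[1]}",
                "beta": float(np.sum(w * b)),
                "SE": float(np.sum(w * s)),
            }
        )
    return pd.DataFrame(rows).set_index("edge")


def _common_n(dags, table, tree) -> int:
    """Complete-case count over all variables used by the DAG set."""
    vars_used = sorted({v for d in dags for v in d.vertices})
    df = table.data[[v for v in vars_used if v in table.data.columns]]
    tips = set(tree.tip_labels)
    df = df.dropna()
    return int(sum(1 for s in df.index if s in tips))


def scenario_layouts(root: str, secondary_sets: list | None = None,
                     tertiary_vertices: tuple = ("CS", "PR", "NP"),
                     require_tertiary: bool = True,
                     require_coverage: bool = True) -> list[CausalDAG]:
    """Generate candidate DAGs for one evolutionary scenario.

    The root variable (PR = Provisioning, BM = Allometry, CS = Fecundity)
    may send primary edges to the other non-AG vertices (every nonempty
    subset).  Secondary edges run among the remaining non-root, non-AG
    vertices (every orientation of every pair subset, unless an explicit
    list of edge sets is supplied).  Tertiary edges point into AG from
    subsets of ``tertiary_vertices``.  ``require_coverage`` keeps only
    graphs where every non-root, non-AG vertex has at least one cause, so
    the root is the sole ultimate source.  Duplicated edge sets are removed;
    every output is acyclic with AG a sink.
    """
    scenario = {"PR": "Provisioning", "BM": "Allometry", "CS": "Fecundity"}.get(root)
    if scenario is None:
        raise ValueError(f"root must be one of PR, BM, CS; got {root!r}")
    others = [v for v in LIFE_HISTORY_VERTICES if v not in ("AG", root)]
    primary_all = [(root, v) for v in others]
    primary_sets = [
        list(combo)
        for size in range(1, len(primary_all) + 1)
        for combo in combinations(primary_all, size)
    ]
    if secondary_sets is None:
        pairs = list(combinations(others, 2))
        secondary_sets = [
            [e for e in choice if e is not None]
            for choice in product(*[(None, (a, b), (b, a)) for a, b in pairs])
        ]
    tertiary_sets = []
    for size in range(0, len(tertiary_vertices) + 1):
        for combo in combinations(tertiary_vertices, size):
            if require_tertiary and size == 0:
                continue
            tertiary_sets.append([(v, "AG") for v in combo])
    seen = set()
    out = []
    idx = 0
    for pri in primary_sets:
        for sec in secondary_sets:
            for ter in tertiary_sets:
                edges = pri + list(sec) + list(ter)
                key = frozenset(edges)
                if key in seen:
                    continue
                g = nx.DiGraph(edges)
                g.add_nodes_from(LIFE_HISTORY_VERTICES)
                if not nx.is_directed_acyclic_graph(g):
                    continue
                if require_coverage and any(g.in_degree(v) == 0 for v in others):
                    continue
                seen.add(key)
                idx += 1
                out.append(
                    CausalDAG(
                        edges=edges,
                        name=f"{root}_{idx:03d}",
                        scenario=scenario,
                    )
                )
    return out


class PathAnalysis:
    """Confirmatory path analysis over a set of candidate DAGs.

    Construct with the data and DAG set; :meth:`fit` runs every d-separation
    test, ranks by CICc, filters to the truly competing subset and averages
    the standardized path coefficients.
    """

    def __init__(self, table, tree: PhyloTree, dags: list[CausalDAG],
                 alpha: float = 0.05, delta_threshold: float = 10.0,
                 grid_size: int = 500):
        self.table = table
        self.tree = tree
        self.dags = list(dags)
        self.alpha = alpha
        self.delta_threshold = delta_threshold
        self.grid_size = grid_size

    def fit(self) -> "PathAnalysisFitted":
        results, competitive = compare_path_models(
            self.dags, self.table, self.tree,
            alpha=self.alpha, delta_threshold=self.delta_threshold,
            grid_size=self.grid_size,
        )
        averaged = average_paths(competitive) if competitive else pd.DataFrame()
        return PathAnalysisFitted(results=results, competitive=competitive, averaged=averaged)


@dataclass
class PathAnalysisFitted:
    results: list
    competitive: list
    averaged: pd.DataFrame

    def plot_averaged(self, ax=None):
        """Minimal diagram of the averaged causal model: arrow width is
        proportional to the magnitude of each averaged path coefficient."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(5, 4))
        if not len(self.averaged):
            raise ValueError("no averaged coefficients to plot")
        edges = []
        for label, row in self.averaged.iterrows():
            a, b = (s.strip() for s in label.split("->"))
            edges.append((a, b, float(row["beta"])))
        g = nx.DiGraph((a, b) for a, b, _ in edges)
        pos = nx.circular_layout(g)
        nx.draw_networkx_nodes(g, pos, ax=ax, node_color="#f0e6c8", node_size=1400)
        nx.draw_networkx_labels(g, pos, ax=ax)
        for a, b, beta in edges:
            nx.draw_networkx_edges(
                g, pos, edgelist=[(a, b)], ax=ax,
                width=0.5 + 4.0 * abs(beta), node_size=1400,
                edge_color="#444444" if beta >= 0 else "#aa3333",
            )
        nx.draw_networkx_edge_labels(
            g, pos, ax=ax,
            edge_labels={(a, b): f"{beta:.2f}" for a, b, beta in edges},
            font_size=8,
        )
        ax.set_axis_off()
        return ax

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "name": r.dag.name,
                "scenario": r.dag.scenario,
                "C": r.C,
                "k": r.k,
                "p": r.p_value,
                "CICc": r.CICc,
                "dCICc": r.delta_CICc,
                "L": r.rel_likelihood,
                "weight": r.weight,
                "direct_AG": ", ".join(
                    sorted(a for a, b in r.dag.edges if b == "AG")
                ),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)
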