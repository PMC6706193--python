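"""Synthetic comparative datasets with the structure the pipeline assumes.

Generates pure-birth (Yule) trees, causally structured traits with
phylogenetic signal, seasonal monthly-productivity series and ranked diet
profiles, emulating a 65-species raptor study: aggression on a 0-3 ordinal
scale (about 21% zeros and 48% top scores), provisioning-related fields
observed for configurable subsets (hourly provisioning 35, feeding method 57,
hunting success 40 species), and 15 years of monthly habitat productivity.

Traits are generated vertex by vertex along a true causal DAG: each trait is
a weighted sum of its parents plus phylogenetically correlated Gaussian noise
drawn from the lambda-scaled Brownian covariance (via its Cholesky factor),
with the residual variance chosen so every trait has unit marginal variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .path_analysis import CausalDAG
from .traits import DietProfile, GPPSeries, TraitTable
from .trees import PhyloTree, parse_newick, vcv_matrix

__all__ = [
    "SyntheticStudyConfig",
    "simulate_tree",
    "simulate_traits",
    "simulate_gpp",
    "build_study_fixture",
    "default_true_dag",
    "StudyFixture",
]


def default_true_dag() -> CausalDAG:
    """The default generating DAG: clutch size as the root cause.

    Clutch size drives provisioning rate and nestling period; provisioning
    rate drives body mass, which in turn lengthens the nestling period;
    aggression is caused directly by clutch size and provisioning rate.
    """
    return CausalDAG(
        edges=[
            ("CS", "PR"), ("CS", "NP"), ("PR", "BM"),
            ("BM", "NP"), ("CS", "AG"), ("PR", "AG"),
        ],
        name="fecundity_root",
        scenario="Fecundity",
    )


#: default standardized path coefficients on the latent scale
DEFAULT_COEFFICIENTS = {
    ("CS", "PR"): 0.24,
    ("CS", "NP"): -0.23,
    ("PR", "BM"): -0.27,
    ("BM", "NP"): 0.56,
    ("CS", "AG"): -0.27,
    ("PR", "AG"): -0.28,
}

#: default per-trait phylogenetic signal of the residual noise
DEFAULT_LAMBDAS = {"BM": 0.9, "CS": 0.8, "NP": 0.5, "PR": 0.6, "AG": 0.2}

#: latent-scale aggression thresholds: cumulative probabilities for the
#: ordinal classes 0/1/2/3 (about 21% zeros, 48% top category)
DEFAULT_AGGRESSION_QUANTILES = (14 / 65, 24 / 65, 34 / 65)


@dataclass
class SyntheticStudyConfig:
    """Generator settings for one synthetic comparative study."""

    seed: int = 0
    n_species: int = 65
    birth_rate: float = 1.0
    dag: CausalDAG = field(default_factory=default_true_dag)
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    lambdas: dict = field(default_factory=lambda: dict(DEFAULT_LAMBDAS))
    aggression_quantiles: tuple = DEFAULT_AGGRESSION_QUANTILES
    # per-column observed counts (rows beyond the count are set missing)
    n_feeding_method: int = 57
    n_hunting_success: int = 40
    n_hourly_provisioning: int = 35
    n_vultures: int = 2
    # GPP generator
    n_years: int = 15
    gpp_baseline: float = 100.0
    gpp_amplitude_range: tuple = (10.0, 80.0)
    gpp_within_year_sd: float = 5.0
    gpp_between_year_sd: float = 5.0

    def __post_init__(self) -> None:
        for cnt in (self.n_feeding_method, self.n_hunting_success, self.n_hourly_provisioning):
            if cnt > self.n_species:
                raise ValueError("missingness counts cannot exceed n_species")

    @classmethod
    def from_file(cls, path) -> "SyntheticStudyConfig":
        """Load a config from YAML or JSON; edge coefficients are given as
        {"A->B": value} mappings and the DAG as an edge list."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "coefficients" in raw:
            raw["coefficients"] = {
                tuple(s.strip() for s in k.split("->")): float(v)
                for k, v in raw["coefficients"].items()
            }
        if "dag" in raw:
            edges = [tuple(s.strip() for s in e.split("->")) for e in raw.pop("dag")]
            from .path_analysis import CausalDAG

            raw["dag"] = CausalDAG(edges=edges)
        if "aggression_quantiles" in raw:
            raw["aggression_quantiles"] = tuple(raw["aggression_quantiles"])
        if "gpp_amplitude_range" in raw:
            raw["gpp_amplitude_range"] = tuple(raw["gpp_amplitude_range"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# tree simulation

def simulate_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> PhyloTree:
    """Ultrametric pure-birth tree with total depth normalized to 1.

    Lineages split at exponential waiting times with total rate
    k * birth_rate; the lineage to split is chosen uniformly.  Deterministic
    given the seed (byte-identical Newick on re-run).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    # each lineage: (parent_id, start_time); nodes stored as dicts
    nodes = {0: {"parent": None, "start": 0.0, "children": []}}
    active = [0]
    next_id = 1
    t = 0.0
    # root immediately bifurcates into two lineages
    for _ in range(2):
        nodes[next_id] = {"parent": 0, "start": 0.0, "children": []}
        nodes[0]["children"].append(next_id)
        active.append(next_id)
        next_id += 1
    active.remove(0)
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        split = active[rng.integers(0, k)]
        nodes[split]["end"] = t
        active.remove(split)
        for _ in range(2):
            nodes[next_id] = {"parent": split, "start": t, "children": []}
            nodes[split]["children"].append(next_id)
            active.append(next_id)
            next_id += 1
    # final waiting time so tips do not end exactly at the last split
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    for tip in active:
        nodes[tip]["end"] = t
    depth = t if t > 0 else 1.0
    labels = {}
    width = len(str(n_species))
    for i, tip in enumerate(sorted(active)):
        labels[tip] = f"sp{i + 1:0{width}d}"

    def newick(node_id: int) -> str:
        node = nodes[node_id]
        length = (node.get("end", t) - node["start"]) / depth if node["parent"] is not None else 0.0
        if not node["children"]:
            return f"{labels[node_id]}:{length:.10f}"
        inner = ",".join(newick(c) for c in node["children"])
        return f"({inner}):{length:.10f}"

    return parse_newick(newick(0) + ";")


# ---------------------------------------------------------------------------
# trait simulation

def simulate_traits(tree: PhyloTree, dag: CausalDAG, coefficients: dict,
                    lambdas: dict, seed: int) -> pd.DataFrame:
    """Latent traits generated along the DAG with phylogenetic noise.

    Returns a species x vertex DataFrame on the standardized latent scale
    (unit marginal variance).  Raises if the coefficient specification leaves
    no room for residual noise (explained variance >= 1).
    """
    rng = np.random.default_rng(seed)
    V = vcv_matrix(tree)
    n = V.n
    M = V.matrix
    diag = np.diag(M)
    chol_cache: dict[float, np.ndarray] = {}

    def noise(lam: float) -> np.ndarray:
        if lam not in chol_cache:
            Vl = lam * M + (1.0 - lam) * np.diag(diag)
            # normalize to unit marginal variance, guard tiny negatives
            scale = np.sqrt(np.outer(diag, diag))
            C = Vl / scale
            C += 1e-10 * np.eye(n)
            chol_cache[lam] = np.linalg.cholesky(C)
        return chol_cache[lam] @ rng.standard_normal(n)

    # Track each trait's loadings on the independent per-vertex noise sources
    # so residual variances are exact (every noise source has unit marginal
    # variance per species), not estimated from a realization.
    values: dict[str, np.ndarray] = {}
    loadings: dict[str, dict[str, float]] = {}
    for v in dag.topological_order():
        parents = sorted(dag.graph.predecessors(v))
        lam = lambdas.get(v, 0.5)
        if not parents:
            values[v] = noise(lam)
            loadings[v] = {v: 1.0}
            continue
        combo = np.zeros(n)
        combo_load: dict[str, float] = {}
        for p in parents:
            c = coefficients.get((p, v))
            if c is None:
                raise KeyError(f"no coefficient supplied for edge {p} -> {v}")
            combo += c * values[p]
            for src, w in loadings[p].items():
                combo_load[src] = combo_load.get(src, 0.0) + c * w
        explained = sum(w * w for w in combo_load.values())
        resid_var = 1.0 - explained
        if resid_var < 0.01:
            raise ValueError(
                f"unstable coefficient specification: explained variance "
                f"{explained:.3f} >= 1 for {v}"
            )
        sigma = math.sqrt(resid_var)
        values[v] = combo + sigma * noise(lam)
        combo_load[v] = sigma
        loadings[v] = combo_load
    return pd.DataFrame(values, index=V.species_order)


# ---------------------------------------------------------------------------
# productivity simulation

def simulate_gpp(config: SyntheticStudyConfig, seed: int,
                 amplitude: float | None = None,
                 breeding_months: list[int] | None = None) -> GPPSeries:
    """One species' monthly GPP grid: baseline + seasonal sinusoid + noise.

    values[y, m] = baseline + amplitude * sin(2 pi (m - phase) / 12)
                   + year_effect[y] + month_noise, truncated at 0.
    """
    rng = np.random.default_rng(seed)
    if amplitude is None:
        amplitude = float(rng.uniform(*config.gpp_amplitude_range))
    if amplitude < 0 or config.gpp_within_year_sd < 0 or config.gpp_between_year_sd < 0:
        raise ValueError("amplitude and noise SDs must be nonnegative")
    phase = int(rng.integers(0, 12))
    months = np.arange(12)
    seasonal = amplitude * np.sin(2 * np.pi * (months - phase) / 12.0)
    year_effects = (
        rng.normal(0.0, config.gpp_between_year_sd, size=config.n_years)
        if config.gpp_between_year_sd > 0
        else np.zeros(config.n_years)
    )
    noise = (
        rng.normal(0.0, config.gpp_within_year_sd, size=(config.n_years, 12))
        if config.gpp_within_year_sd > 0
        else np.zeros((config.n_years, 12))
    )
    vals = config.gpp_baseline + seasonal[None, :] + year_effects[:, None] + noise
    vals = np.maximum(vals, 0.0)
    if breeding_months is None:
        start = int(rng.integers(0, 12))
        length = int(rng.integers(2, 7))
        breeding_months = [(start + i) % 12 for i in range(length)]
    return GPPSeries(vals, breeding_months)


# ---------------------------------------------------------------------------
# diet simulation

def _simulate_diet(rng: np.random.Generator) -> DietProfile:
    from .traits import PREY_CATEGORIES

    k = int(rng.integers(1, 10))
    cats = list(rng.choice(PREY_CATEGORIES, size=k, replace=False))
    # every species takes at least some warm-blooded prey, keeping the
    # reliance score defined for the whole table
    if "mammal" not in cats and "bird" not in cats:
        cats[rng.integers(0, len(cats))] = "mammal" if rng.random() < 0.5 else "bird"
    order = list(rng.permutation(len(cats)))
    ranks = {cats[i]: order.index(i) + 1 for i in range(len(cats))}
    return DietProfile(ranks=ranks)


# ---------------------------------------------------------------------------
# full study fixture

@dataclass
class StudyFixture:
    tree: PhyloTree
    table: TraitTable
    latents: pd.DataFrame
    gpp: dict  # species -> GPPSeries
    diets: dict  # species -> DietProfile
    config: SyntheticStudyConfig


def build_study_fixture(config: SyntheticStudyConfig | None = None) -> StudyFixture:
    """Generate a full synthetic study with realistic units and missingness.

    Latent standardized traits are mapped to observable scales (body mass in
    g, clutch size in eggs, nestling period in d, provisioning in feeds/hr)
    and aggression is discretized onto the 0-3 ordinal scale by thresholding
    its latent value at fixed normal quantiles.
    """
    from scipy import stats as sstats

    from .traits import agility_score, diet_breadth, warm_blooded_reliance

    if config is None:
        config = SyntheticStudyConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, seed=int(rng.integers(2**31)),
                         birth_rate=config.birth_rate)
    latents = simulate_traits(tree, config.dag, config.coefficients, config.lambdas,
                              seed=int(rng.integers(2**31)))
    species = list(latents.index)
    n = len(species)

    thresholds = sstats.norm.ppf(config.aggression_quantiles)
    ag = np.digitize(latents["AG"].to_numpy(), thresholds)

    body_mass = np.exp(math.log(1500.0) + 1.0 * latents["BM"].to_numpy())
    clutch = np.exp(math.log(2.5) + 0.3 * latents["CS"].to_numpy())
    nestling = np.exp(math.log(55.0) + 0.35 * latents["NP"].to_numpy())
    provisioning = np.exp(math.log(0.8) + 0.6 * latents["PR"].to_numpy())

    latitude_class = np.where(rng.random(n) < 0.5, "tropical", "temperate")
    migration = (rng.random(n) < 0.4).astype(int)
    breeding_months = rng.integers(2, 9, size=n)
    max_altitude = np.round(rng.uniform(200, 4500, size=n), 0)
    effort = rng.integers(1, 80, size=n)

    feeding_method = 1.0 / (1.0 + np.exp(-(0.8 * rng.standard_normal(n))))
    feeding_method = np.round(feeding_method, 3)
    hunting_success = 1.0 / (1.0 + np.exp(-(0.3 + 0.7 * rng.standard_normal(n))))
    hunting_success = np.round(np.clip(hunting_success, 0.01, 0.95), 3)

    vultures = list(rng.choice(species, size=config.n_vultures, replace=False))
    is_vulture = np.array([s in vultures for s in species])
    hunting_success[is_vulture] = 0.9

    diets = {s: _simulate_diet(rng) for s in species}
    breadth = np.array([diet_breadth(diets[s]) for s in species], dtype=float)
    warm = np.array([warm_blooded_reliance(diets[s]) for s in species])
    agile = np.array([agility_score(diets[s]) for s in species])

    df = pd.DataFrame(
        {
            "aggression": ag.astype(float),
            "clutch_size": clutch,
            "body_mass": body_mass,
            "nestling_period": nestling,
            "provisioning_rate": provisioning,
            "provisioning_rate_hourly": provisioning,
            "feeding_method": feeding_method,
            "hunting_success": hunting_success,
            "migration": migration.astype(float),
            "breeding_months": breeding_months.astype(float),
            "latitude_class": latitude_class,
            "max_altitude": max_altitude,
            "diet_breadth": breadth,
            "warm_blooded_prey": warm,
            "agile_prey": agile,
            "effort_broods": effort.astype(float),
            "is_vulture": is_vulture.astype(float),
        },
        index=pd.Index(species, name="species"),
    )

    # impose the configured missingness patterns
    def _mask(col: str, n_observed: int, keep=None) -> None:
        candidates = [s for s in species if keep is None or s not in keep]
        n_missing = n - n_observed
        miss = rng.choice(candidates, size=n_missing, replace=False)
        df.loc[miss, col] = np.nan

    _mask("feeding_method", config.n_feeding_method)
    _mask("hunting_success", config.n_hunting_success, keep=set(vultures))
    _mask("provisioning_rate_hourly", config.n_hourly_provisioning)

    gpp = {
        s: simulate_gpp(config, seed=int(rng.integers(2**31)))
        for s in species
    }

    table = TraitTable(df)
    return StudyFixture(tree=tree, table=table, latents=latents, gpp=gpp,
                        diets=diets, config=config)
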