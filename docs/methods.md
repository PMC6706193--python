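# Methods

`pglspath` implements the comparative-inference toolchain used to ask which
behavioural, life-history and ecological traits predict the intensity of
broodmate aggression across a clade (the motivating system is accipitrid
raptors, with aggression scored 0–3 per species), and which causal ordering
of those traits the data support. Three layers sit on top of each other:
phylogenetic generalized least squares (PGLS) with profiled Pagel's λ;
AICc-based multimodel inference with model averaging; and confirmatory path
analysis via d-separation.

## The PGLS model

For a response vector *y* over *n* species and design matrix *X* (intercept
included), the model is

    y = Xβ + ε,   ε ~ N(0, σ² V(λ)),

where V(1) is the Brownian-motion covariance of the phylogeny (entry (i, j)
is the branch length shared from the root to the most recent common
ancestor) and V(λ) multiplies the off-diagonal by λ ∈ [0, 1]. λ = 0 is a
star phylogeny (independent species); λ = 1 is pure Brownian motion.
Estimation is by maximum likelihood throughout — never REML — so that
log-likelihoods are comparable across fixed-effect structures in the AICc
layer.

Numerical choices:

- β is obtained by Cholesky whitening of V(λ) followed by least squares;
  σ²_ML = e'V⁻¹e/n enters the log-likelihood, while standard errors use the
  unbiased e'V⁻¹e/(n − p) scale so that V = I reproduces ordinary least
  squares exactly (this identity is tested to 1e-8).
- λ is profiled on a deterministic grid of 500 equally spaced points on
  [0, 1], and the grid maximizer is polished by bounded golden-section
  search. A seeded random-grid mode (500 uniform draws plus both endpoints)
  is provided for procedures specified that way; the deterministic grid is
  the default because it is exactly reproducible. A flat profile is reported
  at the boundary with a warning.
- When the covariance diagonal is constant (ultrametric tree), V(λ) shares
  V's eigenvectors, so the profile loop runs on a single eigendecomposition
  at O(n p²) per grid point. Non-ultrametric trees fall back to a Cholesky
  factorization per λ.
- Degrees of freedom are n − p; two-sided p-values come from the t
  distribution. Profiling λ is not charged a degree of freedom, matching
  common practice in the comparative literature; the simulation suite checks
  the resulting calibration empirically (coverage of β ± 2 SE between 0.90
  and 0.99 at n = 65).
- Collinear designs raise an error naming the dependent columns; a perfect
  linear fit (zero residuals) is flagged rather than reported with
  unbounded t statistics.

Missing data are handled by listwise deletion per model, so n varies by
analysis exactly as in datasets where provisioning, feeding-method and
hunting-success columns are observed for different species subsets.
Z-standardization (mean 0, sample SD 1) is applied on the analysis subset
after deletion by default; a switch standardizes on the full table first,
since either convention is defensible and the source procedure does not
say which was used.

Sampling-effort weighting models within-species noise by V(λ̂) + (c/effort)I
with the scalar c ≥ 0 estimated by ML after λ is profiled on the unweighted
model. Species observed over more broods therefore carry more weight; c = 0
recovers the unweighted fit, and the returned likelihood is AICc-comparable
with it.

## Variable definitions and transforms

Provisioning rates are circadian (feeds/day = feeds/hr × 24); conversions
back to hourly rates assume 12 daylight hours for tropical species
(|latitude| ≤ 23°) and 14 for temperate ones. Positively skewed variables
(body mass, clutch size, nestling period, provisioning rate) are natural-log
transformed. Proportions (feeding method, hunting success) are logit
transformed after mapping exact 1.0 to 0.95; an exact 0.0 (which does not
occur in the motivating data) is mapped symmetrically to 0.05 and logged.
All SDs are sample SDs (ddof = 1).

Diet profiles rank up to nine prey classes by importance (1 = most
important). Diet breadth is the count of classes present. Warm-blooded
reliance is the mean of the mammal and bird ranks (a single rank if only
one is present; missing — never zero — if neither is). Prey agility is the
weighted mean of class agility scores (1 carrion/worms … 5 birds); the
weighting of classes is not specified by the source, so the default weight
for a class at rank r is 1/r (normalized), exposed as an option. Hunting
success for obligate scavengers (vultures) is imputed at the stated maximum
of 0.9.

Habitat-productivity summaries operate on a years × 12 monthly grid
(default 15 years): overall mean/min/max, breeding-season mean over a month
mask, within-year seasonality (mean annual range, mean within-year SD) and
between-year variability (SD across years of yearly minima and maxima, SD
of all breeding-month values pooled — a per-year-mean variant was
considered and the pooled form chosen as the plainer reading — and SD of
all values). All summaries are invariant to permuting years.

## Model selection and averaging

Candidate sets enumerate predictor subsets within size bounds; a forbidden
pair (body mass and nestling period, Spearman ρ = .84 in the motivating
data) may not co-occur with any third predictor, which keeps variance
inflation factors below ~2.5. AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with
K = coefficients (incl. intercept) + 1 for the residual variance; λ is not
counted (this convention reproduces the published K column: null model
K = 2). Ranking, Akaike weights, the ΔAICc < 10 plausible subset, and the
"truly competing" filter — drop any model whose predictor set is a strict
superset of a retained model with lower AICc, then renormalize weights —
follow the Anderson/Arnold nesting rule; AICc ties are broken in favour of
the smaller model (parsimony). Evidence ratios are computed from AICc
differences, not from rounded weights.

Standardized coefficients use partial standard deviations (Cade 2015):
s*ⱼ = s_xⱼ·VIFⱼ^(−1/2)·√((n−1)/(n−p)), β*ⱼ = βⱼ·s*ⱼ/s_y, with VIFs computed
on the λ-whitened design for consistency with the GLS geometry. Model
averaging substitutes zero (estimate and error) where a predictor is absent
— the full-model-set "shrinkage" convention — and averaged SEs use the same
weighted average; the unconditional-variance formula is deliberately not
used because the replicated tables were produced with the simple form.
Importance is |β̄*ⱼ| relative to the largest |β̄*|.

## Confirmatory path analysis

Causal hypotheses are DAGs over {BM, CS, NP, PR, AG} with aggression (AG) a
pure sink. The testable content of a DAG is its d-separation basis set: one
conditional-independence claim per non-adjacent pair (X, Y), conditioning on
the union of the parents of both. Each claim is tested by a PGLS regression
(λ re-profiled per claim, mirroring per-model λ reporting) of the
topologically later vertex on the earlier plus the conditioning set; the
claim's p-value is the two-sided t-test of the earlier vertex's slope.
Fisher's C = −2Σln pᵢ is χ² with 2k df under the model; CICc =
C + 2qn/(n−1−q) with q = edges + vertices. The q convention is an inference
validated against two published CICc − C offsets (30.00 at C = 8.17 and
26.98 at C = 12.21, both consistent with q = edges + 5).

Model comparison keeps DAGs with nonsignificant C (p > 0.05), applies the
same nested filter on edge sets, renormalizes CICc weights, and averages
partial-SD-standardized path coefficients per edge with zero substitution
where an edge is absent.

`scenario_layouts` generates candidate DAGs for the three evolutionary
scenarios (root PR = Provisioning, BM = Allometry, CS = Fecundity):
nonempty subsets of root→other primary edges, every orientation of every
secondary pair among the non-root, non-AG vertices, and tertiary subsets of
{CS, PR, NP}→AG, keeping acyclic graphs in which every non-root vertex has
at least one cause. This is a general, documented generator — the exact
published enumeration grammar (1,225 paths) is not recoverable from the
main text — and explicit edge lists are accepted wherever exact replication
is required.

## Synthetic data generator

The generator defines the study conditions every statistical guarantee is
tested under: 65 species on an ultrametric pure-birth tree (depth
normalized to 1), traits produced vertex-by-vertex along a true DAG with
phylogenetically correlated Gaussian noise (Cholesky factor of the
λ-scaled covariance — exact, rather than edge-wise Brownian simulation),
and residual variances computed analytically from each trait's loadings on
the independent noise sources so every latent trait has marginal variance
exactly 1.

The default true DAG is the best-supported structure of the motivating
analysis — clutch size as root (CS→PR, CS→NP, PR→BM, BM→NP, CS→AG, PR→AG) —
with coefficient magnitudes taken from its reported averaged path
coefficients (0.24, −0.23, −0.27, 0.56, −0.27, −0.28). Default per-trait λ
of the noise (BM 0.9, CS 0.8, NP 0.5, PR 0.6, AG 0.2) reflect the strong
signal of size-related traits and the near-zero signal reported for
aggression. These defaults describe the generating process only; no test
asserts them back.

Observable scales: body mass is log-normal around 1,500 g, clutch size
around 2.5 eggs, nestling period around 55 d, provisioning around 0.8
feeds/hr (max ≈ 4 feeds/hr). Aggression is discretized 0–3 by thresholding
the latent trait at fixed normal quantiles chosen so that, in expectation,
21% of species score 0 and 48% score 3 (the 1-vs-2 split is even, as the
source does not report it). Missingness is imposed per column: feeding
method observed for 57, hunting success for 40 (vultures always observed,
imputed 0.9), hourly provisioning for 35 of 65 species. Monthly
productivity is baseline + seasonal sinusoid + year effects + month noise,
truncated at zero, over 15 years; ecological columns are generated
independently of the life-history DAG, so ecological-selection results on
synthetic data exercise the machinery, not a planted signal.

What the generator does not emulate: real taxon sampling, correlated
observation effort, non-Gaussian trait noise, spatially structured
productivity, or any coupling between ecology and life history. Passing
simulation tests therefore demonstrate the estimators' statistical
properties under the assumed model, not the field validity of the
motivating conclusions.

## Problem sizes used in the test suite

Simulation-based checks run at the dimensions the analyses target: n = 65
species for bias/coverage (200 replicates), power of the C-test against a
missing standardized effect of 0.6 (100 replicates), and its size under the
true DAG (500 replicates; empirically 0.07 at α = 0.05 — slightly above
nominal, as expected when λ is estimated per claim and claims share data);
λ recovery uses 200-tip trees (50 replicates). The orchestration tests use
reduced λ grids and small DAG sets; the statistical tests always use the
default 500-point grid.

## Known limitations

- The aggression score is treated as numeric, not ordinal; threshold models
  are out of scope.
- Only Pagel's λ is supported as a correlation model (no
  Ornstein–Uhlenbeck).
- Averaged SEs use weighted zero-substitution, which understates
  between-model variance relative to the unconditional-variance formula.
- The effort-weighted fit fixes λ at its unweighted estimate rather than
  re-profiling jointly with c.
- d-separation p-values assume Gaussian residuals; directional separation
  for non-Gaussian responses is not implemented.
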