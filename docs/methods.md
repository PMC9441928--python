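# Methods

This note records the statistical model, algorithmic choices, generator
assumptions and known limitations behind `rootpheno`. Notation: `x̄_W`,
`x̄_D` are a genotype's trait means under well-watered (WW) and drought (D)
treatments; traits follow the dictionary in `rootpheno.traits.DEFAULT_TRAITS`
(RXSA root cross-sectional area, TSA stele area, TCA cortical area, AA
aerenchyma area, LTA living tissue area, MXA/MXV metaxylem vessel area and
count, all areas mm²).

## Input model

Data are tidy plant-level tables keyed by (experiment, genotype, treatment,
replicate). Validation enforces numeric trait columns, nonnegativity for
areas/lengths/counts, integer counts, percentages in [0, 100], unique keys,
and canonical treatment labels (synonyms such as "well-watered" map to WW).
Genotype means are per (experiment, genotype, treatment, trait) with n−1 SD;
single-replicate cells are flagged, all-missing cells omitted. Result CSVs
are written with 12 significant digits so round-trips preserve values to
float precision.

## Derived traits

- `LTA = RXSA − AA − MXA` (optionally `− MXA·MXV` when treating all vessels
  as lumen). Negative results are retained but warned about — they indicate
  inconsistent upstream measurements and must stay visible.
- `percAA = 100·AA/TCA`.
- Axial hydraulic conductance from Hagen–Poiseuille with vessel area A
  (radius r, A = πr²): per vessel `πr⁴/(8η) = A²/(8πη)`, so
  `K = MXV·MXA²/(8πη)` with dynamic viscosity η = 8.9·10⁻⁴ Pa·s by default.
  Consequence tested: K scales with r⁴, i.e. quadratically in vessel area.
- Nodal root angle from a ring intersection at 7.5 cm depth:
  `arcsin(7.5/length)` in degrees; roots shorter than 7.5 cm are undefined.
  Deep roots are those with angle strictly > 30°. Deep-root proportion is
  root length in the 20–40 cm layers over total length across layers.

## Response statistics

- Plasticity: `100·(x̄_D − x̄_W)/x̄_W`, undefined (NaN, with warning) for
  x̄_W = 0. Scale-invariant by construction.
- Percent reduction per experiment: `100·(mean_WW − mean_D)/mean_WW` over
  genotype means with equal genotype weights (not plant-weighted).
- GCV: `100·σ/μ`. Among genotypes, σ is the n−1 SD of genotype means within
  an experiment × treatment and μ their mean. Within genotype, σ is the
  replicate SD; μ defaults to the grand mean of the experiment × treatment
  ("grand") so genotypes are comparable, with a per-genotype option
  ("local").
- ANOVA: statsmodels OLS + `anova_lm`, type I for balanced designs, type II
  otherwise; η² = 100·SS/SS_total, so effect shares plus the residual share
  sum to exactly 100. The interaction is dropped (with a warning) when a
  genotype × treatment cell is empty. Significance stars: *** ≤ 0.001,
  ** ≤ 0.01, * ≤ 0.05, + ≤ 0.1, else ns.
- Correlations: Pearson r on genotype means under drought per experiment,
  flagged significant at α = 0.1 by default, requiring ≥ 3 shared genotypes.

## Performance grouping

Within each experiment, genotypes whose WW biomass mean deviates more than
`sd_multiplier` (default 1) genotype-level SDs from the panel mean are
excluded (two-sided by default; a one-sided mode excludes only unusually
large plants). Retained genotypes split into best (< 50% drought biomass
reduction) and worst (> 50%); exact ties go to best by default. Group
contrasts use Welch's t per trait and treatment, requiring n ≥ 2 per group.

## Clustering (the from-scratch contribution)

PAM (partitioning around medoids) on Euclidean distances between z-scored
genotype means under drought, restricted to the retained genotypes.
Deterministic throughout:

- **BUILD**: first medoid minimizes total dissimilarity; each further medoid
  maximizes the decrease in total cost.
- **SWAP**: every (medoid, non-medoid) exchange is evaluated; the single
  best strictly improving swap (tolerance 10⁻¹²) is applied per iteration
  until none improves. Ties break to the lowest point index.

Silhouette widths follow the definition `s(i) = (b−a)/max(a,b)` with a the
mean within-cluster dissimilarity (self excluded) and b the smallest mean
dissimilarity to another cluster; singletons and fully degenerate partitions
score 0. k is selected by maximum average silhouette over k ∈ [2, 8] (ties
to the smaller k); the within-cluster sum of squared distances to medoids is
recorded for elbow inspection but never decides. Clusters are renumbered by
descending cluster-mean drought biomass (cluster 1 = best). PCA projections
(SVD, largest loading made positive per component) are provided for visual
checks only.

### Known limitation: local optima

BUILD+SWAP PAM is a local-search heuristic: it terminates at a single-swap
local optimum of the k-medoids objective, which is not always the global
optimum. On random small instances (n ≤ 9, k ≤ 3) it misses the exhaustive
optimum in roughly 7–10% of cases; the reference R implementation
(`cluster::pam`, the standard PAM) returns the identical non-global
solutions on the instances we checked, so this is inherent to the algorithm
rather than an implementation error. The acceptance test asserting 100%
global optimality therefore fails by design and documents the gap; the unit
suite instead asserts what PAM actually guarantees (monotone cost descent
and single-swap local optimality), which always holds.

## Integration across experiments

Per experiment, each cluster's central trait values (mean by default,
median optionally) are ranked per trait with 1 = greatest, ties sharing the
minimum rank. Ranks are normalized to (rank − 1)/(k − 1) ∈ [0, 1] so
experiments with different cluster counts are comparable; traits an
experiment did not measure stay missing. The distance between two cluster
profiles is the Euclidean distance over their shared traits divided by
√(#shared) (range [0, 1]; ≥ 2 shared traits required, otherwise the maximum
distance 1 with a warning). Average-linkage agglomeration (scipy) is cut at
G groups (default 6, reduced with a warning if fewer clusters exist), and
groups are renumbered by ascending mean normalized biomass rank — group 1 is
always the best-performing. A rank heatmap (CSV + PNG, yellow = rank 1) is
written for inspection.

## Allometry

For each (y trait, x trait) pair, integrated group and treatment, the
exponent α is the OLS slope of log(y) on log(x), pooling genotype means
across the group's experiments. α is invariant to log base and to
multiplicative rescaling of either trait; adjusted R² uses
1 − (1 − R²)(n − 1)/(n − 2). Nonpositive values are dropped with a warning;
fewer than 3 points yield no fit; a constant y gives α = 0, p = 1. Slopes
with p > 0.05 are "ns"; otherwise isometric when |α − a₀| ≤ 0.15 (edges
inclusive, with a 10⁻⁹ epsilon against float representation), hyper-/
hypoallometric above/below, with a₀ = 0.33 for linear/count/percent traits
and 0.67 for areas (pure ratios need an explicit a₀). An SMA
(standardized-major-axis) slope is available for sensitivity analysis only.
Default pairs: nodal_root_number~biomass, RXSA~biomass, MXA~biomass,
MXA~RXSA, percAA~biomass.

## Synthetic data generator

Design goals: satisfy the package's structural invariants *by construction*
and make every calibration target recoverable.

- Eight base traits (RXSA, TSA, percAA, MXA, MXV, root_depth, biomass,
  tillers) are drawn through a Gaussian copula (Cholesky factor of a target
  correlation matrix; anatomical traits intercorrelated at 0.5, percAA at
  0.2, root–shoot at 0.15) with lognormal marginals — percAA through a
  scaled logistic so it stays in [0, 100].
- Genotypes belong to latent archetypes: per-trait offsets in z-units plus a
  `drought_tolerance` exponent applied to the biomass drought multiplier
  (effective multiplier m^tolerance), so WW biomass is archetype-comparable
  while drought biomass separates the archetypes. Defaults: IP1 (deep,
  large-RXSA, high-aerenchyma; tolerance 0.55, weight 0.35), IP2 (deep,
  small-RXSA, small metaxylem; 0.60, 0.35), IP5 (shallow, few roots; 2.0,
  0.30).
- Structural construction: TSA is capped at 0.6·RXSA, TCA = 0.85·(RXSA −
  TSA), AA = percAA/100·TCA, MXA capped at half the non-aerenchyma area —
  so RXSA ≥ AA + MXA and percAA ∈ [0, 100] always hold.
- Power-law links (default nodal_root_number ~ biomass^0.9) are computed
  from pre-multiplier driver values, so within-treatment log–log slopes
  equal the configured α and zero-noise plasticity equals the configured
  multipliers exactly (count rounding can be disabled where exactness
  matters).
- Experiments: GH-A (14 genotypes × 4 reps, biomass multiplier 0.30 — 70%
  reduction; records root_depth), ROS-B (14 × 4, 0.50; deep_root_prop),
  GH-C (32 × 4, 0.52; root_depth), ROS-D (140 × 3, 0.65; root_angle) —
  contrasting severities and depth proxies, 1320 plants total.
- Determinism: one integer seed via `numpy.random.SeedSequence.spawn`, one
  child per experiment, so adding experiments never perturbs earlier ones
  and outputs are byte-identical across runs.

## What passing on synthetic data does and does not show

The synthetic studies validate the *machinery*: estimators recover the
parameters that generated the data, invariants hold, clustering recovers
archetypes it was told exist at a chosen separation, and the pipeline is
deterministic. They do not validate the *science* on real panels: real
trait distributions, correlation structures and archetype separations are
unknown and certainly messier, and a method that recovers 3-z-unit
archetypes says nothing about 0.5-z-unit ones. Conclusions about real
germplasm require real data through the same pipeline.

## Numerical choices

- Strictly-improving swap tolerance 10⁻¹²; silhouette/rank/percent
  computations in float64 throughout.
- CSV outputs at 12 significant digits (`%.12g`).
- Isometry band comparisons carry a 10⁻⁹ epsilon so nominal band edges
  (e.g. 0.18 = 0.33 − 0.15) classify as isometric despite binary floating
  point.
- Exactly-singular PSD correlation matrices get a 10⁻¹² diagonal jitter
  before Cholesky; indefinite ones are rejected with the nearest PSD
  correlation suggested in the error.
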