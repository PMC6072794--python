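# Methods

This note documents the statistical procedures implemented in `conetstab`,
the choices made where the methodology was genuinely open, the design of
the synthetic-data generator, and the limits of what the tests demonstrate.

## Filtering and diversity

Samples are rarefied to a fixed depth (default 4000 reads) by subsampling
without replacement (multivariate hypergeometric draw); samples below the
depth are dropped and logged. Each sample uses its own RNG stream seeded by
a hash of `(global_seed, sample_id)`, so results do not depend on column
order. Shannon diversity H = −Σ pᵢ ln pᵢ is computed in **nats**; samples
with H above a cut (6 for bacteria-like, 3.2 for fungi-like data — the
scale of these cuts is only consistent with natural logarithms at realistic
richness) are removed as outliers. Taxa with fewer than 10 reads across all
samples are excluded. Evenness is Pielou's J = H / ln S, defined as 0 when
S ≤ 1; the log base and evenness formula are configurable assumptions, not
uniquely determined by convention. Richness and the other metrics are
computed after rarefaction; computing them on unequal depths triggers a
warning because richness then confounds with sequencing effort.

## Distances, ordination, PERMANOVA, resilience

Bray–Curtis dissimilarity is delegated to `scipy.spatial.distance.pdist`.
On equal-depth (rarefied) tables it is identical on counts and on relative
abundances; this invariance is asserted by test.

PCoA is classical metric scaling: eigendecomposition of −½·J·D²·J with J
the centring matrix; coordinates are eigenvectors scaled by √λ for positive
eigenvalues sorted descending. Bray–Curtis matrices are generally
non-Euclidean, so negative eigenvalues occur; they are reported and their
axes omitted, and the proportion explained is taken over the positive
spectrum. Agreement with scikit-bio's implementation (up to axis sign) and
exact recovery of Euclidean configurations (Procrustes error < 1e−8) are
both tested.

PERMANOVA uses SS_total = (1/N)·Σ_{i<j} d²ᵢⱼ, SS_within computed per group,
and pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)). The permutation p uses
the +1 Monte-Carlo correction, p = (1 + #{F* ≥ F}) / (1 + n_perm), and can
therefore never be exactly 0; an exhaustive-enumeration mode is available
for small designs and is compared against a brute-force oracle in tests.
Ties in F under permutation are counted as exceedances (≥ with a 1e−12
tolerance), the conservative choice.

Resistance/resilience is the Bray–Curtis similarity (1 − d) of each drought
community to its control counterpart at the same sampling. How the original
control–drought pairs were formed is not uniquely specified by the
experimental description, so both schemes are implemented: `matched` joins
mesocosms sharing (block, plant treatment) — the default, matching the
split-block design — and `all_pairs` crosses every control with every
drought sample. Similarity across samplings is compared by one-way
fixed-effects ANOVA. Repeated-measures/split-plot error strata are out of
scope; the fixed-effects substitute is a documented simplification, not an
equivalent.

## Indicator analysis

IndVal for taxon i in group g is Aᵢg·Bᵢg where Aᵢg is the group mean
relative abundance divided by the sum of group means and Bᵢg the occurrence
frequency in g. It is computed on relative abundances (on rarefied tables
this equals the count version). Significance uses random reassignment of
sample labels, 1000 rounds by default, with one shared permutation per
round for all taxa — preserving taxon–taxon dependence — and the +1
correction. An exhaustive enumeration (all C(n, n₁) arrangements) serves as
the oracle for small designs. Indicators are taxa with p < 0.05 and mean
relative abundance > 1% in their best group (best-group abundance is the
default gate; an overall-mean variant is available); best group = drought
gives "tolerant", control gives "sensitive". No multiple-testing correction
is applied across taxa, mirroring the raw-threshold convention of this
analysis style; a Benjamini–Hochberg flag exists but is off by default.

## Co-occurrence networks

All-pairs Spearman ρ is the Pearson correlation of mid-ranks (average
ties; zeros tie at the bottom, no pseudocounts). Two-sided p-values use the
t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df, appropriate at the
design's n = 36; |ρ| = 1 maps to the smallest positive float, and an exact
permutation p is available for tiny n. Constant taxa have no defined rank
correlation and are excluded with a log message.

Networks are built per (treatment × sampling) cell after a prevalence
filter (≥ 8 of 36 communities). Edges require ρ > 0.6 **and** p < 0.01
(both configurable; the edge-significance threshold is stated as 0.01 in
one place and 0.001 in another in the source methodology — 0.01 is the
default here) and positive sign; the signed significant set (|ρ| > 0.6,
p < 0.01) is retained for negative-correlation proportions. Isolated taxa
are not nodes.

Node metrics: degree; normalised degree = degree/(n−1) by default — the
phrase "standardised by the total number of connections" is ambiguous, and
degree/(2m) is available behind a flag, but (n−1) bounds the metric in
[0, 1] and matches the cited network methodology; betweenness is the
unnormalised shortest-path count. The clustering coefficient is the global
transitivity 3·triangles/triples.

Module detection is divisive Girvan–Newman: repeatedly remove the edge of
highest edge-betweenness (ties broken by removing the lexicographically
smallest edge, for reproducibility), record the partition whenever the
component count grows, and return the nested partition maximising
Newman–Girvan Q (ties → fewer modules). Girvan–Newman does not guarantee
the globally Q-optimal partition over all partitions; on small graphs the
returned Q is verified to be bounded by the exhaustive optimum, and the
returned partition's Q always matches an independent recomputation. Above
2000 edges the same algorithm is run through igraph's C implementation (the
pure-Python loop is quadratic in edges); both paths are cross-checked on
shared fixtures.

The random-graph null is uniform G(n, m) with the observed node and edge
counts (no self-loops or multi-edges); the empirical clustering p uses the
+1 correction over a default ensemble of 1000.

## Group statistics

χ² of two proportions is the 2×2 Pearson test without continuity
correction (immaterial at the sample sizes these comparisons meet; a Yates
flag exists). One-way ANOVA delegates to scipy with an explicit guard for
SS_total = 0 (reported as F = 0, p = 1); the two-factor crossed version
with interaction uses statsmodels with Type I sums of squares and warns on
unbalanced designs. Regressions are OLS with a two-sided t test on the
slope. The covariate–centrality analysis computes each node's Spearman
correlation with a per-sample covariate (e.g. plant biomass), regresses
|ρ| on normalised degree and betweenness, and contrasts groups by a
difference-of-slopes t test — a documented stand-in for a full ANCOVA whose
original specification (covariate coding, error strata) is not available.

## Synthetic data generator

Log abundances follow a latent-factor model:

    log a_is = mu_i + delta_i * w(sampling) * 1[drought] + sum_k lambda_ik f_ks + eps_is

with fₖₛ ~ N(0,1) i.i.d. per sample, εᵢₛ ~ N(0, σ²), μᵢ ~ N(μ₀, τ²) (log-
normal abundance spread), and counts drawn as one Multinomial(depth, a/Σa)
per sample. Two corrections/choices matter:

- **Lognormal mean correction.** ‖λᵢ‖²/2 is subtracted from μᵢ so a taxon's
  *expected* abundance is independent of its coupling strength; without it,
  strongly coupled blocks dominate the read pool and their oscillation
  induces spurious positive correlations among all other taxa through the
  shared multinomial denominator.
- **Multinomial, not Dirichlet-multinomial.** The simplest model matching
  rarefied-count analysis; compositional distortion of correlations is
  therefore present by construction and is part of what the tests exercise.

The drought effect δᵢ (log-fold units, default ln 4) applies from the
end-of-drought sampling onward, with an optional per-sampling decay to
emulate recovery (the `recovering_responder` preset uses weights
1.0 / 0.5 / 0.2).

Design is the field layout of the motivating experiment: 2 treatments × 4
samplings × 9 plant communities × 4 blocks = 288 samples, i.e. 36
communities per treatment × sampling cell, at depth 4000.

### Organism presets

The presets instantiate two community architectures whose network-level
consequences differ qualitatively:

- `bacteria_like` (2000 taxa, K = 40): factors are organised as 4 pools of
  1 dominant + 9 sub-factors. The 300 participating taxa are the abundant
  ones (μ boost 5.5 log units): at 4000 reads over 2000 taxa only a few
  hundred taxa can be informatively sampled at all, and in real communities
  the dominant taxa are precisely the ones that drive network structure.
  Participants load U(0.95, 1.2) on their pool's dominant gradient plus 0.6
  on one sub-factor; 25% are antagonists carrying a single counter-coupled
  loading of 1.6 (≈ 15% of non-zero loading entries are negative — the
  single strong loading is needed because compositional closure
  systematically attenuates negative count correlations). The result is a
  few large, densely but imperfectly connected communities: pervasive
  moderate couplings, many realised antagonisms, high inclusion and
  normalised degree, and comparatively low transitivity.
- `fungi_like` (400 taxa, K = 15): single-factor blocks of ~8 taxa,
  participation 0.30, loadings U(1.10, 1.25), 5% antagonists, σ = 0.40.
  Couplings are *sparse* — an order of magnitude fewer coupled pairs than
  the bacterial preset and less coupling mass per community — and the few
  coupled guilds are tight, yielding small networks of near-clique modules
  with stably high clustering.

These structural choices (pool count, abundance concentration, antagonist
form, clique saturation) were fixed by factor-model arithmetic plus
design-phase simulation of the generator itself, then frozen; they are the
mechanism behind the five headline bacteria-vs-fungi contrasts, not a
per-test calibration. Benchmark presets: `strong_coupling` (250 taxa, 15
sign-balanced blocks, |λ| = 1.2, σ = 0.3 — sign balance keeps each block's
total abundance stable so the compositional common mode stays small;
used for edge-recovery operating characteristics and as the covariate
test-bed via a biomass covariate tracking factor 0), `strong_responder` /
`recovering_responder` (40 taxa, 25% tolerant + 25% sensitive, ln 4 shift),
and `null` (no effect; drought and control exchangeable — the calibration
regime).

`expected_edges` lists pairs whose *population log-scale Pearson*
correlation (from C = ΛΛᵀ + σ²I) exceeds the threshold. Rank correlation of
counts is attenuated relative to this (monotone transform plus multinomial
noise plus zero ties), which is why recovery is assessed as an operating
characteristic (recall/precision) rather than equality.

### What the generator does not emulate

Phylogenetic structure, mechanistic dynamics (e.g. Lotka–Volterra),
overdispersion beyond multinomial, spatial/temporal autocorrelation between
samplings, and sequencing artefacts (chimeras, contamination). Passing
tests therefore demonstrate correctness and calibration of the *analysis*
under a factor-structured compositional model — not that the biological
claims would replicate on new field data.

## Numerical conventions

Permutation p-values always use the +1 correction and count ties as
exceedances. Girvan–Newman ties break lexicographically. Spearman ρ is
clipped to [−1, 1] before the t transform; |ρ| ≥ 1 − 1e−12 maps to the
smallest positive float. PCoA treats eigenvalues below max(1e−10,
1e−10·λ₁) as zero. Degenerate inputs are contracts, not crashes: empty
networks are returned with a warning, constant covariates and zero-variance
regressors are fatal with a message, all-equal ANOVA data reports F = 0,
p = 1, and J = 0 for richness ≤ 1.

## Problem sizes

The shipped test-suite and acceptance-script sizes — 50 replicates for edge
recovery, 10 replicate pairs for the organism contrasts, 1000-graph null
ensembles, 1000 null datasets (tests) / 500 (script) for PERMANOVA
calibration, 500 taxa × 1000 permutations for IndVal calibration — were
chosen so that Monte-Carlo error is small relative to every margin being
asserted while a full run stays in the minutes range on one core.
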