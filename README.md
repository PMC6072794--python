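# conetstab

Co-occurrence network stability analysis for soil bacterial and fungal
communities under drought.

Soil bacteria and fungi respond very differently to drought, and one
influential line of evidence comes from comparing the *architecture* of
their co-occurrence networks: graphs whose nodes are OTUs (operational
taxonomic units) and whose edges are significant positive rank correlations
of abundance across communities. Bacterial networks tend to be large,
densely connected and weakly compartmentalised — properties associated with
low stability under disturbance — while fungal networks are small, sparse
and tightly clustered. `conetstab` re-implements this entire analysis chain
as a tested, reusable Python library with a command-line interface, and
ships a synthetic OTU-table generator with planted structure so every stage
can be validated against known ground truth.

The pipeline, from a taxa × samples count table and sample metadata:

1. **Preprocessing** — rarefaction to a common depth (default 4000 reads,
   without replacement), removal of Shannon-diversity outlier samples
   (H > 6 bacteria-like, H > 3.2 fungi-like, nats), exclusion of taxa with
   fewer than 10 reads overall; per-sample richness, Shannon H and Pielou
   evenness J = H / ln S.
2. **Community structure** — Bray–Curtis dissimilarity
   d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ); principal coordinates analysis (classical
   scaling); PERMANOVA with pseudo-F
   F = (SS_between/(a−1)) / (SS_within/(N−a)) and a label-permutation null;
   control–drought Bray–Curtis *similarity* (1 − d) per sampling as a
   resistance/resilience metric.
3. **Indicator taxa** — the Dufrêne–Legendre IndVal statistic per taxon and
   treatment, IndVal = A·B with A the relative mean-abundance concentration
   and B the occurrence frequency, permutation significance (1000 rounds),
   and classification of significant (P < 0.05), abundant (> 1% in the best
   group) taxa as drought-tolerant or drought-sensitive.
4. **Co-occurrence networks** — all-pairs Spearman ρ among taxa present in
   ≥ 8 of the 36 communities of one treatment × sampling cell; edges where
   ρ > 0.6 and P < 0.01 (positive only; the signed significant set is kept
   for antagonism proportions); node normalised degree (degree/(n−1)) and
   betweenness; global transitivity; Girvan–Newman edge-betweenness modules
   with Newman–Girvan modularity Q; Erdős–Rényi G(n,m) null ensembles for
   the clustering coefficient; network-membership overlap over time.
5. **Group statistics** — χ² tests of proportions, fixed-effects one- and
   two-factor ANOVA, OLS regressions, and covariate–centrality association
   (per-node Spearman correlation with e.g. plant biomass, regressed on
   centrality with a difference-of-slopes contrast).

The synthetic generator draws log abundances from a latent-factor model
(log aᵢₛ = μᵢ + δᵢ·drought + Σₖ λᵢₖ fₖₛ + εᵢₛ) and reads as one multinomial
draw per sample, so compositional artefacts are present exactly as they are
in rarefied real tables. Presets `bacteria_like` and `fungi_like` plant the
two architectures described above; `SyntheticTruth` records loadings,
planted modules and responder sets for validation.

## Worked example

Build the co-occurrence network of one simulated fungi-like community cell
(36 control communities at the pre-drought sampling):

```python
import conetstab as cs
from conetstab.network import network_summary, random_network_null

cfg = cs.preset("fungi_like", treatments=("control",), samplings=("pre_drought",))
table, meta, truth = cs.generate(cfg, seed=1)           # 400 taxa x 36 samples
eligible = cs.prevalence_filter(table, min_occurrence=8)
net = cs.CooccurrenceNetwork(rho_min=0.6, p_max=0.01).fit(eligible)
print(network_summary(net.graph_, eligible_taxa=eligible.shape[0]))
print(random_network_null(net.graph_, ensemble=1000, seed=1).empirical_p)
```

prints (seed 1):

```
nodes                   155
edges                   322
inclusion_proportion    0.3875
clustering_coefficient  0.8743
modularity_Q            0.9345
n_modules               34
density                 0.027
null_clustering_p       0.001
```

155 of the 400 eligible taxa enter the network (inclusion 0.39); its
transitivity (0.87) is far above the G(n,m) null mean (0.027), so the
empirical p against 1000 random graphs is minimal (1/1001) — the network is
significantly more clustered than random, as co-oscillating guilds should
be. Running the same code with the `bacteria_like` preset yields a larger,
more connected, *less* clustered network; the five headline contrasts
(mean |ρ|, negative-correlation share, inclusion, normalised degree,
clustering) are checked explicitly in `tests/test_acceptance.py`.

The full pipeline (8 networks per organism, diversity, resilience,
indicators, GraphML exports, JSON report) runs from a YAML config:

```sh
conetstab run --config run.yaml
```

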