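"""Synthetic OTU-table generator with planted structure.

The generator emulates the statistical structure the analysis assumes:
taxa co-oscillate through latent Gaussian factors (log-linear loadings),
treatment responders shift their mean log abundance under drought from the
end-of-drought sampling onward (optionally decaying through recovery), and
reads are drawn per sample as one multinomial draw of fixed depth from the
exponentiated log abundances — so compositional distortion is present, as
it is in rarefied real tables.

Model, per taxon i and sample s:

    log a_is = mu_i + delta_i * w(sampling_s) * 1[drought_s] + sum_k lambda_ik f_ks + eps_is
    f_ks ~ N(0,1),  eps_is ~ N(0, sigma^2),  mu_i ~ N(mu0, tau^2)
    counts_.s ~ Multinomial(depth, a_.s / sum_i a_is)

Two loading architectures are available. ``blocks`` assigns each
participating taxon one factor (disjoint co-oscillation blocks — the
fungi-like regime: sparse, weaker couplings). ``pooled`` groups factors into
pools of one dominant plus several sub-factors and gives each participating
taxon a strong loading on its pool's dominant factor plus a weaker loading
on one sub-factor — producing the large, densely connected, less clustered
communities of the bacteria-like regime. A fraction of loading rows is
negated to plant antagonists.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable, SAMPLINGS, TREATMENTS

logger = logging.getLogger("conetstab")

#: drought-effect weight per sampling: no effect before the drought, full
#: effect from its end onward unless a decay schedule is supplied.
DEFAULT_EFFECT_SCHEDULE = {
    "pre_drought": 0.0,
    "end_drought": 1.0,
    "early_recovery": 1.0,
    "late_recovery": 1.0,
}

RECOVERY_EFFECT_SCHEDULE = {
    "pre_drought": 0.0,
    "end_drought": 1.0,
    "early_recovery": 0.5,
    "late_recovery": 0.2,
}


@dataclass
class SyntheticConfig:
    """Generator parameters. Defaults describe a small generic community."""

    n_taxa: int = 100
    n_factors: int = 10
    structure: str = "blocks"          # 'blocks' | 'pooled'
    n_pools: int = 4                   # pooled structure only
    participation: float = 0.5         # fraction of taxa with factor loadings
    loading_low: float = 1.0           # primary |loading| ~ U(low, high)
    loading_high: float = 1.2
    sub_loading: float = 0.7           # pooled structure: sub-factor loading
    neg_frac: float = 0.0              # fraction of loading rows negated
    sigma: float = 0.3                 # residual log-noise sd
    mu0: float = 0.0
    tau: float = 1.0                   # sd of baseline log abundances
    depth: int = 4000
    n_blocks: int = 4                  # experimental blocks (mesocosm rows)
    n_plant_treatments: int = 9        # -> 36 samples per treatment x sampling
    treatments: tuple = TREATMENTS
    samplings: tuple = SAMPLINGS
    frac_tolerant: float = 0.0
    frac_sensitive: float = 0.0
    effect_size: float = np.log(4.0)   # |delta| in log units for responders
    effect_schedule: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SCHEDULE))
    covariate_factor: int | None = None  # biomass covariate tracks this factor
    covariate_noise: float = 0.3
    coupled_mu_boost: float = 0.0      # added to mu of coupled taxa (log units)
    antagonist_loading: float | None = None  # pooled: |loading| of negated rows
    organism_tag: str = "other"

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("invalid config: n_taxa must be >= 2")
        if self.n_factors < 1:
            raise ValueError("invalid config: n_factors must be >= 1")
        if self.depth < 100:
            raise ValueError("invalid config: depth must be >= 100")
        if not 0 <= self.participation <= 1:
            raise ValueError("invalid config: participation must be in [0,1]")
        if self.structure not in ("blocks", "pooled"):
            raise ValueError("invalid config: structure must be 'blocks' or 'pooled'")
        if self.structure == "pooled" and self.n_factors % self.n_pools != 0:
            raise ValueError("invalid config: n_factors must be divisible by n_pools")
        for s in self.samplings:
            if s not in self.effect_schedule:
                raise ValueError(f"invalid config: effect_schedule missing {s!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth: loadings, memberships, responders, config."""

    loadings: np.ndarray               # (taxa, factors)
    factor_of: np.ndarray              # primary factor per taxon (-1 = none)
    pool_of: np.ndarray                # pool per taxon (-1 = none / blocks)
    tolerant: list[str]
    sensitive: list[str]
    delta: np.ndarray                  # per-taxon log effect (signed)
    config: SyntheticConfig
    seed: int

    def module_of(self) -> np.ndarray:
        """Planted module id per taxon (pool for pooled, factor for blocks)."""
        return self.pool_of if self.config.structure == "pooled" else self.factor_of


def _build_loadings(cfg: SyntheticConfig, rng: np.random.Generator):
    t, k = cfg.n_taxa, cfg.n_factors
    lam = np.zeros((t, k))
    factor_of = np.full(t, -1)
    pool_of = np.full(t, -1)
    participants = rng.choice(t, size=int(round(cfg.participation * t)), replace=False)
    # balanced round-robin deal: planted blocks/pools have (near-)equal size
    if cfg.structure == "blocks":
        for pos, i in enumerate(participants):
            f = pos % k
            lam[i, f] = rng.uniform(cfg.loading_low, cfg.loading_high)
            factor_of[i] = f
    else:
        subs = k // cfg.n_pools - 1
        if subs < 1:
            raise ValueError("pooled structure needs >= 2 factors per pool")
        for pos, i in enumerate(participants):
            pool = pos % cfg.n_pools
            dom = pool * (subs + 1)
            sub = dom + 1 + (pos // cfg.n_pools) % subs
            # dominant loadings spread over [low, high]: taxa well coupled to
            # the pool gradient become hubs, marginal ones periphery
            lam[i, dom] = rng.uniform(cfg.loading_low, cfg.loading_high)
            lam[i, sub] = cfg.sub_loading
            factor_of[i] = dom
            pool_of[i] = pool
    if cfg.neg_frac > 0:
        n_flip = int(round(cfg.neg_frac * len(participants)))
        flip_idx = rng.choice(participants, size=n_flip, replace=False)
        flip = np.zeros(t, dtype=bool)
        flip[flip_idx] = True
        lam[flip] *= -1.0
        if cfg.structure == "pooled" and cfg.antagonist_loading is not None:
            # antagonists counter-coupled to the pool gradient at full
            # strength (suppressed by the very conditions the pool tracks)
            for i in np.flatnonzero(flip):
                dom = factor_of[i]
                lam[i, :] = 0.0
                lam[i, dom] = -cfg.antagonist_loading
    return lam, factor_of, pool_of


def generate(config: SyntheticConfig, seed: int = 0):
    """Simulate one community: (OtuTable, metadata DataFrame, SyntheticTruth)."""
    config.validate()
    rng = np.random.default_rng(seed)
    t = config.n_taxa
    lam, factor_of, pool_of = _build_loadings(config, rng)
    mu = rng.normal(config.mu0, config.tau, size=t)
    # lognormal mean correction: E[exp(lam.f)] = exp(|lam|^2/2); subtracting it
    # keeps a taxon's expected abundance independent of its coupling strength,
    # which also tempers the shared-denominator (compositional) common mode.
    mu = mu - 0.5 * (lam ** 2).sum(axis=1)
    # network taxa are the abundant ones (as in real communities, where
    # abundant taxa drive co-occurrence structure): optional boost
    mu = mu + config.coupled_mu_boost * (factor_of >= 0)

    delta = np.zeros(t)
    n_tol = int(round(config.frac_tolerant * t))
    n_sen = int(round(config.frac_sensitive * t))
    responders = rng.choice(t, size=n_tol + n_sen, replace=False)
    delta[responders[:n_tol]] = config.effect_size
    delta[responders[n_tol:]] = -config.effect_size
    taxon_ids = [f"OTU{i:05d}" for i in range(t)]
    tolerant = [taxon_ids[i] for i in responders[:n_tol]]
    sensitive = [taxon_ids[i] for i in responders[n_tol:]]

    rows = []
    columns: dict[str, np.ndarray] = {}
    for treatment in config.treatments:
        for sampling in config.samplings:
            w = config.effect_schedule[sampling] if treatment == "drought" else 0.0
            for plant in range(1, config.n_plant_treatments + 1):
                for block in range(1, config.n_blocks + 1):
                    sid = f"{treatment[:3]}_{sampling}_p{plant}_b{block}"
                    f = rng.normal(size=config.n_factors)
                    eps = rng.normal(0.0, config.sigma, size=t)
                    log_a = mu + delta * w + lam @ f + eps
                    a = np.exp(log_a - log_a.max())
                    counts = rng.multinomial(config.depth, a / a.sum())
                    columns[sid] = counts
                    row = {
                        "sample_id": sid,
                        "treatment": treatment,
                        "sampling": sampling,
                        "block": block,
                        "plant_treatment": f"P{plant}",
                    }
                    if config.covariate_factor is not None:
                        row["biomass"] = float(
                            f[config.covariate_factor]
                            + rng.normal(0.0, config.covariate_noise)
                        )
                    rows.append(row)
    counts_df = pd.DataFrame(columns, index=taxon_ids)
    table = OtuTable(counts_df, config.organism_tag)
    meta = pd.DataFrame(rows)
    meta["treatment"] = pd.Categorical(meta["treatment"], categories=TREATMENTS, ordered=True)
    meta["sampling"] = pd.Categorical(meta["sampling"], categories=SAMPLINGS, ordered=True)
    meta = meta.set_index("sample_id", drop=False)
    truth = SyntheticTruth(lam, factor_of, pool_of, tolerant, sensitive, delta, config, seed)
    return table, meta, truth


def population_correlations(truth: SyntheticTruth) -> np.ndarray:
    """Population Pearson correlation matrix of log abundances from the
    factor model: C = Lambda Lambda' + sigma^2 I, standardised."""
    lam = truth.loadings
    c = lam @ lam.T + truth.config.sigma ** 2 * np.eye(lam.shape[0])
    d = np.sqrt(np.diag(c))
    return c / np.outer(d, d)


def expected_edges(truth: SyntheticTruth, rho_min: float = 0.6) -> pd.DataFrame:
    """Taxon pairs whose population log-scale correlation exceeds rho_min
    in magnitude, with expected sign."""
    corr = population_correlations(truth)
    t = corr.shape[0]
    iu, ju = np.triu_indices(t, k=1)
    keep = np.abs(corr[iu, ju]) > rho_min
    ids = np.asarray([f"OTU{i:05d}" for i in range(t)])
    return pd.DataFrame(
        {
            "taxon_a": ids[iu[keep]],
            "taxon_b": ids[ju[keep]],
            "expected_rho": corr[iu, ju][keep],
            "sign": np.where(corr[iu, ju][keep] > 0, "positive", "negative"),
        }
    )


# -- presets ---------------------------------------------------------------

def preset(name: str, **overrides) -> SyntheticConfig:
    """Named generator presets.

    ``bacteria_like`` — 2000 taxa, K=40 factors in 4 pools (1 dominant + 9
    sub-factors each). The 300 coupled taxa are the abundant ones
    (coupled_mu_boost 5.5, as in real communities where dominant taxa drive
    network structure), load U(0.95, 1.2) on their pool's dominant gradient
    plus 0.6 on a sub-factor, and a quarter of them are antagonists
    counter-coupled at 1.6 (about 15% of non-zero loading entries are
    negative). Yields a few large, densely but imperfectly connected
    communities: high connectedness, lower clustering.
    ``fungi_like`` — 400 taxa, K=15 single-factor blocks of 8, participation
    0.30, 5% antagonists, loadings U(1.10, 1.25), sigma 0.40: sparse, tight
    guilds — small networks with near-clique (high-clustering) modules and
    far fewer coupled pairs overall.
    ``strong_coupling`` — 250 taxa of which half couple through 15 blocks
    with exact |loading| 1.2 and balanced signs, sigma 0.3: the
    edge-recovery benchmark regime. Sign balance keeps each block's total
    abundance stable, so the shared-denominator (compositional) common mode
    stays small and spurious passive-taxon edges are rare.
    ``strong_responder`` — 40 taxa, no couplings, 25% tolerant + 25%
    sensitive responders with a 4-fold (log 4) drought shift.
    ``recovering_responder`` — strong_responder with the drought effect
    decaying through recovery (weights 1.0 / 0.5 / 0.2).
    ``null`` — strong_responder with zero drought effect; control and
    drought are exchangeable (calibration regime).
    """
    presets = {
        "bacteria_like": dict(
            n_taxa=2000, n_factors=40, structure="pooled", n_pools=4,
            participation=0.15, loading_low=0.95, loading_high=1.2,
            sub_loading=0.6, neg_frac=0.25, antagonist_loading=1.6,
            coupled_mu_boost=5.5, sigma=0.30, tau=0.8, depth=4000,
            frac_tolerant=0.05, frac_sensitive=0.05, effect_size=np.log(4.0),
            organism_tag="bacteria_like",
        ),
        "fungi_like": dict(
            n_taxa=400, n_factors=15, structure="blocks",
            participation=0.30, loading_low=1.10, loading_high=1.25,
            neg_frac=0.05, sigma=0.40, tau=0.8, depth=4000,
            frac_tolerant=0.05, frac_sensitive=0.05, effect_size=np.log(4.0),
            organism_tag="fungi_like",
        ),
        "strong_coupling": dict(
            n_taxa=250, n_factors=15, structure="blocks",
            participation=0.5, loading_low=1.2, loading_high=1.2,
            neg_frac=0.5, sigma=0.30, tau=0.7, depth=4000,
            covariate_factor=0, organism_tag="other",
        ),
        "strong_responder": dict(
            n_taxa=40, n_factors=1, structure="blocks",
            participation=0.0, sigma=0.30, tau=0.4, depth=4000,
            frac_tolerant=0.25, frac_sensitive=0.25, effect_size=np.log(4.0),
            organism_tag="other",
        ),
        "recovering_responder": dict(
            n_taxa=40, n_factors=1, structure="blocks",
            participation=0.0, sigma=0.30, tau=0.4, depth=4000,
            frac_tolerant=0.25, frac_sensitive=0.25, effect_size=np.log(4.0),
            effect_schedule=dict(RECOVERY_EFFECT_SCHEDULE), organism_tag="other",
        ),
        "null": dict(
            n_taxa=40, n_factors=1, structure="blocks",
            participation=0.0, sigma=0.30, tau=0.4, depth=4000,
            frac_tolerant=0.0, frac_sensitive=0.0, effect_size=0.0,
            organism_tag="other",
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    params = dict(presets[name])
    params.update(overrides)
    return SyntheticConfig(**params)


def generate_pair(seed: int = 0, **overrides):
    """Bacteria-like and fungi-like communities from one seed (two runs)."""
    out = {}
    for i, name in enumerate(("bacteria_like", "fungi_like")):
        out[name] = generate(preset(name, **overrides), seed=seed * 2 + i)
    return out
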