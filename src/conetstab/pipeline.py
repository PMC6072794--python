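"""End-to-end pipeline: simulate (or load) -> preprocess -> community ->
indicators -> networks -> comparisons.

One co-occurrence network is built per (treatment x sampling) cell — eight
per organism for the full design — and every filter logs its casualty
counts. The pipeline is a pure function of (inputs, config, seeds): a rerun
with the same config yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess, simulate
from .community import bray_curtis, permanova, resilience_similarity
from .indicators import IndValAnalysis
from .network import (
    CooccurrenceNetwork,
    detect_modules,
    network_summary,
    random_network_null,
)
from .otu import OtuTable, SAMPLINGS, TREATMENTS, join_metadata, read_metadata, read_otu_table, write_network

logger = logging.getLogger("conetstab")


@dataclass
class RunConfig:
    """Thresholds, seeds and paths for one pipeline run."""

    otu_table: str | None = None       # path; None -> simulate
    metadata: str | None = None
    preset: str = "fungi_like"
    organism_tag: str = "other"
    out_dir: str = "conetstab_out"
    depth: int = 4000
    min_total: int = 10
    max_shannon: float = 6.0
    min_occurrence: int = 8
    rho_min: float = 0.6
    p_max: float = 0.01
    indicator_p: float = 0.05
    indicator_min_abund: float = 0.01
    indicator_n_perm: int = 1000
    permanova_n_perm: int = 999
    null_ensemble: int = 200
    max_gn_edges: int = 2000
    detect_modules: bool = True
    pairing: str = "matched"
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.min_occurrence < 1:
            raise ValueError("min_occurrence must be >= 1")
        if not (0 < self.rho_min < 1) or not (0 < self.p_max <= 1):
            raise ValueError("rho_min must be in (0,1) and p_max in (0,1]")
        if self.pairing not in ("matched", "all_pairs"):
            raise ValueError("pairing must be 'matched' or 'all_pairs'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written as
    JSON with TSV/GraphML side files under ``config.out_dir``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "filters": {}, "networks": {}}

    # -- inputs ------------------------------------------------------------
    if config.otu_table is not None:
        table = read_otu_table(config.otu_table, config.organism_tag)
        if config.metadata is None:
            raise ValueError("metadata path required with an OTU table path")
        meta = read_metadata(config.metadata)
        report["input"] = {"source": str(config.otu_table)}
    else:
        cfg = simulate.preset(config.preset, depth=config.depth)
        table, meta, _ = simulate.generate(cfg, seed=config.seed)
        report["input"] = {"source": f"simulated:{config.preset}", "seed": config.seed}
    n_taxa0, n_samples0 = table.shape

    # -- preprocess --------------------------------------------------------
    table = preprocess.rarefy(table, depth=config.depth, seed=config.seed)
    table = preprocess.filter_shannon_outliers(table, max_h=config.max_shannon)
    table = preprocess.filter_low_count_taxa(table, min_total=config.min_total)
    meta = join_metadata(table, meta)
    report["filters"] = {
        "taxa_in": n_taxa0, "samples_in": n_samples0,
        "taxa_out": table.shape[0], "samples_out": table.shape[1],
    }

    div = preprocess.diversity(table)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)

    # -- community composition --------------------------------------------
    d = bray_curtis(table)
    d.to_frame().to_csv(out / "bray_curtis.tsv", sep="\t")
    perm = permanova(d, meta["treatment"].astype(str), n_perm=config.permanova_n_perm,
                     seed=config.seed)
    report["permanova_treatment"] = dataclasses.asdict(perm)
    resil, resil_anova = resilience_similarity(table, meta, pairing=config.pairing)
    resil.to_csv(out / "resilience.tsv", sep="\t", index=False)
    report["resilience_anova"] = resil_anova
    report["resilience_mean_by_sampling"] = (
        resil.groupby("sampling", observed=True)["similarity"].mean().to_dict()
    )

    # -- indicators per sampling -------------------------------------------
    ind_frames = []
    for sampling in [s for s in SAMPLINGS if (meta["sampling"] == s).any()]:
        sids = meta.index[meta["sampling"] == sampling]
        sub = table.subset_samples(sids)
        labels = meta.loc[sids, "treatment"].astype(str)
        fit = IndValAnalysis(
            n_permutations=config.indicator_n_perm,
            p_max=config.indicator_p,
            min_relabund=config.indicator_min_abund,
            random_state=config.seed,
        ).fit(sub, labels)
        res = fit.results_.copy()
        res.insert(0, "sampling", sampling)
        ind_frames.append(res)
    indicators = pd.concat(ind_frames, ignore_index=True)
    indicators.to_csv(out / "indicators.tsv", sep="\t", index=False)
    report["indicator_counts"] = (
        indicators.groupby(["sampling", "class"], observed=True).size()
        .unstack(fill_value=0).to_dict(orient="index")
    )

    # -- one network per (treatment, sampling) cell ------------------------
    metric_frames = []
    for treatment in TREATMENTS:
        for sampling in [s for s in SAMPLINGS if (meta["sampling"] == s).any()]:
            cell = meta.index[(meta["treatment"] == treatment) & (meta["sampling"] == sampling)]
            if len(cell) < 4:
                logger.warning("network %s/%s: too few samples", treatment, sampling)
                continue
            sub = table.subset_samples(cell)
            sub = preprocess.prevalence_filter(sub, min_occurrence=config.min_occurrence)
            eligible = sub.shape[0]
            label = f"{treatment}_{sampling}"
            net = CooccurrenceNetwork(rho_min=config.rho_min, p_max=config.p_max).fit(
                sub, label=label
            )
            g = net.graph_
            summary = {
                "eligible_taxa": eligible,
                "nodes": g.number_of_nodes(),
                "edges": g.number_of_edges(),
                "inclusion_proportion": g.number_of_nodes() / eligible if eligible else 0.0,
                "clustering_coefficient": net.clustering_coefficient_,
                "n_signed": int(len(net.signed_pairs_)),
                "n_negative": int((net.signed_pairs_["rho"] < 0).sum()),
            }
            if g.number_of_edges() > 0:
                if config.detect_modules and g.number_of_edges() <= config.max_gn_edges:
                    mod = detect_modules(g, max_exact_edges=config.max_gn_edges)
                    summary["modularity_Q"] = mod.modularity_Q
                    summary["n_modules"] = mod.n_modules
                    for v, m in mod.membership.items():
                        g.nodes[v]["module"] = int(m)
                elif config.detect_modules:
                    mod = detect_modules(g, method="igraph")
                    summary["modularity_Q"] = mod.modularity_Q
                    summary["n_modules"] = mod.n_modules
                    for v, m in mod.membership.items():
                        g.nodes[v]["module"] = int(m)
                null = random_network_null(g, ensemble=config.null_ensemble, seed=config.seed)
                summary["null_clustering_mean"] = null.null_mean
                summary["null_clustering_p"] = null.empirical_p
                nm = net.node_metrics_.copy()
                nm.insert(0, "network", label)
                cls = indicators[indicators["sampling"] == sampling].set_index("taxon_id")["class"]
                nm["indicator_class"] = [cls.get(v, "none") for v in nm.index]
                for v in g.nodes:
                    g.nodes[v]["indicator_class"] = str(cls.get(v, "none"))
                metric_frames.append(nm)
                write_network(g, out / f"network_{label}.graphml", format="graphml")
                write_network(g, out / f"network_{label}.tsv", format="edge_list_tsv")
            report["networks"][label] = summary
    if metric_frames:
        pd.concat(metric_frames, ignore_index=True).to_csv(
            out / "node_metrics.tsv", sep="\t", index=False
        )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
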