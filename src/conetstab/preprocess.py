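"""Quality filters and per-sample diversity.

The filter chain mirrors standard amplicon practice: rarefy every sample to a
common depth (default 4000 reads, subsampling without replacement), drop
whole-community outliers by Shannon diversity, drop taxa with fewer than 10
reads overall, and — per network-building sample set — keep only taxa present
in at least 8 communities.

Each step is a scikit-learn style transformer over :class:`~conetstab.otu.OtuTable`
(``fit`` records the decision, ``transform`` applies it); the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .otu import OtuTable, TableError

logger = logging.getLogger("conetstab")


def _sample_seed(global_seed: int, sample_id: str) -> int:
    """Stable per-sample seed so rarefaction is independent of column order."""
    h = hashlib.sha256(f"{global_seed}:{sample_id}".encode()).digest()
    return int.from_bytes(h[:4], "little")


class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample each sample's reads without replacement to a fixed depth.

    Samples with fewer total reads than ``depth`` are dropped (and logged).
    Each sample draws from its own RNG seeded by ``(random_state, sample_id)``
    so results do not depend on column order.
    """

    def __init__(self, depth: int = 4000, random_state: int = 0):
        self.depth = depth
        self.random_state = random_state

    def fit(self, table: OtuTable, y=None) -> "Rarefier":
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        totals = table.counts.sum(axis=0)
        self.kept_samples_ = list(totals.index[totals >= self.depth])
        self.dropped_samples_ = list(totals.index[totals < self.depth])
        if not self.kept_samples_:
            raise TableError("no samples survive rarefaction")
        if self.dropped_samples_:
            logger.info(
                "rarefy: dropped %d sample(s) below depth %d: %s",
                len(self.dropped_samples_), self.depth, self.dropped_samples_[:5],
            )
        return self

    def transform(self, table: OtuTable) -> OtuTable:
        cols = {}
        for sid in self.kept_samples_:
            col = table.counts[sid].to_numpy()
            total = int(col.sum())
            if total == self.depth:
                cols[sid] = col
                continue
            rng = np.random.default_rng(_sample_seed(self.random_state, sid))
            cols[sid] = rng.multivariate_hypergeometric(col, self.depth)
        out = pd.DataFrame(cols, index=table.counts.index)
        return OtuTable(out, table.organism_tag)


class LowCountFilter(BaseEstimator, TransformerMixin):
    """Exclude taxa with fewer than ``min_total`` reads across all samples."""

    def __init__(self, min_total: int = 10):
        self.min_total = min_total

    def fit(self, table: OtuTable, y=None) -> "LowCountFilter":
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")
        totals = table.counts.sum(axis=1)
        self.kept_taxa_ = list(totals.index[totals >= self.min_total])
        n_drop = table.shape[0] - len(self.kept_taxa_)
        if n_drop:
            logger.info("low-count filter: removed %d taxa (< %d reads)", n_drop, self.min_total)
        return self

    def transform(self, table: OtuTable) -> OtuTable:
        if not self.kept_taxa_:
            logger.warning("low-count filter removed every taxon")
        return table.subset_taxa(self.kept_taxa_)


class ShannonOutlierFilter(BaseEstimator, TransformerMixin):
    """Drop samples whose Shannon diversity H (nats) exceeds ``max_h``.

    The cut emulates removal of implausibly even communities (e.g. cross-
    contamination): H > 6 for bacteria-like, H > 3.2 for fungi-like data.
    """

    def __init__(self, max_h: float = 6.0):
        self.max_h = max_h

    def fit(self, table: OtuTable, y=None) -> "ShannonOutlierFilter":
        if not self.max_h > 0:
            raise ValueError("max_h must be > 0")
        h = shannon(table)
        self.kept_samples_ = list(h.index[h <= self.max_h])
        self.dropped_samples_ = list(h.index[h > self.max_h])
        if self.dropped_samples_:
            logger.info(
                "shannon filter: dropped %d sample(s) with H > %.3g: %s",
                len(self.dropped_samples_), self.max_h, self.dropped_samples_[:5],
            )
        return self

    def transform(self, table: OtuTable) -> OtuTable:
        return table.subset_samples(self.kept_samples_)


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Keep taxa present (count > 0) in at least ``min_occurrence`` samples.

    Applied per network-building sample set (the 36 communities of one
    treatment x sampling cell), so eligibility is always relative to the
    table actually being correlated.
    """

    def __init__(self, min_occurrence: int = 8):
        self.min_occurrence = min_occurrence

    def fit(self, table: OtuTable, y=None) -> "PrevalenceFilter":
        if self.min_occurrence < 1:
            raise ValueError("min_occurrence must be >= 1")
        occ = (table.counts > 0).sum(axis=1)
        self.kept_taxa_ = list(occ.index[occ >= self.min_occurrence])
        return self

    def transform(self, table: OtuTable) -> OtuTable:
        return table.subset_taxa(self.kept_taxa_)


# -- functional wrappers ---------------------------------------------------

def rarefy(table: OtuTable, depth: int = 4000, seed: int = 0) -> OtuTable:
    return Rarefier(depth=depth, random_state=seed).fit_transform(table)


def filter_low_count_taxa(table: OtuTable, min_total: int = 10) -> OtuTable:
    return LowCountFilter(min_total=min_total).fit_transform(table)


def filter_shannon_outliers(table: OtuTable, max_h: float) -> OtuTable:
    return ShannonOutlierFilter(max_h=max_h).fit_transform(table)


def prevalence_filter(table: OtuTable, min_occurrence: int = 8) -> OtuTable:
    return PrevalenceFilter(min_occurrence=min_occurrence).fit_transform(table)


# -- diversity -------------------------------------------------------------

def shannon(table: OtuTable) -> pd.Series:
    """Shannon H in nats per sample, H = -sum p_i ln p_i over p_i > 0."""
    rel = table.relative_abundance().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    return pd.Series(-plogp.sum(axis=0), index=table.sample_ids, name="shannon_H")


def diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Shannon H (nats) and Pielou evenness J.

    J = H / ln(richness), defined as 0 when richness <= 1. Computing on a
    rarefied table (equal depths) is recommended; unequal depths trigger a
    warning because richness then confounds with sequencing effort.
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise TableError(f"sample {bad!r} is empty")
    if totals.nunique() > 1:
        logger.warning("diversity: samples have unequal depths; rarefy first")
    richness = (table.counts > 0).sum(axis=0)
    h = shannon(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(richness > 1, h / np.log(richness.clip(lower=2)), 0.0)
    return pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "richness": richness.to_numpy(),
            "shannon_H": h.to_numpy(),
            "evenness_J": j,
        }
    ).set_index("sample_id", drop=False)
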