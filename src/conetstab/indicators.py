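"""Indicator-taxon analysis (Dufrene-Legendre IndVal) with a permutation null.

For taxon i and group g, A_ig is the taxon's mean relative abundance in g
divided by the sum of its group means (abundance concentration) and B_ig the
fraction of group-g samples where it occurs; IndVal_ig = A_ig * B_ig. The
observed max over groups is compared with its distribution under random
reassignment of sample labels (one shared permutation per round, preserving
taxon-taxon dependence), with the +1 Monte-Carlo correction.

Significant (p < 0.05), abundant (> 1% mean relative abundance in the best
group) indicators are classed drought-tolerant when the best group is the
drought treatment and drought-sensitive when it is the control.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .otu import OtuTable

logger = logging.getLogger("conetstab")


def _group_matrix(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """samples x groups 0/1 indicator matrix."""
    return (labels[:, None] == levels[None, :]).astype(float)


def _indval(rel: np.ndarray, member: np.ndarray) -> np.ndarray:
    """IndVal per taxon and group from relative abundances.

    rel : (taxa, samples); member : (samples, groups) indicator.
    """
    n_per_group = member.sum(axis=0)
    mean_ab = (rel @ member) / n_per_group            # (taxa, groups)
    denom = mean_ab.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, mean_ab / denom, 0.0)
    b = ((rel > 0).astype(float) @ member) / n_per_group
    return a * b


class IndValAnalysis(BaseEstimator):
    """Fit-style IndVal analysis of one table against treatment labels.

    Parameters
    ----------
    n_permutations : permutation rounds for the null (>= 99).
    p_max, min_relabund : significance and best-group mean relative abundance
        gates for calling a taxon an indicator.
    abundance_scope : 'best_group' (default) or 'overall' — which mean
        relative abundance the >1% gate applies to.
    bh_correct : apply Benjamini-Hochberg correction across taxa before the
        significance gate (off by default; raw permutation P is the
        convention this analysis mirrors).
    random_state : permutation seed.

    Attributes (after ``fit(table, labels)``)
    ----------
    results_ : DataFrame, one row per taxon with indval per group, best
        group, permutation p and class in {tolerant, sensitive, none}.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        p_max: float = 0.05,
        min_relabund: float = 0.01,
        abundance_scope: str = "best_group",
        bh_correct: bool = False,
        random_state: int = 0,
    ):
        self.n_permutations = n_permutations
        self.p_max = p_max
        self.min_relabund = min_relabund
        self.abundance_scope = abundance_scope
        self.bh_correct = bh_correct
        self.random_state = random_state

    def fit(self, table: OtuTable, labels) -> "IndValAnalysis":
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.abundance_scope not in ("best_group", "overall"):
            raise ValueError("abundance_scope must be 'best_group' or 'overall'")
        labels = np.asarray(list(labels))
        if len(labels) != table.shape[1]:
            raise ValueError("labels must align with table samples")
        levels = np.unique(labels)
        if len(levels) < 2:
            raise ValueError("need at least 2 groups")
        rel = table.relative_abundance().to_numpy()
        member = _group_matrix(labels, levels)
        iv = _indval(rel, member)
        obs_max = iv.max(axis=1)
        best_idx = iv.argmax(axis=1)

        rng = np.random.default_rng(self.random_state)
        hits = np.zeros(len(obs_max))
        for _ in range(self.n_permutations):
            perm_member = member[rng.permutation(len(labels)), :]
            perm_max = _indval(rel, perm_member).max(axis=1)
            hits += perm_max >= obs_max - 1e-12
        p_perm = (1.0 + hits) / (1.0 + self.n_permutations)
        p_gate = p_perm
        if self.bh_correct:
            from statsmodels.stats.multitest import multipletests

            p_gate = multipletests(p_perm, method="fdr_bh")[1]

        mean_rel = (rel @ member) / member.sum(axis=0)  # taxa x groups
        best_group = levels[best_idx]
        gate_ab = (
            mean_rel[np.arange(len(best_idx)), best_idx]
            if self.abundance_scope == "best_group"
            else rel.mean(axis=1)
        )
        significant = (p_gate < self.p_max) & (gate_ab > self.min_relabund)
        cls = np.where(
            ~significant,
            "none",
            np.where(best_group == "drought", "tolerant",
                     np.where(best_group == "control", "sensitive", "none")),
        )
        res = pd.DataFrame({"taxon_id": table.taxon_ids})
        for gi, g in enumerate(levels):
            res[f"indval_{g}"] = iv[:, gi]
            res[f"mean_relabund_{g}"] = mean_rel[:, gi]
        res["best_group"] = best_group
        res["indval_max"] = obs_max
        res["p_perm"] = p_perm
        if self.bh_correct:
            res["p_adj"] = p_gate
        res["class"] = cls
        self.groups_ = list(levels)
        self.results_ = res.set_index("taxon_id", drop=False)
        return self


# -- functional wrappers ---------------------------------------------------

def indval_scores(table: OtuTable, labels) -> pd.DataFrame:
    """IndVal per taxon and group (no permutation test)."""
    labels = np.asarray(list(labels))
    levels = np.unique(labels)
    rel = table.relative_abundance().to_numpy()
    iv = _indval(rel, _group_matrix(labels, levels))
    return pd.DataFrame(iv, index=table.taxon_ids, columns=levels)


def indval_permutation_test(
    table: OtuTable, labels, n_perm: int = 1000, seed: int = 0
) -> pd.Series:
    fit = IndValAnalysis(n_permutations=n_perm, random_state=seed).fit(table, labels)
    return fit.results_["p_perm"]


def indval_exact_p(table: OtuTable, labels) -> pd.Series:
    """Exact permutation p by exhaustive enumeration of label arrangements.

    Feasible only for small designs (e.g. 6 vs 6 -> 924 arrangements); used
    as an oracle for the Monte-Carlo p.
    """
    labels = np.asarray(list(labels))
    levels = np.unique(labels)
    rel = table.relative_abundance().to_numpy()
    obs = _indval(rel, _group_matrix(labels, levels)).max(axis=1)
    n = len(labels)
    hits = np.zeros(len(obs))
    total = 0
    # enumerate distinct position-assignments of the label multiset
    counts = {g: int((labels == g).sum()) for g in levels}
    first = levels[0]
    for pos in itertools.combinations(range(n), counts[first]):
        if len(levels) != 2:
            raise NotImplementedError("exact enumeration supports 2 groups")
        arr = np.full(n, levels[1], dtype=labels.dtype)
        arr[list(pos)] = first
        perm_max = _indval(rel, _group_matrix(arr, levels)).max(axis=1)
        hits += perm_max >= obs - 1e-12
        total += 1
    return pd.Series(hits / total, index=table.taxon_ids, name="p_exact")


def classify_indicators(
    results: pd.DataFrame,
    p_max: float = 0.05,
    min_relabund: float = 0.01,
) -> pd.Series:
    """Re-apply the significance and abundance gates to a results table."""
    best_ab = np.array(
        [results.loc[t, f"mean_relabund_{results.loc[t, 'best_group']}"] for t in results.index]
    )
    significant = (results["p_perm"] < p_max) & (best_ab > min_relabund)
    cls = np.where(
        ~significant,
        "none",
        np.where(results["best_group"] == "drought", "tolerant",
                 np.where(results["best_group"] == "control", "sensitive", "none")),
    )
    return pd.Series(cls, index=results.index, name="class")


# -- responder proportions (bacteria vs fungi contrast) --------------------

@dataclass
class ResponderComparison:
    k1: int
    n1: int
    k2: int
    n2: int
    chi2: float
    p: float


def increased_under_drought(table: OtuTable, labels) -> pd.Series:
    """Per taxon: True iff mean relative abundance (drought) > (control).

    Taxa absent from both groups are excluded (NaN); ties count as not
    increased.
    """
    labels = np.asarray(list(labels))
    rel = table.relative_abundance().to_numpy()
    mask_d, mask_c = labels == "drought", labels == "control"
    mean_d = rel[:, mask_d].mean(axis=1)
    mean_c = rel[:, mask_c].mean(axis=1)
    out = pd.Series(mean_d > mean_c, index=table.taxon_ids, dtype=object)
    absent = (mean_d == 0) & (mean_c == 0)
    if absent.any():
        logger.info("responders: excluded %d taxa absent from both groups", absent.sum())
        out[absent] = np.nan
    return out


def responder_proportions(
    table_a: OtuTable, labels_a, table_b: OtuTable, labels_b
) -> ResponderComparison:
    """Compare the proportion of taxa increasing under drought between two
    communities with a two-sided chi-square test of proportions."""
    from .group_stats import chi2_proportions

    inc_a = increased_under_drought(table_a, labels_a).dropna()
    inc_b = increased_under_drought(table_b, labels_b).dropna()
    k1, n1 = int(inc_a.sum()), len(inc_a)
    k2, n2 = int(inc_b.sum()), len(inc_b)
    res = chi2_proportions(k1, n1, k2, n2)
    return ResponderComparison(k1, n1, k2, n2, res.statistic, res.p)
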